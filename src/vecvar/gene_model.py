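"""In-memory gene model and genome sequence store.

All genomic coordinates are 1-based inclusive (GTF/VCF native) and stored in
genomic (plus-strand) orientation regardless of transcript strand; translation
order is handled by the consumers.  CDS intervals include the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ModelConsistencyError(ValueError):
    """A gene model violates a structural invariant (e.g. CDS outside exons)."""


@dataclass(frozen=True)
class CDSSegment:
    start: int
    end: int
    phase: int  # GTF frame column: bases to skip before the first full codon

    def __post_init__(self):
        if self.start > self.end:
            raise ModelConsistencyError(f"CDS start {self.start} > end {self.end}")
        if self.phase not in (0, 1, 2):
            raise ModelConsistencyError(f"CDS phase must be 0/1/2, got {self.phase}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)  # sorted by start
    cds: list[CDSSegment] = field(default_factory=list)  # sorted by start
    utrs: list[tuple[int, int, str]] = field(default_factory=list)  # (s, e, '5'|'3')
    tags: set[str] = field(default_factory=set)
    biotype: str = "protein_coding"

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ModelConsistencyError(f"{self.id}: bad strand {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ModelConsistencyError(f"{self.id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ModelConsistencyError(
                    f"{self.id}: exons overlap or are unsorted at {s}"
                )
            prev_end = e
        for seg in self.cds:
            if not any(s <= seg.start and seg.end <= e for s, e in self.exons):
                raise ModelConsistencyError(
                    f"{self.id}: CDS ({seg.start},{seg.end}) outside all exons"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_segments_translation_order(self) -> list[CDSSegment]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def coding_length(self) -> int:
        return sum(seg.length for seg in self.cds)


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)


@dataclass
class GeneModel:
    genes: dict[str, Gene] = field(default_factory=dict)

    def transcripts(self):
        for gene in self.genes.values():
            yield from gene.transcripts

    def transcript(self, tid: str) -> Transcript:
        for t in self.transcripts():
            if t.id == tid:
                return t
        raise KeyError(tid)

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def validate(self) -> None:
        for t in self.transcripts():
            t.validate()


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (an involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceStore:
    """Chromosome name -> uppercase nucleotide string, 1-based accessors.

    Wraps either an in-memory dict or a pyfaidx-backed FASTA; both are
    normalized to uppercase on access.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        # materialize: fixtures are short chromosomes, random access afterwards
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._chrom(chrom))

    def _chrom(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not present in sequence store") from None

    def substring(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive substring; positions beyond the ends read as 'N'."""
        s = self._chrom(chrom)
        if start > end:
            return ""
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - len(s))
        core = s[max(start, 1) - 1 : min(end, len(s))]
        return "N" * left_pad + core + "N" * right_pad

    def base(self, chrom: str, pos: int) -> str:
        return self.substring(chrom, pos, pos)

    def reverse_complement(self, chrom: str, start: int, end: int) -> str:
        return reverse_complement(self.substring(chrom, start, end))
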