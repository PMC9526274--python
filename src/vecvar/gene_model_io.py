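"""Read gene annotations (GTF / GFF3) and genome FASTA into the gene model.

Both attribute dialects are accepted and auto-detected per file (gffutils does
the sniffing).  Transcripts carrying nonsense-mediated-decay or
incomplete-coding-sequence tags are dropped at load time: such annotations are
built from incomplete evidence and would poison frame-sensitive consequence
calls downstream.  "Incomplete coding sequence" is operationalized as
(a) start/stop-not-found tags, or (b) a CDS whose phase-adjusted length is not
a multiple of 3.
"""

from __future__ import annotations

from pathlib import Path

from .gene_model import CDSSegment, Gene, GeneModel, SequenceStore, Transcript

__all__ = [
    "DEFAULT_EXCLUDED_TAGS",
    "AnnotationParseError",
    "load_gene_annotation",
    "load_genome",
    "write_gtf",
]

#: Transcript tags excluded by default: NMD plus incomplete-CDS markers.
DEFAULT_EXCLUDED_TAGS = frozenset(
    {
        "NMD_transcript",
        "nonsense_mediated_decay",
        "cds_start_NF",
        "cds_end_NF",
        "mRNA_start_NF",
        "mRNA_end_NF",
        "incomplete_terminal_codon",
    }
)

_TRANSCRIPT_TYPES = {"transcript", "mRNA"}
_UTR_TYPES = {"five_prime_utr", "three_prime_utr", "UTR"}


class AnnotationParseError(ValueError):
    """Malformed annotation row; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


def _prevalidate(path: Path) -> None:
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    line_no, f"expected 9 tab-separated fields, found {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationParseError(line_no, "non-integer start/end") from None
            if start > end:
                raise AnnotationParseError(line_no, f"start {start} > end {end}")


def _strip_id(value: str) -> str:
    # GFF3 convention: Parent=transcript:ENST...; ID=gene:ENSG...
    return value.split(":", 1)[1] if ":" in value else value


def _first(attrs, *keys) -> str | None:
    for k in keys:
        if k in attrs:
            return attrs[k][0]
    return None


def load_gene_annotation(
    path,
    exclude_tags: frozenset[str] = DEFAULT_EXCLUDED_TAGS,
    require_complete_cds: bool = True,
) -> GeneModel:
    """Parse a GTF or GFF3 file into a :class:`GeneModel`.

    Transcripts carrying any tag in *exclude_tags* are absent from the result;
    with *require_complete_cds*, transcripts whose phase-adjusted CDS length is
    not a multiple of 3 are dropped as well.  Genes left without transcripts
    are removed.
    """
    import gffutils

    path = Path(path)
    _prevalidate(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    transcripts: dict[str, Transcript] = {}
    order: list[str] = []

    for f in db.all_features(order_by=("seqid", "start", "featuretype")):
        if f.featuretype not in _TRANSCRIPT_TYPES:
            continue
        tid = _first(f.attributes, "transcript_id") or _strip_id(
            _first(f.attributes, "ID") or ""
        )
        gid = _first(f.attributes, "gene_id") or _strip_id(
            _first(f.attributes, "Parent") or ""
        )
        if not tid or not gid:
            raise AnnotationParseError(0, f"transcript feature without id/parent: {f}")
        tags = set(f.attributes.get("tag", []))
        biotype = (
            _first(f.attributes, "transcript_biotype", "transcript_type", "biotype")
            or "protein_coding"
        )
        transcripts[tid] = Transcript(
            id=tid, gene_id=gid, chrom=f.seqid, strand=f.strand, tags=tags, biotype=biotype
        )
        order.append(tid)

    for f in db.all_features(order_by=("seqid", "start")):
        ftype = f.featuretype
        if ftype not in ({"exon", "CDS"} | _UTR_TYPES):
            continue
        tid = _first(f.attributes, "transcript_id") or _strip_id(
            _first(f.attributes, "Parent") or ""
        )
        if tid not in transcripts:
            # sub-feature without an explicit transcript row (plain GTF dumps)
            gid = _first(f.attributes, "gene_id") or tid
            transcripts[tid] = Transcript(
                id=tid, gene_id=gid, chrom=f.seqid, strand=f.strand
            )
            order.append(tid)
        t = transcripts[tid]
        if ftype == "exon":
            t.exons.append((f.start, f.end))
        elif ftype == "CDS":
            phase = 0 if f.frame in (None, ".") else int(f.frame)
            t.cds.append(CDSSegment(f.start, f.end, phase))
        else:
            side = (
                "5"
                if ftype == "five_prime_utr"
                else "3"
                if ftype == "three_prime_utr"
                else "?"
            )
            t.utrs.append((f.start, f.end, side))

    model = GeneModel()
    for tid in order:
        t = transcripts[tid]
        t.exons.sort()
        t.cds.sort(key=lambda seg: seg.start)
        t.utrs.sort()
        # resolve generic UTR rows by position relative to the CDS extent
        if t.cds and any(side == "?" for _, _, side in t.utrs):
            cds_lo = min(seg.start for seg in t.cds)
            resolved = []
            for s, e, side in t.utrs:
                if side == "?":
                    upstream = e < cds_lo
                    side = ("5" if upstream else "3") if t.strand == "+" else (
                        "3" if upstream else "5"
                    )
                resolved.append((s, e, side))
            t.utrs = resolved
        t.validate()  # structural errors surface even for filtered transcripts
        if t.tags & exclude_tags:
            continue
        if t.biotype == "nonsense_mediated_decay":
            continue
        if require_complete_cds and t.cds:
            first = t.cds_segments_translation_order()[0]
            if (t.coding_length() - first.phase) % 3 != 0:
                continue
        gene = model.genes.setdefault(t.gene_id, Gene(t.gene_id, t.chrom, t.strand))
        gene.transcripts.append(t)
    return model


def load_genome(path) -> SequenceStore:
    """Load an (optionally faidx-indexed) FASTA into a :class:`SequenceStore`."""
    return SequenceStore.from_fasta(path)


def _fmt_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(model: GeneModel, path) -> None:
    """Write a GeneModel as GTF with canonical attribute ordering.

    Re-parsing the output (with filtering disabled) yields an identical model.
    """
    lines = []
    for gene in model.genes.values():
        gs, ge = gene.span
        lines.append(
            "\t".join(
                [
                    gene.chrom,
                    "vecvar",
                    "gene",
                    str(gs),
                    str(ge),
                    ".",
                    gene.strand,
                    ".",
                    _fmt_attrs([("gene_id", gene.id)]),
                ]
            )
        )
        for t in gene.transcripts:
            ts, te = t.span
            attrs = [("gene_id", gene.id), ("transcript_id", t.id)]
            attrs.append(("transcript_biotype", t.biotype))
            attrs.extend(("tag", tag) for tag in sorted(t.tags))
            lines.append(
                "\t".join(
                    [
                        t.chrom,
                        "vecvar",
                        "transcript",
                        str(ts),
                        str(te),
                        ".",
                        t.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
            )
            base = [("gene_id", gene.id), ("transcript_id", t.id)]
            for s, e in t.exons:
                lines.append(
                    "\t".join(
                        [t.chrom, "vecvar", "exon", str(s), str(e), ".", t.strand, ".", _fmt_attrs(base)]
                    )
                )
            for seg in t.cds:
                lines.append(
                    "\t".join(
                        [
                            t.chrom,
                            "vecvar",
                            "CDS",
                            str(seg.start),
                            str(seg.end),
                            ".",
                            t.strand,
                            str(seg.phase),
                            _fmt_attrs(base),
                        ]
                    )
                )
            for s, e, side in t.utrs:
                ftype = "five_prime_utr" if side == "5" else "three_prime_utr"
                lines.append(
                    "\t".join(
                        [t.chrom, "vecvar", ftype, str(s), str(e), ".", t.strand, ".", _fmt_attrs(base)]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")
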