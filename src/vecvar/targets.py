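"""Target regions and the stitched linear ("vectorized") coordinate system.

Extended CDS (or exon) intervals are collected per transcript or per gene,
sorted by (start, element id) within each chromosome, and stitched end to end
into one logical vector of length ``l_T = sum(e_i - s_i + 1)``.  One genomic
position may map to several vector coordinates — once per containing region —
because overlapping transcripts are deliberately represented redundantly.

Vector coordinates ``nu`` are 1-based (1 <= nu <= l_T); region indices are
0-based Python indices.  The genomic position of a vector coordinate is
``c = s_k + (nu - cum[k] - 1)`` so that nu=1 maps to the first base of the
first region and the round trip genomic -> vector -> genomic is the identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_model import GeneModel

__all__ = [
    "TargetRegion",
    "TargetRegionSet",
    "CoordinateError",
    "build_transcript_targets",
    "build_gene_targets",
    "write_bed",
    "read_bed",
]


class CoordinateError(ValueError):
    """Vector coordinate out of [1, l_T] or otherwise unmappable."""


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int  # 1-based inclusive, already extended
    end: int
    element_id: str  # transcript id (transcript mode) or gene id (gene mode)
    transcript_id: str  # representative transcript for frame/codon context
    strand: str
    frame: int  # phase of the source CDS
    kind: str = "cds"  # 'cds', 'exon' or 'bed'
    cds_start: int = 0  # unextended source interval (0 when kind='bed')
    cds_end: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise CoordinateError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _natural_key(chrom: str):
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", chrom)]


@dataclass
class TargetRegionSet:
    """Sorted, stitched target regions with cumulative offsets."""

    regions: list[TargetRegion]
    l_ext: int = 0

    cum: np.ndarray = field(init=False, repr=False)  # cum[i] = nucleotides before region i
    l_T: int = field(init=False)

    def __post_init__(self):
        self.regions = sorted(
            self.regions,
            key=lambda r: (
                _natural_key(r.chrom),
                r.start,
                r.element_id,
                r.end,
                r.frame,
            ),
        )
        lengths = np.array([r.length for r in self.regions], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(lengths)])
        self.l_T = int(self.cum[-1])
        self._trees = None

    # -- identity ---------------------------------------------------------
    def content_hash(self) -> str:
        """Stable digest of the stitched layout; guards cross-stage mixups."""
        import hashlib

        h = hashlib.sha256()
        for r in self.regions:
            h.update(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.element_id}\t{r.strand}\t{r.frame}\n".encode()
            )
        h.update(str(self.l_ext).encode())
        return h.hexdigest()[:16]

    # -- vector -> genomic ------------------------------------------------
    def region_index(self, nu: int) -> int:
        """0-based index of the region containing vector coordinate *nu*."""
        if not 1 <= nu <= self.l_T:
            raise CoordinateError(f"vector coordinate {nu} outside [1, {self.l_T}]")
        return int(np.searchsorted(self.cum, nu - 1, side="right")) - 1

    def vector_to_genomic(self, nu: int) -> tuple[int, str, int]:
        """Map nu to (region index, chrom, genomic position)."""
        k = self.region_index(nu)
        r = self.regions[k]
        return k, r.chrom, r.start + (nu - int(self.cum[k]) - 1)

    def vector_to_genomic_bulk(self, nus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (region index, genomic position) for an array of nu."""
        nus = np.asarray(nus, dtype=np.int64)
        if nus.size and (nus.min() < 1 or nus.max() > self.l_T):
            raise CoordinateError("vector coordinate outside [1, l_T]")
        ks = np.searchsorted(self.cum, nus - 1, side="right") - 1
        starts = np.array([r.start for r in self.regions], dtype=np.int64)
        return ks, starts[ks] + (nus - self.cum[ks] - 1)

    # -- genomic -> vector ------------------------------------------------
    def _ensure_trees(self):
        if self._trees is None:
            from intervaltree import IntervalTree

            trees: dict[str, "IntervalTree"] = {}
            for i, r in enumerate(self.regions):
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, i)
            self._trees = trees
        return self._trees

    def overlapping_regions(self, chrom: str, pos: int) -> list[int]:
        trees = self._ensure_trees()
        if chrom not in trees:
            return []
        return sorted(iv.data for iv in trees[chrom].at(pos))

    def overlapping_regions_span(self, chrom: str, lo: int, hi: int) -> list[int]:
        """Indices of regions overlapping the genomic interval [lo, hi]."""
        trees = self._ensure_trees()
        if chrom not in trees:
            return []
        return sorted(iv.data for iv in trees[chrom].overlap(lo, hi + 1))

    def genomic_to_vector(self, chrom: str, pos: int) -> list[int]:
        """All vector coordinates mapping to a genomic position (may be empty)."""
        return [
            int(self.cum[i]) + (pos - self.regions[i].start) + 1
            for i in self.overlapping_regions(chrom, pos)
        ]

    def region_vector_range(self, k: int) -> tuple[int, int]:
        """Inclusive vector-coordinate range [lo, hi] of region k."""
        return int(self.cum[k]) + 1, int(self.cum[k + 1])

    def region_id_vector(self) -> np.ndarray:
        """Length-l_T array assigning each slot its region index."""
        lengths = np.diff(self.cum)
        return np.repeat(np.arange(len(self.regions), dtype=np.int64), lengths)

    def genomic_position_vector(self) -> np.ndarray:
        """Length-l_T array of genomic positions (the brute-force stitched array)."""
        parts = [np.arange(r.start, r.end + 1, dtype=np.int64) for r in self.regions]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def _cds_regions_for_transcript(t, l_ext: int, use_utr: bool):
    if use_utr:
        intervals = [(s, e, _phase_for_exon(t, s, e)) for s, e in t.exons]
        kind = "exon"
    else:
        intervals = [(seg.start, seg.end, seg.phase) for seg in t.cds]
        kind = "cds"
    for s, e, phase in intervals:
        yield s, e, phase, kind


def _phase_for_exon(t, s, e) -> int:
    for seg in t.cds:
        if s <= seg.start and seg.end <= e:
            return seg.phase
    return 0


def build_transcript_targets(
    model: GeneModel, l_ext: int = 10, use_utr: bool = False
) -> TargetRegionSet:
    """Transcript-specific target regions: one region per CDS per transcript.

    Every CDS (or whole exon when *use_utr*) is extended by *l_ext* bp on each
    side so that splice acceptor/donor motifs fall inside the targets.
    Genomic positions shared by several transcripts appear once per transcript.
    """
    if l_ext < 0:
        raise ValueError(f"l_ext must be non-negative, got {l_ext}")
    regions = []
    for t in model.transcripts():
        for s, e, phase, kind in _cds_regions_for_transcript(t, l_ext, use_utr):
            regions.append(
                TargetRegion(
                    chrom=t.chrom,
                    start=max(1, s - l_ext),
                    end=e + l_ext,
                    element_id=t.id,
                    transcript_id=t.id,
                    strand=t.strand,
                    frame=phase,
                    kind=kind,
                    cds_start=s,
                    cds_end=e,
                )
            )
    return TargetRegionSet(regions, l_ext=l_ext)


def build_gene_targets(model: GeneModel, l_ext: int = 10) -> TargetRegionSet:
    """Gene-specific target regions: per gene, CDSs unique on (start, end, frame).

    Alternatively spliced transcripts frequently repeat a CDS at the same
    coordinates and frame; any variant has the same impact on all of them, so
    one copy per gene suffices.  Identical coordinates at a *different* frame
    are kept as separate regions.
    """
    if l_ext < 0:
        raise ValueError(f"l_ext must be non-negative, got {l_ext}")
    regions = []
    for gene in model.genes.values():
        seen: set[tuple[int, int, int]] = set()
        for t in gene.transcripts:
            for seg in t.cds:
                key = (seg.start, seg.end, seg.phase)
                if key in seen:
                    continue
                seen.add(key)
                regions.append(
                    TargetRegion(
                        chrom=t.chrom,
                        start=max(1, seg.start - l_ext),
                        end=seg.end + l_ext,
                        element_id=gene.id,
                        transcript_id=t.id,
                        strand=t.strand,
                        frame=seg.phase,
                        kind="cds",
                        cds_start=seg.start,
                        cds_end=seg.end,
                    )
                )
    return TargetRegionSet(regions, l_ext=l_ext)


def write_bed(targets: TargetRegionSet, path) -> None:
    """Write target regions as BED (0-based half-open), in stitched order."""
    with open(path, "w") as fh:
        for r in targets.regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.element_id}\t0\t{r.strand}\n"
            )


def read_bed(path, l_ext: int = 0) -> TargetRegionSet:
    """Read user-supplied target regions from BED (name and strand honored)."""
    regions = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {line_no}: fewer than 3 columns")
        chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"region_{line_no}"
        strand = fields[5] if len(fields) > 5 else "+"
        regions.append(
            TargetRegion(
                chrom=chrom,
                start=start0 + 1,
                end=end,
                element_id=name,
                transcript_id=name,
                strand=strand,
                frame=0,
                kind="bed",
            )
        )
    return TargetRegionSet(regions, l_ext=l_ext)
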