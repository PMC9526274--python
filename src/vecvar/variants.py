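"""VCF parsing, variant normalization, and binary loci / genotype encoding.

Variants are normalized to three shapes — SNV, deletion span, insertion-after
position — by splitting multi-allelic rows and stripping VCF anchor bases:
``REF=ACT ALT=A`` at pos p is the deletion of [p+1, p+2]; ``REF=A ALT=ACT`` is
the insertion of "CT" after p; alleles are plus-strand as in the VCF and no
re-alignment beyond anchor stripping is performed.  Each variant is then
written into per-allele binary vectors over the stitched target coordinates
(every vector coordinate the variant maps to is set, once per containing
region), or into an l_T x n_G genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .impact import ALLELES, DEL_ALLELE, INS_ALLELE
from .targets import TargetRegionSet

__all__ = [
    "SNV",
    "Deletion",
    "Insertion",
    "VariantSet",
    "VariantLociVector",
    "GenotypeMatrix",
    "VcfRecordError",
    "parse_vcf",
    "vectorize_loci",
    "vectorize_genotypes",
    "vectorize_noncoding_elements",
]


class VcfRecordError(ValueError):
    """A VCF record is inconsistent with its stated POS/REF/ALT semantics."""


@dataclass(frozen=True, order=True)
class SNV:
    chrom: str
    pos: int
    alt: str  # single base, != reference


@dataclass(frozen=True, order=True)
class Deletion:
    chrom: str
    d1: int  # first deleted base (1-based inclusive)
    d2: int  # last deleted base

    def __post_init__(self):
        if self.d1 > self.d2:
            raise ValueError(f"deletion start {self.d1} > end {self.d2}")

    @property
    def length(self) -> int:
        return self.d2 - self.d1 + 1


@dataclass(frozen=True, order=True)
class Insertion:
    chrom: str
    pos: int  # base AFTER which the sequence is inserted
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError("inserted sequence must be non-empty")


@dataclass
class VariantSet:
    snvs: list[SNV] = field(default_factory=list)
    deletions: list[Deletion] = field(default_factory=list)
    insertions: list[Insertion] = field(default_factory=list)
    skipped_symbolic: int = 0
    skipped_complex: int = 0

    def __len__(self) -> int:
        return len(self.snvs) + len(self.deletions) + len(self.insertions)


def _classify_alleles(chrom: str, pos: int, ref: str, alt: str, where: str):
    """Normalize one (REF, ALT) pair; returns an SNV/Deletion/Insertion or None."""
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise VcfRecordError(f"{where}: empty REF/ALT")
    if any(c in alt for c in "<>[]"):
        return "symbolic"
    # strip common prefix (VCF anchor convention)
    n = 0
    while n < min(len(ref), len(alt)) - 0 and n < len(ref) and n < len(alt) and ref[n] == alt[n]:
        n += 1
    if len(ref) == len(alt) == 1:
        if ref == alt:
            return None  # monomorphic record
        return SNV(chrom, pos, alt)
    if alt == ref[: len(alt)] and len(ref) > len(alt):
        return Deletion(chrom, pos + len(alt), pos + len(ref) - 1)
    if ref == alt[: len(ref)] and len(alt) > len(ref):
        return Insertion(chrom, pos + len(ref) - 1, alt[len(ref) :])
    if n >= 1 and len(ref) - n == 1 and len(alt) - n == 1:
        return SNV(chrom, pos + n, alt[n:])
    return "complex"


def parse_vcf(path) -> VariantSet:
    """Read a VCF 4.x file (sites are enough) into a normalized VariantSet.

    Multi-allelic rows are split; symbolic alleles and complex substitutions
    are skipped and counted.
    """
    import pysam

    vs = VariantSet()
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf, start=1):
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt in (None, "*", "."):
                    continue
                out = _classify_alleles(
                    rec.chrom, rec.pos, rec.ref, alt, f"record {i} ({rec.chrom}:{rec.pos})"
                )
                if out is None:
                    continue
                if out == "symbolic":
                    vs.skipped_symbolic += 1
                elif out == "complex":
                    vs.skipped_complex += 1
                elif isinstance(out, SNV):
                    vs.snvs.append(out)
                elif isinstance(out, Deletion):
                    vs.deletions.append(out)
                else:
                    vs.insertions.append(out)
    return vs


@dataclass
class VariantLociVector:
    """Binary length-l_T vector marking variant positions for one allele."""

    allele: str
    bits: np.ndarray  # uint8 in {0,1}
    targets: TargetRegionSet = field(repr=False)
    target_hash: str = ""
    skipped_off_target: int = 0

    def __post_init__(self):
        if self.allele not in ALLELES:
            raise ValueError(f"unknown allele {self.allele!r}")
        if len(self.bits) != self.targets.l_T:
            raise ValueError("loci vector length != l_T")
        if not self.target_hash:
            self.target_hash = self.targets.content_hash()


def vectorize_loci(vs: VariantSet, targets: TargetRegionSet, allele: str) -> VariantLociVector:
    """Build the variant loci vector for one allele.

    SNVs set every vector coordinate of their position (alt must match the
    allele); deletions set every coordinate of every deleted base; insertions
    set the coordinates of the base they follow.  Variants mapping to no
    target contribute nothing and are counted as skipped.
    """
    if allele not in ALLELES:
        raise ValueError(f"unknown allele {allele!r}")
    bits = np.zeros(targets.l_T, dtype=np.uint8)
    skipped = 0

    def hit(chrom, pos) -> bool:
        nus = targets.genomic_to_vector(chrom, pos)
        for nu in nus:
            bits[nu - 1] = 1
        return bool(nus)

    if allele in "ACGT":
        for v in vs.snvs:
            if v.alt == allele:
                if not hit(v.chrom, v.pos):
                    skipped += 1
    elif allele == DEL_ALLELE:
        for d in vs.deletions:
            any_hit = False
            for c in range(d.d1, d.d2 + 1):
                any_hit |= hit(d.chrom, c)
            if not any_hit:
                skipped += 1
    else:
        for ins in vs.insertions:
            if not hit(ins.chrom, ins.pos):
                skipped += 1
    return VariantLociVector(
        allele=allele, bits=bits, targets=targets, skipped_off_target=skipped
    )


@dataclass
class GenotypeMatrix:
    """l_T x n_G integer genotype matrix for one allele.

    ``mode='dosage'`` stores alternate-allele counts {0,1,2}; ``'existence'``
    stores 2-level presence flags {0,1} (beacon-style).
    """

    allele: str
    values: np.ndarray  # int16, shape (l_T, n_G)
    mode: str
    samples: list[str]
    targets: TargetRegionSet = field(repr=False)
    target_hash: str = ""
    missing_per_sample: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("dosage", "existence"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if self.values.shape != (self.targets.l_T, len(self.samples)):
            raise ValueError("genotype matrix shape != (l_T, n_G)")
        hi = 2 if self.mode == "dosage" else 1
        if self.values.size and (self.values.min() < 0 or self.values.max() > hi):
            raise ValueError(f"values outside [0, {hi}] for mode {self.mode}")
        if not self.target_hash:
            self.target_hash = self.targets.content_hash()

    @property
    def n_G(self) -> int:
        return len(self.samples)


def vectorize_genotypes(
    path, targets: TargetRegionSet, allele: str, mode: str = "dosage"
) -> GenotypeMatrix:
    """Encode the GT fields of a multi-sample VCF onto the vector coordinates.

    Deletion genotypes expand over every deleted base.  Missing genotypes
    (./.) encode as reference and are counted per sample; non-diploid
    genotypes are an error.
    """
    import pysam

    if allele not in ALLELES:
        raise ValueError(f"unknown allele {allele!r}")
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        values = np.zeros((targets.l_T, len(samples)), dtype=np.int16)
        missing = np.zeros(len(samples), dtype=np.int64)
        for i, rec in enumerate(vf, start=1):
            if rec.alts is None:
                continue
            shapes = [
                _classify_alleles(rec.chrom, rec.pos, rec.ref, alt, f"record {i}")
                for alt in rec.alts
            ]
            for k, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or all(g is None for g in gt):
                    missing[k] += 1
                    continue
                if len(gt) != 2:
                    raise VcfRecordError(f"record {i}: sample {sample} ploidy {len(gt)} != 2")
                for ai, shape in enumerate(shapes, start=1):
                    dose = sum(1 for g in gt if g == ai)
                    if not dose or not isinstance(shape, (SNV, Deletion, Insertion)):
                        continue
                    if allele in "ACGT":
                        match = isinstance(shape, SNV) and shape.alt == allele
                        spans = [(shape.chrom, shape.pos)] if match else []
                    elif allele == DEL_ALLELE:
                        spans = (
                            [(shape.chrom, c) for c in range(shape.d1, shape.d2 + 1)]
                            if isinstance(shape, Deletion)
                            else []
                        )
                    else:
                        spans = (
                            [(shape.chrom, shape.pos)] if isinstance(shape, Insertion) else []
                        )
                    for chrom, pos in spans:
                        for nu in targets.genomic_to_vector(chrom, pos):
                            values[nu - 1, k] += dose
    if mode == "existence":
        values = np.minimum(values, 1)
    else:
        values = np.minimum(values, 2)
    return GenotypeMatrix(
        allele=allele,
        values=values,
        mode=mode,
        samples=samples,
        targets=targets,
        missing_per_sample=missing,
    )


def vectorize_noncoding_elements(vs: VariantSet, elements) -> np.ndarray:
    """Element-level binary vector: entry j = 1 iff any variant overlaps
    element j.  *elements* is a sorted list of (chrom, start, end, name)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for j, (chrom, start, end, _name) in enumerate(elements):
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, j)
    bits = np.zeros(len(elements), dtype=np.uint8)

    def mark(chrom, lo, hi):
        if chrom in trees:
            for iv in trees[chrom].overlap(lo, hi + 1):
                bits[iv.data] = 1

    for v in vs.snvs:
        mark(v.chrom, v.pos, v.pos)
    for d in vs.deletions:
        mark(d.chrom, d.d1, d.d2)
    for ins in vs.insertions:
        mark(ins.chrom, ins.pos, ins.pos)
    return bits
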