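"""Canonical impact-term table and the 58-bit packed impact value.

Every possible point mutation (SNV allele, 1-bp deletion, 1-bp insertion) on
the target regions is annotated with a set of consequence terms drawn from a
frozen, 38-entry vocabulary.  The assignment is packed into a single integer

    packed = (((bitmap << 18) + neighborhood) << 2) + frame        (< 2**58)

where ``bitmap`` is a 38-bit set over the vocabulary, ``neighborhood`` encodes
the 6-nt genomic vicinity of the mutation at 3 bits per base
(A:000, C:001, G:010, T:011, N:100, leftmost base most significant) and
``frame`` is the coding frame (offset of the position within its codon,
0 for non-coding positions).  The value fits comfortably in a 64-bit slot.

The first 20 vocabulary entries follow the published coding-region term table
in its printed order; the remainder completes the standard variant-consequence
vocabulary (alphabetically) to the fixed width of 38.  Indices are public,
frozen constants: two parties exchanging packed vectors must agree on them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ALLELES",
    "DEL_ALLELE",
    "INS_ALLELE",
    "IMPACT_TERMS",
    "TERM_INDEX",
    "SEVERITY",
    "HIGH_IMPACT_TERMS",
    "N_TERMS",
    "NEIGHBORHOOD_LEN",
    "encode_neighborhood",
    "decode_neighborhood",
    "pack_impact",
    "unpack_impact",
    "bitmap_of",
    "terms_of",
    "severity_of",
    "PackingError",
]


class PackingError(ValueError):
    """Raised when a field does not fit its allotted bit width."""


#: The six variant alleles: four SNV alternates plus the 1-bp deletion and
#: 1-bp insertion states.  Arbitrary-length indels are represented through
#: the 1-bp states (runs for deletions, a single junction slot for insertions).
DEL_ALLELE = "del"
INS_ALLELE = "ins"
ALLELES: tuple[str, ...] = ("A", "C", "G", "T", DEL_ALLELE, INS_ALLELE)


#: Canonical ordered vocabulary; index in this tuple == bit index in bitmaps.
IMPACT_TERMS: tuple[str, ...] = (
    # coding-region table, printed order
    "intron_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
    "coding_sequence_variant",
    "synonymous_variant",
    "stop_retained_variant",
    "start_retained_variant",
    "incomplete_terminal_codon_variant",
    "splice_region_variant",
    "protein_altering_variant",
    "missense_variant",
    "inframe_deletion",
    "inframe_insertion",
    "transcript_amplification",
    "start_lost",
    "stop_lost",
    "frameshift_variant",
    "stop_gained",
    "splice_donor_variant",
    "splice_acceptor_variant",
    # remaining standard consequence vocabulary, alphabetical
    "NMD_transcript_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "downstream_gene_variant",
    "feature_elongation",
    "feature_truncation",
    "intergenic_variant",
    "mature_miRNA_variant",
    "non_coding_transcript_exon_variant",
    "non_coding_transcript_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "regulatory_region_variant",
    "splice_donor_5th_base_variant",
    "splice_donor_region_variant",
    "transcript_ablation",
    "upstream_gene_variant",
)

N_TERMS = 38
assert len(IMPACT_TERMS) == N_TERMS

TERM_INDEX: dict[str, int] = {t: i for i, t in enumerate(IMPACT_TERMS)}

#: Standard 4-level severity classes.  The six HIGH coding terms are
#: frameshift_variant, splice_acceptor_variant, splice_donor_variant,
#: stop_gained, stop_lost, start_lost.
SEVERITY: dict[str, str] = {
    "transcript_ablation": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "stop_gained": "HIGH",
    "frameshift_variant": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "transcript_amplification": "HIGH",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "missense_variant": "MODERATE",
    "protein_altering_variant": "MODERATE",
    "splice_region_variant": "LOW",
    "splice_donor_5th_base_variant": "LOW",
    "splice_donor_region_variant": "LOW",
    "incomplete_terminal_codon_variant": "LOW",
    "start_retained_variant": "LOW",
    "stop_retained_variant": "LOW",
    "synonymous_variant": "LOW",
}
for _t in IMPACT_TERMS:
    SEVERITY.setdefault(_t, "MODIFIER")

HIGH_IMPACT_TERMS: frozenset[str] = frozenset(
    {
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
    }
)

_SEV_RANK = {"MODIFIER": 0, "LOW": 1, "MODERATE": 2, "HIGH": 3}

NEIGHBORHOOD_LEN = 6
_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_NT = "ACGTN"

# numpy lookup: ASCII byte -> 3-bit code (255 = invalid)
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _NT_CODE.items():
    _BYTE_CODE[ord(_b)] = _c


def encode_neighborhood(seq: str) -> int:
    """Encode a 6-nt string over {A,C,G,T,N} into an 18-bit integer.

    The leftmost nucleotide occupies the most significant 3-bit group.
    """
    if len(seq) != NEIGHBORHOOD_LEN:
        raise PackingError(f"neighborhood must be {NEIGHBORHOOD_LEN} nt, got {len(seq)}")
    value = 0
    for ch in seq:
        try:
            code = _NT_CODE[ch]
        except KeyError:
            raise PackingError(f"invalid nucleotide {ch!r} in neighborhood") from None
        value = (value << 3) | code
    return value


def decode_neighborhood(value: int) -> str:
    """Inverse of :func:`encode_neighborhood`."""
    if not 0 <= value < (1 << 18):
        raise PackingError(f"neighborhood code out of range: {value}")
    out = []
    for shift in range(15, -3, -3):
        code = (value >> shift) & 0b111
        if code > 4:
            raise PackingError(f"invalid 3-bit nucleotide code {code}")
        out.append(_CODE_NT[code])
    return "".join(out)


def bitmap_of(terms) -> int:
    """Build a 38-bit bitmap from an iterable of term strings."""
    bm = 0
    for t in terms:
        bm |= 1 << TERM_INDEX[t]
    return bm


def terms_of(bitmap: int) -> frozenset[str]:
    """Inverse of :func:`bitmap_of`; rejects bits beyond the vocabulary."""
    if bitmap >> N_TERMS:
        raise PackingError(f"bitmap has bits set beyond index {N_TERMS - 1}")
    return frozenset(IMPACT_TERMS[i] for i in range(N_TERMS) if (bitmap >> i) & 1)


def severity_of(terms) -> str:
    """Highest severity class among *terms* (MODIFIER when empty)."""
    best = "MODIFIER"
    for t in terms:
        if _SEV_RANK[SEVERITY[t]] > _SEV_RANK[best]:
            best = SEVERITY[t]
    return best


def pack_impact(frame: int, neighborhood, bitmap: int) -> int:
    """Pack (frame, neighborhood, bitmap) into the 58-bit impact value.

    *neighborhood* may be a 6-nt string or a pre-encoded 18-bit integer.
    """
    if frame not in (0, 1, 2):
        raise PackingError(f"coding frame must be 0, 1 or 2, got {frame}")
    if isinstance(neighborhood, str):
        ncode = encode_neighborhood(neighborhood)
    else:
        ncode = int(neighborhood)
        if not 0 <= ncode < (1 << 18):
            raise PackingError(f"neighborhood code out of range: {ncode}")
    if not 0 <= bitmap < (1 << N_TERMS):
        raise PackingError(f"impact bitmap out of range: {bitmap}")
    return (((bitmap << 18) + ncode) << 2) + frame


def unpack_impact(value: int) -> tuple[int, int, int]:
    """Split a packed impact value into (frame, neighborhood code, bitmap)."""
    value = int(value)
    if not 0 <= value < (1 << 58):
        raise PackingError(f"packed impact value out of range: {value}")
    frame = value & 0b11
    ncode = (value >> 2) & ((1 << 18) - 1)
    bitmap = value >> 20
    return frame, ncode, bitmap
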