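"""Secure annotation pipeline: multiply, decrypt, and translate.

The client encrypts its binary variant loci vector; the server multiplies it
slot-wise with the (public) packed annotation vector; the client decrypts the
product and translates non-zero slots back into per-element annotation
records.  SNV slots translate one-for-one.  Deletions are reconstructed from
runs of 1-bp deletion impacts: the merge counts deleted coding bases for the
frameshift / in-frame call, unions loss terms, and rebuilds the junction
codon from the stored 6-nt neighborhoods and coding frame to detect created
or retained stop codons.  Insertions translate the inserted sequence in frame
at the junction.

Known blind spots of the 1-bp merge (documented, asserted in tests): stop
codons created downstream of the one-codon junction window, and stop codons
formed across spliced exon junctions — the stored neighborhoods are genomic,
not spliced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotator import AnnotationVector, STOP_CODONS
from .gene_model import reverse_complement
from .impact import (
    DEL_ALLELE,
    INS_ALLELE,
    TERM_INDEX,
    decode_neighborhood,
    severity_of,
    terms_of,
    unpack_impact,
)
from .secure import CipherVector, PlainBackend
from .targets import TargetRegionSet
from .variants import VariantSet

__all__ = [
    "AnnotationRecord",
    "ConfigurationError",
    "InconsistencyError",
    "secure_annotate",
    "translate_snv",
    "translate_deletion",
    "translate_insertion",
    "write_report",
    "secure_pipeline",
]


class ConfigurationError(ValueError):
    """Inputs from different target sets were mixed."""


class InconsistencyError(ValueError):
    """Decrypted product disagrees with the client's own variant list."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One translated annotation: a variant's impact on one target element."""

    chrom: str
    start: int
    end: int
    kind: str  # 'snv' | 'del' | 'ins'
    allele: str  # alt base, deleted span "d1-d2", or inserted sequence
    element_id: str
    terms: frozenset[str]
    severity: str

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.kind, self.allele, self.element_id)


def secure_annotate(
    backend: PlainBackend,
    enc_loci: CipherVector,
    ann: AnnotationVector,
    loci_target_hash: str | None = None,
) -> CipherVector:
    """Server step: slot-wise product of the encrypted loci vector and the
    plaintext packed annotation vector.  Slots without a variant decrypt to 0."""
    if loci_target_hash is not None and loci_target_hash != ann.target_hash:
        raise ConfigurationError(
            f"loci vector target hash {loci_target_hash} != annotation {ann.target_hash}"
        )
    if enc_loci.length != len(ann.values):
        raise ConfigurationError("loci vector and annotation vector lengths differ")
    return backend.mul_plain(enc_loci, ann.values.astype(np.int64))


def _record(targets, k, start, end, kind, allele, terms) -> AnnotationRecord:
    r = targets.regions[k]
    return AnnotationRecord(
        chrom=r.chrom,
        start=start,
        end=end,
        kind=kind,
        allele=allele,
        element_id=r.element_id,
        terms=frozenset(terms),
        severity=severity_of(terms),
    )


def translate_snv(
    decrypted: np.ndarray, targets: TargetRegionSet, allele: str
) -> list[AnnotationRecord]:
    """One record per non-zero slot of a decrypted SNV product vector."""
    if len(decrypted) != targets.l_T:
        raise ConfigurationError("decrypted vector length != l_T")
    records = []
    for nu in np.flatnonzero(decrypted) + 1:
        value = int(decrypted[nu - 1])
        _frame, _ncode, bitmap = unpack_impact(value)
        k, _chrom, pos = targets.vector_to_genomic(int(nu))
        records.append(_record(targets, k, pos, pos, "snv", allele, terms_of(bitmap)))
    return records


_FS_BIT = 1 << TERM_INDEX["frameshift_variant"]
_LOSS_BITS = {
    t: 1 << TERM_INDEX[t]
    for t in (
        "start_lost",
        "stop_lost",
        "splice_donor_variant",
        "splice_acceptor_variant",
    )
}


def _region_slots(targets, k, lo, hi):
    """Vector slots (0-based) of genomic [lo, hi] within region k."""
    r = targets.regions[k]
    p_lo, p_hi = max(lo, r.start), min(hi, r.end)
    if p_lo > p_hi:
        return None
    base = int(targets.cum[k]) - r.start  # nu-1 = base + pos
    return p_lo, p_hi, np.arange(base + p_lo, base + p_hi + 1)


def translate_deletion(
    decrypted: np.ndarray, vs: VariantSet, targets: TargetRegionSet
) -> list[AnnotationRecord]:
    """Merge per-base 1-bp deletion impacts into per-deletion annotations.

    The client's own variant list delimits the spans (runs of non-zero slots
    cannot separate adjacent deletions); the decrypted product is used for
    the impact content and as a consistency check.
    """
    if len(decrypted) != targets.l_T:
        raise ConfigurationError("decrypted vector length != l_T")
    records = []
    for d in vs.deletions:
        for k in targets.overlapping_regions_span(d.chrom, d.d1, d.d2):
            r = targets.regions[k]
            span = _region_slots(targets, k, d.d1, d.d2)
            if span is None:
                continue
            p_lo, p_hi, slots = span
            values = decrypted[slots]
            if (values == 0).any():
                raise InconsistencyError(
                    f"deletion {d.chrom}:{d.d1}-{d.d2} has zero-valued slots in "
                    f"region {k} — loci/annotation vectors disagree"
                )
            unpacked = [unpack_impact(int(v)) for v in values]
            union = 0
            for _f, _n, bm in unpacked:
                union |= bm
            coding_flags = [bool(bm & _FS_BIT) for _f, _n, bm in unpacked]
            k_cod = sum(coding_flags)

            terms = set(terms_of(union & ~_FS_BIT & ((1 << 38) - 1)))
            if k_cod:
                terms.add("frameshift_variant" if k_cod % 3 else "inframe_deletion")

            # junction codon reconstruction (transcription order)
            splice_hit = bool(
                union & (_LOSS_BITS["splice_donor_variant"] | _LOSS_BITS["splice_acceptor_variant"])
            )
            start_hit = bool(union & _LOSS_BITS["start_lost"])
            u_i, v_i = (0, len(values) - 1) if r.strand == "+" else (len(values) - 1, 0)
            if k_cod and coding_flags[u_i] and not splice_hit and not start_hit:
                f_u, n_u, _bm_u = unpacked[u_i]
                f_v, n_v, _bm_v = unpacked[v_i]
                nb_u = decode_neighborhood(n_u)
                nb_v = decode_neighborhood(n_v)
                if r.strand == "+":
                    left, right = nb_u[:3], nb_v[3:]
                else:
                    left, right = reverse_complement(nb_u[3:]), reverse_complement(nb_v[:3])
                inframe = k_cod % 3 == 0
                end_aligned = bool(coding_flags[v_i]) and f_v == 2
                junction_is_new = ("stop_lost" in terms) or not (
                    f_u == 0 and end_aligned and inframe
                )
                if junction_is_new:
                    codon = (left[3 - f_u :] if f_u else "") + right[: 3 - f_u]
                    if len(codon) == 3 and codon in STOP_CODONS:
                        terms.add(
                            "stop_retained_variant" if "stop_lost" in terms else "stop_gained"
                        )
            records.append(
                _record(targets, k, p_lo, p_hi, "del", f"{d.d1}-{d.d2}", terms)
            )
    return records


def translate_insertion(
    decrypted: np.ndarray, vs: VariantSet, targets: TargetRegionSet
) -> list[AnnotationRecord]:
    """Translate insertion slots: frame and junction window come from the
    packed value; the inserted sequence comes from the client's variant list."""
    if len(decrypted) != targets.l_T:
        raise ConfigurationError("decrypted vector length != l_T")
    records = []
    for ins in vs.insertions:
        for k in targets.overlapping_regions(ins.chrom, ins.pos):
            r = targets.regions[k]
            span = _region_slots(targets, k, ins.pos, ins.pos)
            if span is None:
                continue
            _p, _p2, slots = span
            value = int(decrypted[slots[0]])
            if value == 0:
                raise InconsistencyError(
                    f"insertion {ins.chrom}:{ins.pos} decrypts to zero in region {k}"
                )
            frame, ncode, bitmap = unpack_impact(value)
            nb = decode_neighborhood(ncode)
            terms = set(terms_of(bitmap))
            coding_ins = "frameshift_variant" in terms
            klen = len(ins.seq)
            if coding_ins:
                terms.discard("frameshift_variant")
                terms.add("frameshift_variant" if klen % 3 else "inframe_insertion")
            splice_hit = bool(
                terms & {"splice_donor_variant", "splice_acceptor_variant"}
            )
            if coding_ins and "start_lost" not in terms and not splice_hit:
                if r.strand == "+":
                    left, right, s_m = nb[:3], nb[3:], ins.seq.upper()
                    r_pref = (frame + 1) % 3
                else:
                    left, right = reverse_complement(nb[3:]), reverse_complement(nb[:3])
                    s_m = reverse_complement(ins.seq.upper())
                    r_pref = frame
                window = left + s_m + right
                start = 3 - r_pref
                while start + 3 <= len(window) and start < 3 + klen:
                    codon = window[start : start + 3]
                    if codon in STOP_CODONS and "N" not in codon:
                        terms.add(
                            "stop_retained_variant" if "stop_lost" in terms else "stop_gained"
                        )
                        break
                    start += 3
            records.append(
                _record(targets, k, ins.pos, ins.pos, "ins", ins.seq.upper(), terms)
            )
    return records


def write_report(records: list[AnnotationRecord], path) -> None:
    """Tab-delimited annotation report, sorted by position."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tallele\telement\tterms\tseverity\n")
        for rec in sorted(records, key=AnnotationRecord.sort_key):
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.start),
                        str(rec.end),
                        rec.kind,
                        rec.allele,
                        rec.element_id,
                        ",".join(sorted(rec.terms)),
                        rec.severity,
                    ]
                )
                + "\n"
            )


def secure_pipeline(
    annotator,
    vs: VariantSet,
    backend: PlainBackend | None = None,
    alleles=("A", "C", "G", "T", DEL_ALLELE, INS_ALLELE),
) -> list[AnnotationRecord]:
    """Full client/server round trip on the mock backend for a variant set.

    Client: vectorize + encrypt loci per allele.  Server: multiply with the
    packed annotation vectors.  Client: decrypt and translate.  Returns all
    records across the requested alleles.
    """
    from .variants import vectorize_loci

    backend = backend or PlainBackend()
    keys = backend.keygen()
    targets = annotator.targets
    records: list[AnnotationRecord] = []
    for allele in alleles:
        loci = vectorize_loci(vs, targets, allele)
        if not loci.bits.any():
            continue
        enc = backend.encrypt(loci.bits.astype(np.int64), keys.public)
        ann = annotator.build_annotation_vector(allele)
        product = secure_annotate(backend, enc, ann, loci.target_hash)
        decrypted = backend.decrypt(product, keys.secret)
        if allele == DEL_ALLELE:
            records.extend(translate_deletion(decrypted, vs, targets))
        elif allele == INS_ALLELE:
            records.extend(translate_insertion(decrypted, vs, targets))
        else:
            records.extend(translate_snv(decrypted, targets, allele))
    return records
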