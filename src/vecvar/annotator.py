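"""Built-in reference annotator for point mutations on the target regions.

Enumerates the consequence of every possible point mutation — the four SNV
alternate alleles, the 1-bp deletion state and the 1-bp insertion state — at
every vector position, and packs the results into per-allele annotation
vectors (one 64-bit packed impact per slot).  It plays two roles:

* the server-side annotation-vector generator of the secure pipeline (a
  stand-in for an external consequence predictor such as VEP), and
* the direct full-variant oracle (:meth:`ReferenceAnnotator.oracle_deletion`,
  :meth:`ReferenceAnnotator.oracle_insertion`) used to validate the 1-bp
  merge translation of arbitrary-length indels.

Consequence semantics
---------------------
Splice acceptor/donor: the 2 intronic bp flanking each internal exon junction.
Splice region: 1-3 exonic or 3-8 intronic bp from a junction.  Coding SNVs are
classified by codon translation on the transcript strand (synonymous /
missense / stop_gained / stop_lost / stop_retained / start_lost); 1-bp coding
deletions and insertions are frameshift by construction.  The stored 6-nt
neighborhood is always in genomic plus-strand orientation: 3 bp each side of
the position for SNV/deletion slots, and the window (p-2..p, p+1..p+3) around
the junction for insertion slots (the insertion applies after position p).
Reference-allele slots and off-transcript slots with no consequence are 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .gene_model import GeneModel, SequenceStore, Transcript
from .impact import (
    ALLELES,
    DEL_ALLELE,
    INS_ALLELE,
    TERM_INDEX,
    pack_impact,
    terms_of,
)
from .targets import CoordinateError, TargetRegionSet

__all__ = ["AnnotationVector", "ReferenceAnnotator", "OracleAnnotation"]

# -- codon tables ---------------------------------------------------------

_STD = CodonTable.unambiguous_dna_by_id[1]
_NTS = "ACGT"
#: amino acid (byte) per codon integer 16*b0+4*b1+b2; stop codons map to b'*'
AA64 = np.zeros(64, dtype=np.uint8)
STOP64 = np.zeros(64, dtype=bool)
for _i in range(64):
    _codon = _NTS[_i >> 4] + _NTS[(_i >> 2) & 3] + _NTS[_i & 3]
    if _codon in _STD.stop_codons:
        AA64[_i] = ord("*")
        STOP64[_i] = True
    else:
        AA64[_i] = ord(_STD.forward_table[_codon])

STOP_CODONS = tuple(_STD.stop_codons)  # ("TAA", "TAG", "TGA")

# -- impact bit masks -----------------------------------------------------

_B = {t: np.uint64(1 << i) for t, i in TERM_INDEX.items()}
_MULT = np.array([16, 4, 1], dtype=np.int64)  # codon base multiplier by offset

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _chrom_codes(seq: SequenceStore, chrom: str) -> np.ndarray:
    s = seq.substring(chrom, 1, seq.length(chrom))
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.uint8)
    for b, c in _CODE.items():
        table[ord(b)] = c
    return table[codes]


class TranscriptIndex:
    """Per-transcript lookup tables used by all consequence calls."""

    def __init__(self, t: Transcript, chrom_codes: np.ndarray):
        self.t = t
        self.strand = t.strand
        self.span = t.span
        self.codes = chrom_codes

        segs = t.cds
        self.seg_s = np.array([s.start for s in segs], dtype=np.int64)
        self.seg_e = np.array([s.end for s in segs], dtype=np.int64)
        lens = self.seg_e - self.seg_s + 1
        self.cum_before = np.concatenate([[0], np.cumsum(lens)])[:-1]
        self.L = int(lens.sum()) if len(segs) else 0
        self.complete = self.L % 3 == 0 and self.L >= 6

        gpos = (
            np.concatenate([np.arange(s, e + 1) for s, e in zip(self.seg_s, self.seg_e)])
            if self.L
            else np.empty(0, dtype=np.int64)
        )
        if self.strand == "-":
            gpos = gpos[::-1]
        self.gpos_trans = gpos  # genomic position of coding index 0..L-1

        codes = chrom_codes[gpos - 1].astype(np.int64) if self.L else np.empty(0, np.int64)
        if self.strand == "-":
            codes = np.where(codes < 4, 3 - codes, codes)
        self.mrna_codes = codes
        self.mrna = "".join("ACGTN"[c] for c in codes)

        n_cod = self.L // 3
        self.n_codons = n_cod
        if n_cod:
            c = codes[: n_cod * 3].reshape(n_cod, 3)
            valid = (c < 4).all(axis=1)
            self.codon_int = np.where(valid, c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2], -1)
        else:
            self.codon_int = np.empty(0, dtype=np.int64)

        self.exon_s = np.array([s for s, _ in t.exons], dtype=np.int64)
        self.exon_e = np.array([e for _, e in t.exons], dtype=np.int64)

        donor, acceptor, sregion = [], [], []
        for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
            ilo, ihi = e1 + 1, s2 - 1
            left2 = range(ilo, min(ilo + 2, ihi + 1))
            right2 = range(max(ihi - 1, ilo), ihi + 1)
            if t.strand == "+":
                donor += list(left2)
                acceptor += list(right2)
            else:
                acceptor += list(left2)
                donor += list(right2)
            # splice region: 1-3 exonic and 3-8 intronic bases from each junction
            sregion += list(range(max(s1, e1 - 2), e1 + 1))
            sregion += list(range(s2, min(s2 + 3, e2 + 1)))
            sregion += list(range(min(ilo + 2, ihi + 1), min(ilo + 8, ihi + 1)))
            sregion += list(range(max(ihi - 7, ilo), max(ihi - 1, ilo)))
        self.donor = np.unique(np.array(donor, dtype=np.int64))
        self.acceptor = np.unique(np.array(acceptor, dtype=np.int64))
        self.splice_region = np.unique(np.array(sregion, dtype=np.int64))

        if self.L:
            self.cds_glo = int(self.seg_s[0])
            self.cds_ghi = int(self.seg_e[-1])
        else:
            self.cds_glo = self.cds_ghi = 0

    # -- per-position primitives -----------------------------------------
    def trans_idx(self, pos: np.ndarray) -> np.ndarray:
        """Translation-order coding index of genomic positions (-1 if non-coding)."""
        pos = np.asarray(pos, dtype=np.int64)
        if not len(self.seg_s):
            return np.full(pos.shape, -1, dtype=np.int64)
        k = np.searchsorted(self.seg_s, pos, side="right") - 1
        kc = np.clip(k, 0, len(self.seg_s) - 1)
        inside = (k >= 0) & (pos <= self.seg_e[kc])
        fwd = self.cum_before[kc] + (pos - self.seg_s[kc])
        tidx = fwd if self.strand == "+" else self.L - 1 - fwd
        return np.where(inside, tidx, -1)

    def in_exon(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        k = np.searchsorted(self.exon_s, pos, side="right") - 1
        kc = np.clip(k, 0, len(self.exon_s) - 1)
        return (k >= 0) & (pos <= self.exon_e[kc])

    def downstream_seq(self, gstart: int, n: int) -> str:
        """Next *n* mRNA-sense bases from genomic *gstart* in transcription
        direction, splicing out introns; runs into raw genomic sequence past
        the transcript end.  Used to rebuild post-variant coding sequence."""
        step = 1 if self.strand == "+" else -1
        span_lo, span_hi = self.span
        out: list[str] = []
        pos = gstart
        while len(out) < n and 1 <= pos <= len(self.codes):
            exonic = bool(self.in_exon(np.array([pos]))[0])
            intronic = (span_lo <= pos <= span_hi) and not exonic
            if not intronic:
                c = int(self.codes[pos - 1])
                if self.strand == "-" and c < 4:
                    c = 3 - c
                out.append("ACGTN"[c])
            pos += step
        return "".join(out)

    def classify(self, pos: np.ndarray) -> dict[str, np.ndarray]:
        """Structural classification of genomic positions for this transcript."""
        pos = np.asarray(pos, dtype=np.int64)
        tidx = self.trans_idx(pos)
        coding = tidx >= 0
        cid = np.where(coding, tidx // 3, -1)
        off = np.where(coding, tidx % 3, 0)
        is_start = coding & (cid == 0) if self.complete else np.zeros_like(coding)
        is_stop = (
            coding & (cid == self.n_codons - 1) if self.complete else np.zeros_like(coding)
        )
        exonic = self.in_exon(pos)
        span_lo, span_hi = self.span
        in_span = (pos >= span_lo) & (pos <= span_hi)
        intronic = in_span & ~exonic
        utr = exonic & ~coding
        if self.L:
            before_cds = pos < self.cds_glo
            after_cds = pos > self.cds_ghi
        else:
            before_cds = after_cds = np.zeros_like(exonic)
        if self.strand == "+":
            utr5, utr3 = utr & before_cds, utr & after_cds
            upstream, downstream = pos < span_lo, pos > span_hi
        else:
            utr5, utr3 = utr & after_cds, utr & before_cds
            upstream, downstream = pos > span_hi, pos < span_lo
        return {
            "tidx": tidx,
            "coding": coding,
            "codon_id": cid,
            "offset": off,
            "is_start": is_start,
            "is_stop": is_stop,
            "exonic": exonic,
            "intronic": intronic,
            "utr5": utr5,
            "utr3": utr3,
            "upstream": upstream,
            "downstream": downstream,
            "donor": np.isin(pos, self.donor),
            "acceptor": np.isin(pos, self.acceptor),
            "splice_region": np.isin(pos, self.splice_region),
        }


@dataclass
class AnnotationVector:
    """Packed impact values for one allele over a stitched target set."""

    allele: str
    values: np.ndarray  # uint64, length l_T
    targets: TargetRegionSet = field(repr=False)
    target_hash: str = ""

    def __post_init__(self):
        if self.allele not in ALLELES:
            raise ValueError(f"unknown allele {self.allele!r}")
        if len(self.values) != self.targets.l_T:
            raise ValueError("annotation vector length != l_T")
        if not self.target_hash:
            self.target_hash = self.targets.content_hash()


@dataclass(frozen=True)
class OracleAnnotation:
    """Direct (full-variant) consequence call for one variant on one region.

    ``stop_offset`` reports where a created/retained stop codon was found:
    0 = inside the junction/inserted-codon window that the 1-bp merge
    translation can also see, >0 = that many codons further downstream (a
    documented blind spot of the merge translation).  ``flank_contiguous`` is
    False when the one-codon junction flank crosses an exon boundary, i.e. the
    genomic neighborhood differs from the spliced mRNA neighborhood (the other
    documented blind spot).
    """

    terms: frozenset[str]
    coding_count: int = 0
    stop_offset: int | None = None
    flank_contiguous: bool = True


def _noncoding_bits(cls) -> np.ndarray:
    bits = np.zeros(len(cls["coding"]), dtype=np.uint64)
    bits |= np.where(cls["intronic"], _B["intron_variant"], np.uint64(0))
    bits |= np.where(cls["utr5"], _B["5_prime_UTR_variant"], np.uint64(0))
    bits |= np.where(cls["utr3"], _B["3_prime_UTR_variant"], np.uint64(0))
    bits |= np.where(cls["upstream"], _B["upstream_gene_variant"], np.uint64(0))
    bits |= np.where(cls["downstream"], _B["downstream_gene_variant"], np.uint64(0))
    bits |= np.where(cls["donor"], _B["splice_donor_variant"], np.uint64(0))
    bits |= np.where(cls["acceptor"], _B["splice_acceptor_variant"], np.uint64(0))
    bits |= np.where(cls["splice_region"], _B["splice_region_variant"], np.uint64(0))
    return bits


class ReferenceAnnotator:
    """Consequence calls for every point mutation on a target set."""

    def __init__(self, model: GeneModel, seq: SequenceStore, targets: TargetRegionSet):
        self.model = model
        self.seq = seq
        self.targets = targets
        self._codes: dict[str, np.ndarray] = {}
        self._tindex: dict[str, TranscriptIndex] = {}
        self._region_cache: dict[int, dict] = {}

    # -- caches -----------------------------------------------------------
    def chrom_codes(self, chrom: str) -> np.ndarray:
        if chrom not in self._codes:
            self._codes[chrom] = _chrom_codes(self.seq, chrom)
        return self._codes[chrom]

    def tindex(self, tid: str) -> TranscriptIndex:
        if tid not in self._tindex:
            t = self.model.transcript(tid)
            self._tindex[tid] = TranscriptIndex(t, self.chrom_codes(t.chrom))
        return self._tindex[tid]

    def _code_at(self, chrom: str, pos: np.ndarray, offset: int) -> np.ndarray:
        """3-bit base code at pos+offset, 'N' (4) outside the chromosome."""
        codes = self.chrom_codes(chrom)
        p = np.asarray(pos, dtype=np.int64) + offset - 1
        out = np.full(p.shape, 4, dtype=np.int64)
        ok = (p >= 0) & (p < len(codes))
        out[ok] = codes[p[ok]]
        return out

    def _region_tables(self, k: int) -> dict:
        if k in self._region_cache:
            return self._region_cache[k]
        r = self.targets.regions[k]
        idx = self.tindex(r.transcript_id)
        pos = np.arange(r.start, r.end + 1, dtype=np.int64)
        cls = idx.classify(pos)
        ref = self._code_at(r.chrom, pos, 0)

        def neigh(offsets):
            n = np.zeros(len(pos), dtype=np.int64)
            for o in offsets:
                n = (n << 3) | self._code_at(r.chrom, pos, o)
            return n

        tbl = {
            "region": r,
            "idx": idx,
            "pos": pos,
            "cls": cls,
            "ref": ref,
            "neigh_point": neigh((-3, -2, -1, 1, 2, 3)).astype(np.uint64),
            "neigh_ins": neigh((-2, -1, 0, 1, 2, 3)).astype(np.uint64),
            "base_bits": _noncoding_bits(cls),
        }
        self._region_cache[k] = tbl
        return tbl

    # -- per-region packed values ----------------------------------------
    def _region_values(self, k: int, allele: str) -> np.ndarray:
        tbl = self._region_tables(k)
        cls, idx, r = tbl["cls"], tbl["idx"], tbl["region"]
        n = len(tbl["pos"])
        frame = cls["offset"].astype(np.uint64)

        if allele in "ACGT":
            bits = tbl["base_bits"].copy()
            x = _CODE[allele]
            xm = x if r.strand == "+" else 3 - x  # allele on the mRNA strand
            coding = cls["coding"] & (cls["codon_id"] < idx.n_codons)
            cid = np.clip(cls["codon_id"], 0, max(idx.n_codons - 1, 0))
            cint = idx.codon_int[cid] if idx.n_codons else np.full(n, -1)
            known = coding & (cint >= 0)
            mult = _MULT[cls["offset"]]
            old = (np.where(cint >= 0, cint, 0) // mult) % 4
            new = np.where(cint >= 0, cint, 0) + (xm - old) * mult
            new = np.clip(new, 0, 63)
            same_aa = AA64[np.clip(cint, 0, 63)] == AA64[new]
            new_stop = STOP64[new]
            cbits = np.zeros(n, dtype=np.uint64)
            start, stop = cls["is_start"], cls["is_stop"]
            mid = known & ~start & ~stop
            cbits |= np.where(known & start, _B["start_lost"], np.uint64(0))
            cbits |= np.where(known & stop & new_stop, _B["stop_retained_variant"], np.uint64(0))
            cbits |= np.where(known & stop & ~new_stop, _B["stop_lost"], np.uint64(0))
            cbits |= np.where(mid & new_stop, _B["stop_gained"], np.uint64(0))
            cbits |= np.where(mid & ~new_stop & same_aa, _B["synonymous_variant"], np.uint64(0))
            cbits |= np.where(mid & ~new_stop & ~same_aa, _B["missense_variant"], np.uint64(0))
            cbits |= np.where(
                coding & (cint < 0), _B["coding_sequence_variant"], np.uint64(0)
            )
            cbits |= np.where(
                coding & cls["splice_region"], _B["splice_region_variant"], np.uint64(0)
            )
            bits = np.where(coding, cbits, bits)
            valid = (tbl["ref"] != x) & (tbl["ref"] != 4) & (bits != 0)
            packed = (((bits << np.uint64(18)) | tbl["neigh_point"]) << np.uint64(2)) | frame
            return np.where(valid, packed, np.uint64(0))

        if allele == DEL_ALLELE:
            bits = tbl["base_bits"].copy()
            coding = cls["coding"]
            cbits = np.where(coding, _B["frameshift_variant"], np.uint64(0))
            cbits |= np.where(cls["is_start"], _B["start_lost"], np.uint64(0))
            cbits |= np.where(cls["is_stop"], _B["stop_lost"], np.uint64(0))
            cbits |= np.where(
                coding & cls["splice_region"], _B["splice_region_variant"], np.uint64(0)
            )
            bits = np.where(coding, cbits, bits)
            packed = (((bits << np.uint64(18)) | tbl["neigh_point"]) << np.uint64(2)) | frame
            return np.where(bits != 0, packed, np.uint64(0))

        if allele == INS_ALLELE:
            pos = tbl["pos"]
            cls1 = idx.classify(pos + 1)
            t0, t1 = cls["tidx"], cls1["tidx"]
            coding_ins = (t0 >= 0) & (t1 >= 0) & (np.abs(t1 - t0) == 1)
            same_codon = coding_ins & (cls["codon_id"] == cls1["codon_id"])
            bits = np.where(coding_ins, _B["frameshift_variant"], np.uint64(0))
            bits |= np.where(same_codon & cls["is_start"], _B["start_lost"], np.uint64(0))
            bits |= np.where(same_codon & cls["is_stop"], _B["stop_lost"], np.uint64(0))
            # splice motif split: insertion strictly between the 2 motif bases
            bits |= np.where(
                cls["donor"] & cls1["donor"], _B["splice_donor_variant"], np.uint64(0)
            )
            bits |= np.where(
                cls["acceptor"] & cls1["acceptor"], _B["splice_acceptor_variant"], np.uint64(0)
            )
            bits |= np.where(
                cls["splice_region"] | cls1["splice_region"],
                _B["splice_region_variant"],
                np.uint64(0),
            )
            motif_bits = (
                _B["splice_donor_variant"]
                | _B["splice_acceptor_variant"]
                | _B["splice_region_variant"]
            )
            nc0 = _noncoding_bits(cls) & ~motif_bits
            nc1 = _noncoding_bits(cls1) & ~motif_bits
            # junction context: fall back to the base after the junction when
            # the base before it is coding (e.g. insertion after a stop codon)
            nc = np.where(nc0 != 0, nc0, nc1)
            bits |= np.where(~coding_ins, nc, np.uint64(0))
            packed = (((bits << np.uint64(18)) | tbl["neigh_ins"]) << np.uint64(2)) | frame
            return np.where(bits != 0, packed, np.uint64(0))

        raise ValueError(f"unknown allele {allele!r}")

    # -- public API -------------------------------------------------------
    def annotate_point_mutation(self, nu: int, allele: str) -> tuple[int, str, int]:
        """(frame, 6-nt neighborhood, impact bitmap) for allele at vector position nu."""
        if allele not in ALLELES:
            raise ValueError(f"unknown allele {allele!r}")
        if not 1 <= nu <= self.targets.l_T:
            raise CoordinateError(f"vector coordinate {nu} outside [1, {self.targets.l_T}]")
        k = self.targets.region_index(nu)
        off = nu - int(self.targets.cum[k]) - 1
        value = int(self._region_values(k, allele)[off])
        from .impact import decode_neighborhood, unpack_impact

        if value == 0:
            tbl = self._region_tables(k)
            key = "neigh_ins" if allele == INS_ALLELE else "neigh_point"
            return 0, decode_neighborhood(int(tbl[key][off])), 0
        frame, ncode, bitmap = unpack_impact(value)
        return frame, decode_neighborhood(ncode), bitmap

    def build_annotation_vector(self, allele: str) -> AnnotationVector:
        """Packed annotation vector for one allele over the whole target set."""
        if allele not in ALLELES:
            raise ValueError(f"unknown allele {allele!r}")
        values = np.zeros(self.targets.l_T, dtype=np.uint64)
        for k in range(len(self.targets.regions)):
            lo, hi = self.targets.region_vector_range(k)
            values[lo - 1 : hi] = self._region_values(k, allele)
        return AnnotationVector(allele=allele, values=values, targets=self.targets)

    # -- full-variant oracle ----------------------------------------------
    def oracle_snv(self, region_k: int, pos: int, alt: str) -> OracleAnnotation:
        """Direct SNV call on one region (same semantics as the point vector)."""
        r = self.targets.regions[region_k]
        nus = [
            nu
            for nu in self.targets.genomic_to_vector(r.chrom, pos)
            if self.targets.region_index(nu) == region_k
        ]
        if not nus:
            raise CoordinateError(f"position {pos} not in region {region_k}")
        _f, _n, bitmap = self.annotate_point_mutation(nus[0], alt)
        return OracleAnnotation(terms=terms_of(bitmap))

    def _flank_match(
        self, idx: TranscriptIndex, chrom: str, g1: int, g2: int, mrna_left: str, spliced_right: str
    ) -> bool:
        """True when the raw genomic 3-bp flanks of [g1, g2] equal the spliced
        mRNA flanks — i.e. no exon boundary falls inside the one-codon window,
        so a genomic-neighborhood junction reconstruction is exact."""
        from .gene_model import reverse_complement

        if idx.strand == "+":
            raw_left = self.seq.substring(chrom, g1 - 3, g1 - 1)
            raw_right = self.seq.substring(chrom, g2 + 1, g2 + 3)
        else:
            raw_left = reverse_complement(self.seq.substring(chrom, g2 + 1, g2 + 3))
            raw_right = reverse_complement(self.seq.substring(chrom, g1 - 3, g1 - 1))
        left_ok = (not mrna_left) or raw_left.endswith(mrna_left[-3:])
        right = spliced_right[:3]
        right_ok = (not right) or raw_right.startswith(right)
        return left_ok and right_ok

    def oracle_deletion(self, region_k: int, d1: int, d2: int) -> OracleAnnotation:
        """Direct consequence call for deleting genomic span [d1, d2] (inclusive)
        against the transcript backing region *region_k*.

        Rebuilds the spliced coding sequence with the deletion applied and
        scans it for created/retained stop codons; the scan is skipped when
        the deletion ablates a splice site or the start codon (downstream
        frame undefined).
        """
        r = self.targets.regions[region_k]
        idx = self.tindex(r.transcript_id)
        pos = np.arange(d1, d2 + 1, dtype=np.int64)
        cls = idx.classify(pos)

        terms: set[str] = set()
        k_cod = int(cls["coding"].sum())
        if k_cod:
            terms.add("frameshift_variant" if k_cod % 3 else "inframe_deletion")
        if cls["is_start"].any():
            terms.add("start_lost")
        if cls["is_stop"].any():
            terms.add("stop_lost")
        if cls["donor"].any():
            terms.add("splice_donor_variant")
        if cls["acceptor"].any():
            terms.add("splice_acceptor_variant")
        if cls["splice_region"].any():
            terms.add("splice_region_variant")
        if cls["intronic"].any():
            terms.add("intron_variant")
        if cls["utr5"].any():
            terms.add("5_prime_UTR_variant")
        if cls["utr3"].any():
            terms.add("3_prime_UTR_variant")

        stop_offset = None
        contiguous = True
        splice_hit = bool(cls["donor"].any() or cls["acceptor"].any())
        if k_cod and not splice_hit and "start_lost" not in terms and idx.complete:
            tidx = cls["tidx"][cls["coding"]]
            t_lo, t_hi = int(tidx.min()), int(tidx.max())
            g_after = d2 + 1 if idx.strand == "+" else d1 - 1
            # only stop-loss compensation needs a long downstream trace
            tail_n = (idx.L - t_lo) + 33 if "stop_lost" in terms else 6
            tail = idx.downstream_seq(g_after, tail_n)
            contiguous = self._flank_match(
                idx, r.chrom, d1, d2, idx.mrna[max(t_lo - 3, 0) : t_lo], tail
            )
            new_cds = idx.mrna[:t_lo] + tail
            jc = t_lo // 3
            inframe = k_cod % 3 == 0
            junction_is_new = (t_lo % 3 != 0) or ((t_hi + 1) % 3 != 0)
            # Only the newly-formed junction codon is checked for a created
            # stop; downstream codons are traced solely to find the
            # compensating stop after a stop-loss (mirroring how external
            # annotators report these classes).
            last = jc if "stop_lost" not in terms else len(new_cds) // 3 - 1
            for m in range(jc, last + 1):
                codon = new_cds[3 * m : 3 * m + 3]
                if len(codon) < 3 or "N" in codon:
                    continue
                if m == jc and not junction_is_new and "stop_lost" not in terms:
                    continue
                if codon in STOP_CODONS:
                    stop_offset = m - jc
                    terms.add("stop_retained_variant" if "stop_lost" in terms else "stop_gained")
                    break
        return OracleAnnotation(
            terms=frozenset(terms),
            coding_count=k_cod,
            stop_offset=stop_offset,
            flank_contiguous=contiguous,
        )

    def oracle_insertion(self, region_k: int, pos: int, inserted: str) -> OracleAnnotation:
        """Direct consequence call for inserting *inserted* after genomic *pos*."""
        from .gene_model import reverse_complement

        r = self.targets.regions[region_k]
        idx = self.tindex(r.transcript_id)
        p = np.array([pos, pos + 1], dtype=np.int64)
        cls = idx.classify(p)
        t0, t1 = int(cls["tidx"][0]), int(cls["tidx"][1])
        coding_ins = t0 >= 0 and t1 >= 0 and abs(t1 - t0) == 1
        same_codon = coding_ins and cls["codon_id"][0] == cls["codon_id"][1]

        terms: set[str] = set()
        k = len(inserted)
        if coding_ins:
            terms.add("frameshift_variant" if k % 3 else "inframe_insertion")
            if same_codon and cls["is_start"][0]:
                terms.add("start_lost")
            if same_codon and cls["is_stop"][0]:
                terms.add("stop_lost")
        if cls["donor"][0] and cls["donor"][1]:
            terms.add("splice_donor_variant")
        if cls["acceptor"][0] and cls["acceptor"][1]:
            terms.add("splice_acceptor_variant")
        if cls["splice_region"].any():
            terms.add("splice_region_variant")
        if not coding_ins:
            j = 0 if not cls["coding"][0] else 1
            if cls["intronic"][j]:
                terms.add("intron_variant")
            if cls["utr5"][j]:
                terms.add("5_prime_UTR_variant")
            if cls["utr3"][j]:
                terms.add("3_prime_UTR_variant")

        stop_offset = None
        contiguous = True
        if coding_ins and "start_lost" not in terms and idx.complete:
            i_ins = min(t0, t1) + 1
            right = idx.mrna[i_ins:]
            if len(right) < (idx.L - i_ins) + 33:
                g_after = int(idx.gpos_trans[idx.L - 1]) + (1 if idx.strand == "+" else -1)
                right = right + idx.downstream_seq(g_after, 33)
            contiguous = self._flank_match(
                idx, r.chrom, pos + 1, pos, idx.mrna[max(i_ins - 3, 0) : i_ins], right
            )
            s_mrna = inserted.upper() if r.strand == "+" else reverse_complement(inserted.upper())
            new_cds = idx.mrna[:i_ins] + s_mrna + right
            jc = i_ins // 3
            window_last = (i_ins + k - 1) // 3  # last codon containing an inserted base
            last = window_last if "stop_lost" not in terms else len(new_cds) // 3 - 1
            for m in range(jc, last + 1):
                codon = new_cds[3 * m : 3 * m + 3]
                if len(codon) < 3 or "N" in codon:
                    continue
                if codon in STOP_CODONS:
                    stop_offset = max(0, m - window_last)
                    terms.add(
                        "stop_retained_variant" if "stop_lost" in terms else "stop_gained"
                    )
                    break
        return OracleAnnotation(
            terms=frozenset(terms),
            coding_count=k if coding_ins else 0,
            stop_offset=stop_offset,
            flank_contiguous=contiguous,
        )
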