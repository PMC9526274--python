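"""Secure annotation round trip and 1-bp indel merge translation."""

import numpy as np
import pytest

from vecvar.impact import DEL_ALLELE, HIGH_IMPACT_TERMS, INS_ALLELE
from vecvar.secure import PlainBackend
from vecvar.simulate import SimulationConfig, simulate_variants
from vecvar.translate import (
    ConfigurationError,
    InconsistencyError,
    secure_annotate,
    secure_pipeline,
    translate_deletion,
    translate_insertion,
    translate_snv,
)
from vecvar.variants import Deletion, Insertion, SNV, VariantSet, vectorize_loci


def _decrypted_product(annr, vs, allele):
    """Run the mock-encrypted multiply for one allele and return the plaintext."""
    be = PlainBackend()
    kp = be.keygen()
    targets = annr.targets
    loci = vectorize_loci(vs, targets, allele)
    enc = be.encrypt(loci.bits.astype(np.int64), kp.public)
    product = secure_annotate(be, enc, annr.build_annotation_vector(allele), loci.target_hash)
    return be.decrypt(product, kp.secret)


class TestSecureAnnotate:
    def test_zero_loci_gives_zero_product(self, toy):
        _seq, _model, _targets, annr = toy
        dec = _decrypted_product(annr, VariantSet(), "A")
        assert not dec.any()

    def test_single_bit_picks_single_slot(self, toy):
        _seq, _model, targets, annr = toy
        vs = VariantSet(snvs=[SNV("chrT", 117, "A")])
        dec = _decrypted_product(annr, vs, "A")
        nz = np.flatnonzero(dec) + 1
        ann = annr.build_annotation_vector("A")
        assert list(nz) == targets.genomic_to_vector("chrT", 117)
        assert all(dec[nu - 1] == int(ann.values[nu - 1]) for nu in nz)

    def test_product_equals_plaintext_mask(self, sim_small):
        cfg, seq, _model, targets, annr = sim_small
        vs = simulate_variants(targets, seq, SimulationConfig(seed=31, mutation_rate=0.05),
                               kind="snv", seed=31)
        for allele in "AG":
            dec = _decrypted_product(annr, vs, allele)
            loci = vectorize_loci(vs, targets, allele)
            ann = annr.build_annotation_vector(allele)
            assert (dec == loci.bits.astype(np.int64) * ann.values.astype(np.int64)).all()

    def test_target_hash_mismatch_refused(self, toy):
        _seq, _model, targets, annr = toy
        be = PlainBackend()
        kp = be.keygen()
        enc = be.encrypt(np.zeros(targets.l_T, dtype=np.int64), kp.public)
        with pytest.raises(ConfigurationError):
            secure_annotate(be, enc, annr.build_annotation_vector("A"), "deadbeef")


class TestTranslateSnv:
    def test_zero_vector_empty_report(self, toy):
        _seq, _model, targets, _annr = toy
        assert translate_snv(np.zeros(targets.l_T, dtype=np.int64), targets, "A") == []

    def test_record_positions_match_coordinate_map(self, toy):
        _seq, _model, targets, annr = toy
        vs = VariantSet(snvs=[SNV("chrT", 117, "A"), SNV("chrT", 246, "T")])
        recs = translate_snv(_decrypted_product(annr, vs, "A"), targets, "A")
        assert {r.start for r in recs} == {117}
        recs_t = translate_snv(_decrypted_product(annr, vs, "T"), targets, "T")
        assert {(r.start, r.severity) for r in recs_t} == {(246, "HIGH")}
        assert recs_t[0].terms == frozenset({"stop_gained"})


class TestTranslateDeletion:
    def _merge(self, toy, d1, d2):
        _seq, _model, targets, annr = toy
        vs = VariantSet(deletions=[Deletion("chrT", d1, d2)])
        dec = _decrypted_product(annr, vs, DEL_ALLELE)
        recs = translate_deletion(dec, vs, targets)
        assert len(recs) == 1
        return recs[0]

    def test_full_codon_deletion_is_inframe(self, toy):
        rec = self._merge(toy, 117, 119)
        assert "inframe_deletion" in rec.terms
        assert "frameshift_variant" not in rec.terms
        assert not (rec.terms & {"stop_gained", "stop_lost"})

    def test_two_bp_deletion_is_frameshift(self, toy):
        rec = self._merge(toy, 117, 118)
        assert "frameshift_variant" in rec.terms

    def test_stop_engulfing_deletion_retains_stop(self, toy):
        # deleting the stop codon 249-251 re-forms TAA from the 3'UTR
        rec = self._merge(toy, 249, 251)
        assert {"stop_lost", "stop_retained_variant", "inframe_deletion"} <= rec.terms

    def test_partial_stop_deletion_keeps_frameshift(self, toy):
        # 2-bp deletion of the stop codon's last base + first UTR base:
        # junction codon TG|A re-forms TGA
        rec = self._merge(toy, 251, 252)
        assert {"stop_lost", "frameshift_variant", "stop_retained_variant"} <= rec.terms

    def test_splice_site_deletion_reports_donor_loss(self, toy):
        rec = self._merge(toy, 131, 134)
        assert {"splice_donor_variant", "frameshift_variant"} <= rec.terms

    def test_matches_full_variant_oracle_on_toy(self, toy):
        _seq, _model, targets, annr = toy
        for d1, d2 in [(117, 119), (117, 118), (249, 251), (251, 252), (111, 113), (240, 248)]:
            vs = VariantSet(deletions=[Deletion("chrT", d1, d2)])
            rec = translate_deletion(_decrypted_product(annr, vs, DEL_ALLELE), vs, targets)[0]
            k = targets.overlapping_regions_span("chrT", d1, d2)[0]
            oracle = annr.oracle_deletion(k, d1, d2)
            assert rec.terms & HIGH_IMPACT_TERMS == oracle.terms & HIGH_IMPACT_TERMS, (d1, d2)

    def test_inconsistent_product_detected(self, toy):
        _seq, _model, targets, _annr = toy
        vs = VariantSet(deletions=[Deletion("chrT", 117, 119)])
        with pytest.raises(InconsistencyError):
            translate_deletion(np.zeros(targets.l_T, dtype=np.int64), vs, targets)


class TestTranslateInsertion:
    def _merge(self, toy, pos, seq_ins):
        _seq, _model, targets, annr = toy
        vs = VariantSet(insertions=[Insertion("chrT", pos, seq_ins)])
        dec = _decrypted_product(annr, vs, INS_ALLELE)
        recs = translate_insertion(dec, vs, targets)
        assert len(recs) == 1
        return recs[0]

    def test_codon_aligned_triplet_is_inframe(self, toy):
        rec = self._merge(toy, 119, "AAA")
        assert "inframe_insertion" in rec.terms
        assert "stop_gained" not in rec.terms

    def test_two_bp_insertion_is_frameshift(self, toy):
        assert "frameshift_variant" in self._merge(toy, 119, "AT").terms

    def test_inserted_stop_codon_detected(self, toy):
        rec = self._merge(toy, 119, "TAA")
        assert {"inframe_insertion", "stop_gained"} <= rec.terms

    def test_mid_codon_insertion_frame_arithmetic(self, toy):
        # after 118 (codon offset 1): junction codon = CC + first inserted base
        rec = self._merge(toy, 118, "ATAA")
        assert "frameshift_variant" in rec.terms

    def test_matches_full_variant_oracle_on_toy(self, toy):
        _seq, _model, targets, annr = toy
        cases = [(119, "AAA"), (119, "TAA"), (119, "AT"), (118, "ATAA"), (138, "GG"), (105, "CCC")]
        for pos, s in cases:
            vs = VariantSet(insertions=[Insertion("chrT", pos, s)])
            rec = translate_insertion(_decrypted_product(annr, vs, INS_ALLELE), vs, targets)[0]
            k = targets.overlapping_regions("chrT", pos)[0]
            oracle = annr.oracle_insertion(k, pos, s)
            assert rec.terms & HIGH_IMPACT_TERMS == oracle.terms & HIGH_IMPACT_TERMS, (pos, s)


class TestPipelineEquivalence:
    def test_snv_pipeline_equals_direct_annotation(self, sim_small):
        from vecvar.impact import terms_of

        cfg, seq, _model, targets, annr = sim_small
        vs = simulate_variants(targets, seq, SimulationConfig(seed=41, mutation_rate=0.1),
                               kind="snv", seed=41)
        recs = secure_pipeline(annr, vs, alleles=("A", "C", "G", "T"))
        direct = []
        for v in vs.snvs:
            for nu in targets.genomic_to_vector(v.chrom, v.pos):
                _f, _n, bm = annr.annotate_point_mutation(nu, v.alt)
                if bm:
                    k, _c, pos = targets.vector_to_genomic(nu)
                    direct.append((v.chrom, pos, v.alt, targets.regions[k].element_id,
                                   frozenset(terms_of(bm))))
        got = sorted((r.chrom, r.start, r.allele, r.element_id, r.terms) for r in recs)
        assert got == sorted(direct)

    def test_indel_merge_agrees_with_oracle_outside_known_classes(self, sim_small):
        cfg, seq, _model, targets, annr = sim_small
        for kind, allele in (("del", DEL_ALLELE), ("ins", INS_ALLELE)):
            vs = simulate_variants(targets, seq, SimulationConfig(seed=43, mutation_rate=0.05),
                                   kind=kind, seed=43)
            recs = secure_pipeline(annr, vs, alleles=(allele,))
            merged = {(r.chrom, r.allele, r.element_id, r.start): r.terms for r in recs}
            checked = 0
            for v in vs.deletions or vs.insertions:
                if kind == "del":
                    ks = targets.overlapping_regions_span(v.chrom, v.d1, v.d2)
                else:
                    ks = targets.overlapping_regions(v.chrom, v.pos)
                for k in ks:
                    r = targets.regions[k]
                    if kind == "del":
                        o = annr.oracle_deletion(k, v.d1, v.d2)
                        key = (v.chrom, f"{v.d1}-{v.d2}", r.element_id, max(v.d1, r.start))
                    else:
                        o = annr.oracle_insertion(k, v.pos, v.seq)
                        key = (v.chrom, v.seq, r.element_id, v.pos)
                    if key not in merged:
                        continue
                    checked += 1
                    if merged[key] & HIGH_IMPACT_TERMS != o.terms & HIGH_IMPACT_TERMS:
                        # only the two documented blind spots may diverge
                        assert (o.stop_offset or 0) > 0 or not o.flank_contiguous, (v, k)
            assert checked > 100

    def test_deletion_superset_keeps_loss_terms(self, toy):
        """A deletion covering a splice/stop site never loses the loss term
        relative to a sub-deletion that also covers it."""
        _seq, _model, targets, annr = toy
        vs_small = VariantSet(deletions=[Deletion("chrT", 250, 251)])
        vs_big = VariantSet(deletions=[Deletion("chrT", 246, 253)])
        small = translate_deletion(_decrypted_product(annr, vs_small, DEL_ALLELE), vs_small, targets)[0]
        big = translate_deletion(_decrypted_product(annr, vs_big, DEL_ALLELE), vs_big, targets)[0]
        loss = {"stop_lost", "start_lost", "splice_donor_variant", "splice_acceptor_variant"}
        assert small.terms & loss <= big.terms & loss
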