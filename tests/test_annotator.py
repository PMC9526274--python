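"""Point-mutation consequence calls and packed annotation vectors.

The toy gene's codon layout (translation order, genomic plus strand):
ATG@111 AAA@114 CCC@117 GGG@120 TTT@123 ACA@126 CAC@129 GAG@{132,232,233}
CTC@234 ATC@237 TTG@240 GAC@243 GAA@246 TGA@249 — stop codon at 249-251,
intron 133-231, donor window {133,134}, acceptor window {230,231}.
"""

import numpy as np
import pytest

from vecvar.annotator import ReferenceAnnotator
from vecvar.gene_model import CDSSegment, Gene, GeneModel, SequenceStore, Transcript
from vecvar.impact import DEL_ALLELE, INS_ALLELE, terms_of
from vecvar.targets import CoordinateError, build_transcript_targets

from conftest import build_toy


def _terms_at(annr, targets, pos, allele):
    nus = targets.genomic_to_vector("chrT", pos)
    assert nus, f"position {pos} not on targets"
    frame, neigh, bitmap = annr.annotate_point_mutation(nus[0], allele)
    return frame, neigh, terms_of(bitmap)


class TestSnvCalls:
    @pytest.mark.parametrize(
        "pos,alt,expected",
        [
            (119, "T", {"synonymous_variant"}),  # CCC -> CCT (Pro)
            (117, "A", {"missense_variant"}),  # CCC -> ACC (Pro -> Thr)
            (246, "T", {"stop_gained"}),  # GAA -> TAA
            (251, "G", {"stop_lost"}),  # TGA -> TGG (Trp)
            (250, "A", {"stop_retained_variant"}),  # TGA -> TAA
            (112, "C", {"start_lost"}),  # ATG -> ACG
            (105, "A", {"5_prime_UTR_variant"}),
            (253, "G", {"3_prime_UTR_variant"}),
            (141, "C", {"intron_variant"}),
        ],
    )
    def test_expected_terms(self, toy, pos, alt, expected):
        _seq, _model, targets, annr = toy
        _f, _n, terms = _terms_at(annr, targets, pos, alt)
        assert terms == frozenset(expected)

    def test_splice_acceptor_and_donor(self, toy):
        _seq, _model, targets, annr = toy
        assert "splice_donor_variant" in _terms_at(annr, targets, 133, "G")[2]
        assert "splice_acceptor_variant" in _terms_at(annr, targets, 230, "A")[2]

    def test_frame_is_codon_offset(self, toy):
        _seq, _model, targets, annr = toy
        assert _terms_at(annr, targets, 117, "A")[0] == 0
        assert _terms_at(annr, targets, 118, "A")[0] == 1
        assert _terms_at(annr, targets, 119, "T")[0] == 2
        # codon spanning the splice junction: 232 has offset 1
        assert _terms_at(annr, targets, 232, "T")[0] == 1

    def test_neighborhood_is_genomic_3bp_each_side(self, toy):
        seq, _model, targets, annr = toy
        _f, neigh, _t = _terms_at(annr, targets, 119, "T")
        assert neigh == seq.substring("chrT", 116, 118) + seq.substring("chrT", 120, 122)
        assert neigh == "ACCGGG"


class TestSpliceWindows:
    def test_exactly_two_positions_per_intron_side(self, toy):
        _seq, _model, targets, annr = toy
        donors, acceptors = [], []
        for nu in range(1, targets.l_T + 1):
            t = frozenset()
            for allele in "ACGT":  # skip the reference allele implicitly (packs to 0)
                _f, _n, bm = annr.annotate_point_mutation(nu, allele)
                t |= terms_of(bm)
            _k, _c, pos = targets.vector_to_genomic(nu)
            if "splice_donor_variant" in t:
                donors.append(pos)
            if "splice_acceptor_variant" in t:
                acceptors.append(pos)
        assert sorted(set(donors)) == [133, 134]
        assert sorted(set(acceptors)) == [230, 231]

    def test_splice_region_band(self, toy):
        _seq, _model, targets, annr = toy
        in_region = set()
        for pos in range(120, 145):
            nus = targets.genomic_to_vector("chrT", pos)
            if not nus:
                continue
            for allele in "ACGT":
                _f, _n, bm = annr.annotate_point_mutation(nus[0], allele)
                if "splice_region_variant" in terms_of(bm):
                    in_region.add(pos)
        # 1-3 exonic (130-132) and 3-8 intronic (135-140) around the donor
        assert in_region == set(range(130, 133)) | set(range(135, 141))


class TestIndelAlleles:
    def test_deletion_of_stop_first_base(self, toy):
        _seq, _model, targets, annr = toy
        _f, _n, terms = _terms_at(annr, targets, 249, DEL_ALLELE)
        assert {"stop_lost", "frameshift_variant"} <= terms

    def test_deletion_of_coding_base_is_frameshift(self, toy):
        _seq, _model, targets, annr = toy
        assert "frameshift_variant" in _terms_at(annr, targets, 117, DEL_ALLELE)[2]

    def test_insertion_between_coding_bases(self, toy):
        _seq, _model, targets, annr = toy
        f, _n, terms = _terms_at(annr, targets, 117, INS_ALLELE)
        assert "frameshift_variant" in terms
        assert f == 0

    def test_insertion_inside_donor_motif(self, toy):
        _seq, _model, targets, annr = toy
        assert "splice_donor_variant" in _terms_at(annr, targets, 133, INS_ALLELE)[2]
        # between exon end and motif: region term only, motif intact
        t132 = _terms_at(annr, targets, 132, INS_ALLELE)[2]
        assert "splice_donor_variant" not in t132
        assert "splice_region_variant" in t132

    def test_insertion_neighborhood_covers_junction(self, toy):
        seq, _model, targets, annr = toy
        _f, neigh, _t = _terms_at(annr, targets, 119, INS_ALLELE)
        assert neigh == seq.substring("chrT", 117, 119) + seq.substring("chrT", 120, 122)


class TestAnnotationVector:
    def test_reference_allele_slots_are_zero(self, toy):
        seq, _model, targets, annr = toy
        for allele in "ACGT":
            vec = annr.build_annotation_vector(allele)
            for nu in range(1, targets.l_T + 1, 7):
                _k, chrom, pos = targets.vector_to_genomic(nu)
                if seq.base(chrom, pos) == allele:
                    assert vec.values[nu - 1] == 0

    def test_vector_matches_per_position_calls(self, toy):
        from vecvar.impact import pack_impact

        _seq, _model, targets, annr = toy
        for allele in ("A", "T", DEL_ALLELE, INS_ALLELE):
            vec = annr.build_annotation_vector(allele)
            for nu in range(1, targets.l_T + 1):
                frame, neigh, bitmap = annr.annotate_point_mutation(nu, allele)
                expected = pack_impact(frame, neigh, bitmap) if bitmap else 0
                assert int(vec.values[nu - 1]) == expected

    def test_nonzero_entries_have_terms(self, sim_small):
        _cfg, _seq, _model, targets, annr = sim_small
        vec = annr.build_annotation_vector("G")
        nz = vec.values[vec.values != 0]
        assert len(nz)
        assert all(int(v) >> 20 for v in nz[:500])  # bitmap part non-empty

    def test_all_values_fit_58_bits(self, sim_small):
        _cfg, _seq, _model, _targets, annr = sim_small
        for allele in ("A", DEL_ALLELE, INS_ALLELE):
            vec = annr.build_annotation_vector(allele)
            assert int(vec.values.max()) < (1 << 58)

    def test_out_of_range_coordinate(self, toy):
        _seq, _model, targets, annr = toy
        with pytest.raises(CoordinateError):
            annr.annotate_point_mutation(targets.l_T + 1, "A")


class TestStrandSymmetry:
    def test_mirrored_gene_gives_complementary_calls(self):
        from vecvar.gene_model import reverse_complement

        seq, model = build_toy()
        L = seq.length("chrT")
        mirror_seq = SequenceStore({"chrT": reverse_complement(seq.substring("chrT", 1, L))})
        flip = lambda p: L - p + 1
        t = model.genes["toy"].transcripts[0]
        mt = Transcript(
            id="toy.t1", gene_id="toy", chrom="chrT", strand="-",
            exons=sorted((flip(e), flip(s)) for s, e in t.exons),
            cds=sorted(
                (CDSSegment(flip(c.end), flip(c.start), c.phase) for c in t.cds),
                key=lambda c: c.start,
            ),
        )
        mmodel = GeneModel(genes={"toy": Gene("toy", "chrT", "-", [mt])})
        mmodel.validate()
        targets = build_transcript_targets(model, l_ext=10)
        mtargets = build_transcript_targets(mmodel, l_ext=10)
        annr = ReferenceAnnotator(model, seq, targets)
        mannr = ReferenceAnnotator(mmodel, mirror_seq, mtargets)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos in range(101, 260, 3):
            nus = targets.genomic_to_vector("chrT", pos)
            mnus = mtargets.genomic_to_vector("chrT", flip(pos))
            if not nus or not mnus:
                continue
            for alt in "ACGT":
                _f1, _n1, bm1 = annr.annotate_point_mutation(nus[0], alt)
                _f2, _n2, bm2 = mannr.annotate_point_mutation(mnus[0], comp[alt])
                assert terms_of(bm1) == terms_of(bm2), (pos, alt)
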