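"""Synthetic data generator: determinism, structural validity, calibration."""

import numpy as np
import pytest
from scipy import stats

from vecvar.annotator import ReferenceAnnotator
from vecvar.gene_model import SequenceStore
from vecvar.gene_model_io import load_gene_annotation, load_genome, write_gtf
from vecvar.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_genotypes,
    simulate_reference,
    simulate_variants,
    write_fasta,
    write_vcf,
)
from vecvar.targets import build_transcript_targets
from vecvar.variants import SNV, parse_vcf


SMALL = dict(chrom_length=150_000, n_genes=8)


class TestReference:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            cfg = SimulationConfig(seed=9, **SMALL)
            genome, model = simulate_reference(cfg)
            (tmp_path / d).mkdir()
            write_fasta(genome, tmp_path / d / "g.fa")
            write_gtf(model, tmp_path / d / "m.gtf")
        assert (tmp_path / "a/g.fa").read_bytes() == (tmp_path / "b/g.fa").read_bytes()
        assert (tmp_path / "a/m.gtf").read_bytes() == (tmp_path / "b/m.gtf").read_bytes()

    def test_every_cds_is_a_valid_orf(self, sim_small):
        _cfg, seq, model, targets, annr = sim_small
        assert model.n_transcripts() > 0
        for t in model.transcripts():
            idx = annr.tindex(t.id)
            assert idx.mrna.startswith("ATG"), t.id
            assert idx.mrna[-3:] in ("TAA", "TAG", "TGA"), t.id
            assert idx.L % 3 == 0
            assert "N" not in idx.mrna

    def test_both_strands_and_shared_exons_present(self, sim_small):
        _cfg, _seq, model, _t, _a = sim_small
        strands = {g.strand for g in model.genes.values()}
        assert strands == {"+", "-"}
        shared = 0
        for g in model.genes.values():
            exon_sets = [frozenset(t.exons) for t in g.transcripts]
            if len(exon_sets) > 1 and len(set().union(*exon_sets)) < sum(map(len, exon_sets)):
                shared += 1
        assert shared >= 1

    def test_overlapping_gene_pair_exists(self):
        cfg = SimulationConfig(seed=9, chrom_length=400_000, n_genes=12)
        _genome, model = simulate_reference(cfg)
        spans = sorted((g.span, g.id) for g in model.genes.values())
        overlap = any(
            s2[0][0] <= s1[0][1] for s1, s2 in zip(spans, spans[1:])
        )
        assert overlap

    def test_nmd_isoforms_filtered_on_reload(self, tmp_path):
        cfg = SimulationConfig(seed=9, nmd_prob=1.0, **SMALL)
        genome, model = simulate_reference(cfg)
        write_fasta(genome, tmp_path / "g.fa")
        write_gtf(model, tmp_path / "m.gtf")
        reloaded = load_gene_annotation(tmp_path / "m.gtf")
        raw = load_gene_annotation(tmp_path / "m.gtf", exclude_tags=frozenset())
        assert reloaded.n_transcripts() < raw.n_transcripts()
        assert all("NMD_transcript" not in t.tags for t in reloaded.transcripts())
        # sequence survives the round trip too
        store = load_genome(tmp_path / "g.fa")
        assert store.substring(cfg.chrom_name, 1, 50) == genome[cfg.chrom_name][:50]

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ConfigError):
            simulate_reference(SimulationConfig(seed=1, chrom_length=5_000, n_genes=10))

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=4, chrom_length=50_000, n_genes=3, utr_length=(4, 9))
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg
        assert SimulationConfig.from_yaml(tmp_path / "sim.yaml", seed=9).seed == 9


class TestVariants:
    def test_zero_rate_gives_empty_vcf(self, sim_small, tmp_path):
        _cfg, seq, _model, targets, _a = sim_small
        cfg = SimulationConfig(seed=2, mutation_rate=0.0)
        vs = simulate_variants(targets, seq, cfg, kind="snv")
        assert len(vs) == 0
        write_vcf(vs, seq, tmp_path / "empty.vcf")
        assert len(parse_vcf(tmp_path / "empty.vcf")) == 0

    def test_snv_count_within_binomial_bounds(self):
        # single-isoform genes: unique covered positions == l_T exactly
        cfg = SimulationConfig(seed=3, chrom_length=150_000, n_genes=8,
                               transcripts_per_gene=(1, 1), nmd_prob=0, incomplete_prob=0,
                               nested_gene_every=0)
        genome, model = simulate_reference(cfg)
        seq = SequenceStore(genome)
        targets = build_transcript_targets(model, l_ext=10)
        p = cfg.mutation_rate
        sigma = np.sqrt(targets.l_T * p * (1 - p))
        vs = simulate_variants(targets, seq, cfg, kind="snv", seed=77)
        assert abs(len(vs.snvs) - p * targets.l_T) < 4 * sigma

    def test_alt_alleles_uniform_over_non_reference(self, sim_mb):
        cfg, seq, _model, targets, _a = sim_mb
        vs = simulate_variants(targets, seq, cfg, kind="snv", seed=55)
        assert len(vs.snvs) > 10_000
        # per reference base, alternates should be uniform over the other 3
        counts = {}
        for v in vs.snvs[:20_000]:
            ref = seq.base(v.chrom, v.pos)
            counts.setdefault(ref, {}).setdefault(v.alt, 0)
            counts[ref][v.alt] += 1
        for ref, alts in counts.items():
            obs = np.array(list(alts.values()))
            assert len(obs) == 3
            _chi, pval = stats.chisquare(obs)
            assert pval > 0.01, (ref, alts)

    def test_indel_lengths_uniform_on_range(self, sim_small):
        cfg, seq, _model, targets, _a = sim_small
        vs = simulate_variants(targets, seq, cfg, kind="del", seed=6)
        lengths = np.array([d.length for d in vs.deletions])
        assert lengths.min() >= 1 and lengths.max() <= 10
        _chi, pval = stats.chisquare(np.bincount(lengths, minlength=11)[1:])
        assert pval > 0.01

    def test_scripted_variants_injected(self, sim_small):
        _cfg, seq, _model, targets, _a = sim_small
        from vecvar.variants import VariantSet

        extra = VariantSet(snvs=[SNV("chrS", 12345, "A")])
        cfg = SimulationConfig(seed=2, mutation_rate=0.0)
        vs = simulate_variants(targets, seq, cfg, kind="snv", extra=extra)
        assert vs.snvs == extra.snvs

    def test_emitted_vcf_reparses_identically(self, sim_small, tmp_path):
        _cfg, seq, _model, targets, _a = sim_small
        cfg = SimulationConfig(seed=8, mutation_rate=0.03)
        for kind in ("snv", "del", "ins"):
            vs = simulate_variants(targets, seq, cfg, kind=kind, seed=8)
            path = tmp_path / f"{kind}.vcf"
            write_vcf(vs, seq, path)
            back = parse_vcf(path)
            assert sorted(back.snvs) == sorted(vs.snvs)
            assert sorted(back.deletions, key=lambda d: d.d1) == sorted(vs.deletions, key=lambda d: d.d1)
            assert sorted(back.insertions, key=lambda i: i.pos) == sorted(vs.insertions, key=lambda i: i.pos)
            assert back.skipped_symbolic == back.skipped_complex == 0


class TestGenotypes:
    def test_zero_spectrum_is_all_reference(self, sim_small):
        _cfg, seq, _model, targets, _a = sim_small
        vs = simulate_variants(targets, seq, SimulationConfig(seed=2, mutation_rate=0.01),
                               kind="snv", seed=2)
        _samples, rows = simulate_genotypes(vs, 10, seed=3, fixed_af=0.0)
        assert all(not d.any() for _v, d in rows)

    def test_written_ac_matches_gt_fields(self, sim_small, tmp_path):
        _cfg, seq, _model, targets, _a = sim_small
        vs = simulate_variants(targets, seq, SimulationConfig(seed=2, mutation_rate=0.01),
                               kind="snv", seed=2)
        samples, rows = simulate_genotypes(vs, 15, seed=4)
        path = tmp_path / "gt.vcf"
        write_vcf(rows, seq, path, samples=samples)
        import pysam

        by_pos = {(v.chrom, v.pos, v.alt): int(d.sum()) for (v, d) in rows}
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                ac = sum(
                    sum(1 for g in rec.samples[s]["GT"] if g == 1) for s in samples
                )
                assert ac == by_pos[(rec.chrom, rec.pos, rec.alts[0])]

    def test_sample_split_additivity(self, sim_small):
        _cfg, seq, _model, targets, _a = sim_small
        vs = simulate_variants(targets, seq, SimulationConfig(seed=2, mutation_rate=0.01),
                               kind="snv", seed=2)
        _samples, rows = simulate_genotypes(vs, 30, seed=5)
        for _v, doses in rows[:50]:
            assert doses[:12].sum() + doses[12:].sum() == doses.sum()

    def test_invalid_sample_count(self, sim_small):
        _cfg, seq, _model, _t, _a = sim_small
        from vecvar.variants import VariantSet

        with pytest.raises(ConfigError):
            simulate_genotypes(VariantSet(snvs=[SNV("chrS", 1, "A")]), 0, seed=1)
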