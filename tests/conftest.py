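"""Shared fixtures: a hand-crafted two-exon gene (exact, human-checkable
coordinates and codons) and seeded simulated references at two scales."""

import numpy as np
import pytest

from vecvar.annotator import ReferenceAnnotator
from vecvar.gene_model import CDSSegment, Gene, GeneModel, SequenceStore, Transcript
from vecvar.simulate import SimulationConfig, simulate_reference
from vecvar.targets import build_transcript_targets

# hand-built coding sequence: ATG + 12 non-stop codons + TGA (42 nt, 14 codons)
TOY_CDS = "ATG" + "AAACCCGGGTTTACACACGAGCTCATCTTGGACGAA" + "TGA"
TOY_UTR5 = "CTCTCTCTCT"  # 101-110
TOY_UTR3 = "TAACCGGA"  # 252-259; starts with TAA so a stop-engulfing
#                        deletion re-forms a stop codon at the junction


def build_toy():
    """One plus-strand gene on a 400 bp chromosome.

    exon1 = [101, 132] (UTR5 101-110, CDS 111-132, 22 coding nt)
    intron = [133, 231]
    exon2 = [232, 259] (CDS 232-251 incl. stop codon 249-251, UTR3 252-259)
    """
    chrom = list("ACGT" * 100)
    chrom[100:110] = TOY_UTR5
    chrom[110:132] = TOY_CDS[:22]
    chrom[231:251] = TOY_CDS[22:]
    chrom[251:259] = TOY_UTR3
    seq = SequenceStore({"chrT": "".join(chrom)})

    t = Transcript(
        id="toy.t1",
        gene_id="toy",
        chrom="chrT",
        strand="+",
        exons=[(101, 132), (232, 259)],
        cds=[CDSSegment(111, 132, 0), CDSSegment(232, 251, 2)],
        utrs=[(101, 110, "5"), (252, 259, "3")],
    )
    model = GeneModel(genes={"toy": Gene("toy", "chrT", "+", [t])})
    model.validate()
    return seq, model


@pytest.fixture(scope="session")
def toy():
    seq, model = build_toy()
    targets = build_transcript_targets(model, l_ext=10)
    return seq, model, targets, ReferenceAnnotator(model, seq, targets)


@pytest.fixture(scope="session")
def sim_small():
    """Seeded 200 kb / 10-gene reference with overlapping transcripts."""
    cfg = SimulationConfig(seed=5, chrom_length=200_000, n_genes=10)
    genome, model = simulate_reference(cfg)
    seq = SequenceStore(genome)
    targets = build_transcript_targets(model, l_ext=10)
    return cfg, seq, model, targets, ReferenceAnnotator(model, seq, targets)


@pytest.fixture(scope="session")
def sim_mb():
    """The 1 Mb / 50-gene study fixture (100 bp extensions, as in the
    simulation protocol the indel comparisons use)."""
    cfg = SimulationConfig(seed=101)
    genome, model = simulate_reference(cfg)
    seq = SequenceStore(genome)
    targets = build_transcript_targets(model, l_ext=100)
    return cfg, seq, model, targets, ReferenceAnnotator(model, seq, targets)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
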