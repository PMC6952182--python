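import numpy as np
import pandas as pd
import pytest

from accessome.gene_models import GeneModel, Transcript
from accessome.intervals import Accessome, merge_to_accessome


@pytest.fixture
def genome_sizes():
    return {"chr1": 100_000, "chr2": 80_000}


@pytest.fixture
def small_accessome(genome_sizes):
    intervals = [
        ("chr1", 100, 400),
        ("chr1", 1_000, 1_300),
        ("chr1", 9_800, 10_200),
        ("chr1", 30_000, 30_250),
        ("chr2", 500, 900),
        ("chr2", 50_000, 50_400),
    ]
    return merge_to_accessome([intervals], genome_sizes)


def make_transcript(tid, chrom, strand, exons, utr5=None, utr3=None):
    tx = Transcript(tid, chrom, strand, exons=list(exons))
    tx.utr5 = list(utr5 or [])
    tx.utr3 = list(utr3 or [])
    tx.finalize()
    return tx


@pytest.fixture
def plus_gene():
    """+ strand gene on chr1: 5'UTR starts at 10,000, two exons, 3'UTR ends at 12,000."""
    tx = make_transcript(
        "gA.t1", "chr1", "+",
        exons=[(10_000, 10_600), (11_200, 12_000)],
        utr5=[(10_000, 10_150)],
        utr3=[(11_800, 12_000)],
    )
    return GeneModel("gA", "chr1", [tx])


@pytest.fixture
def minus_gene():
    """- strand gene on chr2: TSS anchored at the 5'UTR end (coordinate 40,000)."""
    tx = make_transcript(
        "gB.t1", "chr2", "-",
        exons=[(38_000, 38_900), (39_300, 40_001)],
        utr5=[(39_850, 40_001)],
        utr3=[(38_000, 38_120)],
    )
    return GeneModel("gB", "chr2", [tx])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def nb_counts(rng, mu, alpha):
    """Draw NB(mean mu, Var mu + alpha mu^2) counts."""
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


@pytest.fixture
def toy_da_tables():
    """Minimal DA tables over 8 peaks exercising all six set definitions."""
    peaks = [f"p{i}" for i in range(8)]

    def table(lfc, fdr):
        return pd.DataFrame(
            {"log2fc": lfc, "p_value": fdr, "fdr": fdr}, index=peaks
        )

    z = [0.0] * 8
    sig = [0.9] * 8
    tables = {}
    # p0: closed in fgfr_dn vs control (first union branch of "opened at 10")
    # p1: open in mek vs fgfr_dn only (second union branch)
    # p2: boundary case log2fc == -0.5 exactly (must be excluded)
    lfc = [-0.6, 0.0, -0.5, 0, 0, 0, 0, 0]
    fdr = [0.01, 0.9, 0.01, 0.9, 0.9, 0.9, 0.9, 0.9]
    tables["fgfr_dn_vs_control"] = table(lfc, fdr)
    tables["mek_act_vs_control"] = table([0, 0, 0, -1.2, 0, 0, 0, 0],
                                         [0.9, 0.9, 0.9, 0.01, 0.9, 0.9, 0.9, 0.9])
    tables["mek_act_vs_fgfr_dn"] = table([0, 0.8, 0, 0, -0.9, 0, 0, 0],
                                         [0.9, 0.02, 0.9, 0.9, 0.01, 0.9, 0.9, 0.9])
    tables["fgfr_dn_vs_control_18"] = table([0, 0, 0, 0, 0, -0.7, 0.9, 0],
                                            [0.9, 0.9, 0.9, 0.9, 0.9, 0.01, 0.01, 0.9])
    tables["mras_ca_vs_control_18"] = table(z, sig)
    tables["mras_ca_vs_fgfr_dn_18"] = table(z, sig)
    # p7 closed at 10 vs 18 (de novo candidate); p0 must stay primed
    tables["control_10_vs_18"] = table([0, 0, 0, 0, 0, 0, 0, -1.5],
                                       [0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.001])
    return tables
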