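import numpy as np
import pandas as pd
import pytest

from tmztk import screen_quant, screen_stats, simulate


@pytest.fixture(scope="session")
def small_library():
    return simulate.gen_library(
        n_genes=20, guides_per_gene=5, n_controls=30, spacer_len=20, seed=11
    )


@pytest.fixture(scope="session")
def null_screen(small_library):
    """A no-effect screen: one genotype, 3 replicates, both treatments."""
    design = simulate.ScreenDesign(genotypes=("RAD18+/+",), depth=2e5)
    mat, truth = simulate.gen_screen_counts(
        small_library, design, simulate.EffectSpec(), seed=5
    )
    return mat, truth


@pytest.fixture(scope="session")
def null_lfc(null_screen):
    mat, _ = null_screen
    return screen_stats.guide_lfc(screen_quant.normalize_counts(mat))


@pytest.fixture(scope="session")
def signature_matrix():
    return simulate.synthetic_signature_matrix()


@pytest.fixture()
def toy_lfc():
    """Hand-constructed LFC table: one gene, two guides, one replicate,
    both treatments, plus two control guides."""
    rows = []
    for trt, vals in [("TMZ", [-1.0, -0.6]), ("DMSO", [0.0, 0.2])]:
        for guide, val in zip(["GENEA_sg1", "GENEA_sg2"], vals):
            rows.append((guide, "WT", trt, 1, val))
        for i, val in enumerate([0.05, -0.05]):
            rows.append((f"NTC_sg{i+1}", "WT", trt, 1, val))
    return pd.DataFrame(
        rows, columns=["guide_id", "genotype", "treatment", "replicate", "lfc"]
    )


@pytest.fixture()
def toy_library():
    return pd.DataFrame(
        {
            "guide_id": ["GENEA_sg1", "GENEA_sg2", "NTC_sg1", "NTC_sg2"],
            "spacer": ["ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA",
                       "GGGGCCCCAAAATTTTACGT", "AAAACCCCGGGGTTTTTGCA"],
            "gene": ["GENEA", "GENEA", "", ""],
            "pathways": ["PW1", "PW1", "", ""],
            "is_control": [False, False, True, True],
        }
    )
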