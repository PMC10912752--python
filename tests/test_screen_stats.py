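import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmztk import screen_quant, screen_stats, simulate
from tmztk.screen_quant import CountMatrix


def _matrix_from_pairs(pairs, pseudo_meta=None):
    """Build a normalized-flagged CountMatrix from {guide: (n0, n20)}."""
    guides = list(pairs)
    counts = pd.DataFrame(
        {
            "s0": [pairs[g][0] for g in guides],
            "s1": [pairs[g][1] for g in guides],
        },
        index=guides,
    )
    samples = pd.DataFrame(
        {
            "genotype": ["WT", "WT"],
            "treatment": ["TMZ", "TMZ"],
            "timepoint": ["PD0", "PD20"],
            "replicate": [1, 1],
        },
        index=["s0", "s1"],
    )
    return CountMatrix(counts, samples, normalized=True, norm_constant=1.0)


class TestGuideLfc:
    def test_hand_arithmetic(self):
        mat = _matrix_from_pairs({"g": (100, 25)})
        lfc = screen_stats.guide_lfc(mat, pseudocount=1.0)
        assert lfc["lfc"].iloc[0] == pytest.approx(np.log2(26 / 101), abs=1e-12)

    def test_unchanged_and_double_zero(self):
        mat = _matrix_from_pairs({"same": (40, 40), "zero": (0, 0)})
        lfc = screen_stats.guide_lfc(mat).set_index("guide_id")["lfc"]
        assert lfc["same"] == 0.0
        assert lfc["zero"] == 0.0  # pseudocount guard

    def test_missing_timepoint_errors(self):
        mat = _matrix_from_pairs({"g": (1, 1)})
        mat.samples.loc["s1", "timepoint"] = "PD10"
        with pytest.raises(ValueError, match="PD20"):
            screen_stats.guide_lfc(mat)


class TestSigmaFC:
    def test_sum_of_guide_means(self, toy_library):
        rows = []
        for g, vals in [("GENEA_sg1", [-1.0, -1.0]), ("GENEA_sg2", [-2.0, -2.0])]:
            for rep, v in enumerate(vals, 1):
                rows.append((g, "WT", "TMZ", rep, v))
        lfc = pd.DataFrame(
            rows, columns=["guide_id", "genotype", "treatment", "replicate", "lfc"]
        )
        out = screen_stats.gene_sigma_fc(lfc, toy_library, gene="GENEA")
        assert out.iloc[0] == pytest.approx(-3.0)

    def test_linearity_in_guide_count(self, null_lfc, small_library):
        sigma = screen_stats.gene_sigma_fc(null_lfc, small_library)
        doubled_lib = pd.concat(
            [small_library,
             small_library[~small_library.is_control].assign(
                 guide_id=lambda d: d.guide_id + "_b",
                 spacer=lambda d: d.spacer.str[::-1])],
            ignore_index=True,
        )
        doubled_lfc = pd.concat(
            [null_lfc,
             null_lfc.merge(small_library[["guide_id", "is_control"]],
                            on="guide_id")
             .query("~is_control").drop(columns="is_control")
             .assign(guide_id=lambda d: d.guide_id + "_b")],
            ignore_index=True,
        )
        sigma2 = screen_stats.gene_sigma_fc(doubled_lfc, doubled_lib)
        merged = sigma.merge(sigma2, on=["gene", "genotype", "treatment"])
        np.testing.assert_allclose(
            2 * merged["sigma_fc_x"], merged["sigma_fc_y"], rtol=1e-10
        )

    def test_unknown_gene(self, null_lfc, small_library):
        with pytest.raises(KeyError):
            screen_stats.gene_sigma_fc(null_lfc, small_library, gene="NOPE")


class TestPermutation:
    def test_zero_observed_is_nonsignificant(self):
        controls = np.concatenate([np.arange(-5, 0), np.arange(1, 6)]) / 10
        p = screen_stats.permutation_pvalue(0.0, controls, m=3, B=500, seed=0)
        assert p == 1.0

    def test_enumeration_small_B(self):
        # nulls all smaller in magnitude than observed -> p = 1/(B+1)
        controls = np.full(10, 0.01)
        p = screen_stats.permutation_pvalue(5.0, controls, m=2, B=3, seed=1)
        assert p == pytest.approx(1 / 4)

    def test_lower_bound_attained_never_zero(self):
        controls = np.random.default_rng(2).normal(0, 0.1, 50)
        p = screen_stats.permutation_pvalue(100.0, controls, m=5, B=99, seed=3)
        assert p == pytest.approx(1 / 100)

    def test_too_few_controls(self):
        with pytest.raises(ValueError):
            screen_stats.permutation_pvalue(1.0, np.ones(3), m=5, B=10)

    def test_batch_matches_single(self):
        rng = np.random.default_rng(7)
        controls = rng.normal(0, 1, 40)
        obs = pd.Series({"a": 0.5, "b": -2.0, "c": 0.0})
        batch = screen_stats.permutation_pvalues(obs, controls, m=4, B=200, seed=9)
        for k in obs.index:
            single = screen_stats.permutation_pvalue(
                obs[k], controls, m=4, B=200, seed=9
            )
            assert batch[k] == pytest.approx(single)


class TestGeneZ:
    def test_hand_arithmetic(self, toy_lfc, toy_library):
        X, S, Z = screen_stats.gene_zstat(toy_lfc, toy_library, "GENEA", "WT")
        assert X == pytest.approx(-0.9)
        assert S == pytest.approx(np.sqrt(0.08 / 2 + 0.02 / 2), abs=1e-12)
        assert Z == pytest.approx(-0.9 / 0.22360679, abs=1e-6)

    def test_identical_conditions_zero(self, toy_lfc, toy_library):
        sym = toy_lfc.copy()
        sym.loc[sym.treatment == "DMSO", "lfc"] = (
            sym.loc[sym.treatment == "TMZ", "lfc"].to_numpy()
        )
        X, S, Z = screen_stats.gene_zstat(sym, toy_library, "GENEA", "WT")
        assert (X, Z) == (0.0, 0.0)

    def test_antisymmetry(self, toy_lfc, toy_library):
        X1, _, Z1 = screen_stats.gene_zstat(toy_lfc, toy_library, "GENEA", "WT")
        X2, _, Z2 = screen_stats.gene_zstat(
            toy_lfc, toy_library, "GENEA", "WT",
            treatment_test="DMSO", treatment_ref="TMZ",
        )
        assert X2 == pytest.approx(-X1)
        assert Z2 == pytest.approx(-Z1)


class TestPathwayZ:
    def test_arithmetic_oracle(self):
        scores = pd.DataFrame(
            {"X": [-0.9, -0.3], "S": np.sqrt([0.05, 0.04])},
            index=["g1", "g2"],
        )
        z, p = screen_stats.pathway_zstat(scores, ["g1", "g2"])
        assert z == pytest.approx(-1.2 / 0.3)
        assert p == pytest.approx(2 * stats.norm.sf(4.0), rel=1e-9)

    def test_single_gene_reduction(self):
        scores = pd.DataFrame({"X": [-0.5], "S": [0.1]}, index=["g"])
        z, _ = screen_stats.pathway_zstat(scores, ["g"])
        assert z == pytest.approx(-5.0)

    def test_order_and_split_invariance(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            {"X": rng.normal(size=6), "S": rng.uniform(0.1, 1, 6)},
            index=[f"g{i}" for i in range(6)],
        )
        members = list(scores.index)
        z_fwd, _ = screen_stats.pathway_zstat(scores, members)
        z_rev, _ = screen_stats.pathway_zstat(scores, members[::-1])
        assert z_fwd == pytest.approx(z_rev, rel=1e-12)
        # recombining singleton (X, S) pairs through the same formula
        z_manual = scores["X"].sum() / np.sqrt((scores["S"] ** 2).sum())
        assert z_fwd == pytest.approx(z_manual, rel=1e-12)

    def test_empty_pathway(self):
        with pytest.raises(ValueError):
            screen_stats.pathway_zstat(pd.DataFrame(columns=["X", "S"]), [])


class TestPathwayDropout:
    def _null_norm(self, small_library, null_screen):
        mat, _ = null_screen
        return screen_quant.normalize_counts(mat)

    def test_no_change_convention(self, toy_library):
        counts = pd.DataFrame(
            {"s0": [100, 200, 10, 10], "s1": [100, 200, 10, 10]},
            index=toy_library.guide_id,
        )
        samples = pd.DataFrame(
            {"genotype": "WT", "treatment": "TMZ",
             "timepoint": ["PD0", "PD20"], "replicate": 1},
            index=["s0", "s1"],
        )
        mat = CountMatrix(counts, samples, normalized=True)
        p, l2 = screen_stats.pathway_dropout_stats(
            mat, toy_library, ["GENEA"], "WT", "TMZ"
        )
        assert p == 1.0
        assert l2 == 0.0

    def test_halving_gives_minus_one(self, toy_library):
        counts = pd.DataFrame(
            {"s0": [100, 200, 10, 10], "s1": [50, 100, 10, 10]},
            index=toy_library.guide_id,
        )
        samples = pd.DataFrame(
            {"genotype": "WT", "treatment": "TMZ",
             "timepoint": ["PD0", "PD20"], "replicate": 1},
            index=["s0", "s1"],
        )
        mat = CountMatrix(counts, samples, normalized=True)
        with pytest.warns(UserWarning):
            p, l2 = screen_stats.pathway_dropout_stats(
                mat, toy_library, ["GENEA"], "WT", "TMZ", pseudocount=0.0
            )
        assert l2 == pytest.approx(-1.0)
        assert p == 0.0  # exact halving: zero-variance non-zero differences

    def test_matches_textbook_paired_t(self, small_library, null_screen):
        norm = self._null_norm(small_library, null_screen)
        members = small_library.loc[~small_library.is_control, "gene"].unique()[:4]
        p, _ = screen_stats.pathway_dropout_stats(
            norm, small_library, list(members), "RAD18+/+", "TMZ"
        )
        # independent textbook computation of the paired t-test
        guides = small_library.loc[
            small_library.gene.isin(members), "guide_id"
        ]
        mask = norm.guide_ids.isin(guides)
        meta = norm.samples
        d = []
        for rep in sorted(meta["replicate"].unique()):
            sel = meta[(meta.genotype == "RAD18+/+") & (meta.treatment == "TMZ")
                       & (meta.replicate == rep)]
            s0 = sel.index[sel.timepoint == "PD0"][0]
            s1 = sel.index[sel.timepoint == "PD20"][0]
            d.append(np.log10(norm.counts.loc[mask, s1].to_numpy() + 1)
                     - np.log10(norm.counts.loc[mask, s0].to_numpy() + 1))
        d = np.concatenate(d)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_ref = 2 * stats.t.sf(abs(t), d.size - 1)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestNormalizationInvariance:
    def test_statistics_invariant_to_constant(self, null_screen, small_library):
        mat, _ = null_screen
        out = {}
        for const in (1e6, 1e7):
            lfc = screen_stats.guide_lfc(
                screen_quant.normalize_counts(mat, const), pseudocount=0.0
            )
            zs = screen_stats.gene_zstats(lfc, small_library, "RAD18+/+")
            out[const] = zs
        # pseudocount 0 makes the LFC ratio exactly scale-free
        pd.testing.assert_frame_equal(out[1e6], out[1e7])
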