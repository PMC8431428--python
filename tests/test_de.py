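"""DE engine: size factors, dispersion, Wald test, BH, DEG calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from triadex import de, simulate


def _counts(mat, genes=None, samples=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=genes, columns=samples)


def _design(genotypes, time_point="T1"):
    return pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(len(genotypes))],
            "genotype": genotypes,
            "role": ["female_parent"] * len(genotypes),
            "time_point": time_point,
            "replicate": list(range(1, len(genotypes) + 1)),
        }
    )


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = _counts([[10, 10], [5, 5], [100, 100]])
        sf = de.estimate_size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), [1.0, 1.0])

    def test_proportional_samples(self):
        """sample2 = 2 x sample1 forces factors (1/sqrt2, sqrt2) under a
        geometric-mean reference."""
        counts = _counts([[10, 20], [20, 40], [30, 60]])
        sf = de.estimate_size_factors(counts)
        np.testing.assert_allclose(
            sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_three_sample_toy_matches_direct_arithmetic(self):
        """Frozen median-of-ratios hand computation."""
        counts = _counts([[10, 20, 15], [100, 50, 80], [5, 5, 5], [40, 80, 120]])
        sf = de.estimate_size_factors(counts)
        np.testing.assert_allclose(
            sf.to_numpy(), [0.84668064, 1.05032121, 1.06290448], rtol=1e-7
        )

    def test_scale_equivariance_of_factor_ratios(self):
        """Multiplying one sample by c multiplies its factor relative to
        every other sample by c, leaving between-sample fold changes of
        normalised counts unchanged."""
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 200, size=(50, 4))
        counts = _counts(mat)
        sf = de.estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["s2"] = scaled["s2"] * 7
        sf2 = de.estimate_size_factors(scaled)
        np.testing.assert_allclose(
            (sf2 / sf2["s0"]).to_numpy(), (7 ** (sf.index == "s2")) * (sf / sf["s0"]).to_numpy(),
            rtol=1e-12,
        )
        norm, norm2 = (counts / sf).to_numpy(), (scaled / sf2).to_numpy()
        np.testing.assert_allclose(
            norm2 / norm2[:, :1], norm / norm[:, :1], rtol=1e-9
        )

    def test_no_all_positive_gene_errors_and_fallback(self):
        counts = _counts([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo"):
            de.estimate_size_factors(counts)
        sf = de.estimate_size_factors(counts, allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersion:
    def test_poisson_like_hits_floor(self):
        """Genes whose variance equals the mean get the alpha floor."""
        # two groups of 3, within-group variance == grand mean by construction
        counts = _counts(
            [[9, 10, 11, 9, 10, 11]], genes=["g0"],
        )
        design = _design(["A"] * 3 + ["B"] * 3)
        sf = pd.Series(1.0, index=counts.columns)
        alpha = de.estimate_dispersion(counts, design, "A", "B", sf)
        # s2 = 1 < mean 10 -> negative MoM -> floored
        assert alpha["g0"] == de.ALPHA_MIN

    def test_direct_formula(self):
        """mean 100, pooled within-group s2 600 -> alpha = 0.05."""
        a = np.array([100 - np.sqrt(600), 100, 100 + np.sqrt(600)])
        counts = _counts([np.concatenate([a, a])])
        design = _design(["A"] * 3 + ["B"] * 3)
        sf = pd.Series(1.0, index=counts.columns)
        alpha = de.estimate_dispersion(counts, design, "A", "B", sf)
        # pooled s2 = (1200+1200)/4 = 600, mean 100: alpha = (600-100)/1e4
        np.testing.assert_allclose(alpha["g0"], 0.05, rtol=1e-9)

    def test_monte_carlo_recovery(self):
        """Median MoM estimate near the simulating alpha at n=50."""
        rng = np.random.default_rng(5)
        mu, alpha_true, n = 200.0, 0.1, 50
        size = 1 / alpha_true
        mat = rng.negative_binomial(size, size / (size + mu), size=(500, 2 * n))
        counts = _counts(mat)
        design = _design(["A"] * n + ["B"] * n)
        sf = pd.Series(1.0, index=counts.columns)
        alpha = de.estimate_dispersion(counts, design, "A", "B", sf)
        assert 0.05 <= np.median(alpha) <= 0.2

    def test_unknown_group_label(self):
        counts = _counts([[1, 2, 3, 4]])
        design = _design(["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            de.estimate_dispersion(counts, design, "A", "C")


class TestWald:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(9)
        mat = rng.poisson(100, size=(40, 6))
        counts = _counts(mat)
        design = _design(["A"] * 3 + ["B"] * 3)
        return counts, design

    def test_identical_groups_are_null(self):
        counts = _counts([[10, 20, 30, 10, 20, 30], [5, 6, 7, 5, 6, 7]])
        design = _design(["A"] * 3 + ["B"] * 3)
        sf = pd.Series(1.0, index=counts.columns)
        res = de.nb_wald_test(counts, design, "A", "B", size_factors=sf)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], 1.0, atol=1e-12)

    def test_swapping_groups_negates_log2fc(self, toy):
        counts, design = toy
        ab = de.nb_wald_test(counts, design, "A", "B")
        ba = de.nb_wald_test(counts, design, "B", "A")
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-10)
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-10)

    def test_all_zero_gene_degenerate(self):
        counts = _counts([[0, 0, 0, 0, 0, 0], [50, 60, 55, 50, 60, 55]])
        design = _design(["A"] * 3 + ["B"] * 3)
        res = de.nb_wald_test(counts, design, "A", "B")
        assert res.loc["g0", "log2fc"] == 0.0
        assert res.loc["g0", "p_value"] == 1.0

    def test_planted_log2fc_recovered(self):
        """Mean estimated log2FC within 0.2 of the planted value 2."""
        rng = np.random.default_rng(17)
        n_genes, alpha_true = 2000, 0.05
        mu_a = rng.lognormal(5, 1, size=n_genes)
        mu_b = mu_a * 4.0
        size = 1 / alpha_true

        def draw(mu, n):
            return np.column_stack(
                [rng.negative_binomial(size, size / (size + mu)) for _ in range(n)]
            )

        mat = np.hstack([draw(mu_a, 3), draw(mu_b, 3)])
        counts = _counts(mat)
        design = _design(["A"] * 3 + ["B"] * 3)
        sf = pd.Series(1.0, index=counts.columns)
        res = de.nb_wald_test(counts, design, "A", "B", size_factors=sf)
        assert abs(res["log2fc"].mean() - 2.0) < 0.2

    def test_overlapping_groups_rejected(self, toy):
        counts, design = toy
        with pytest.raises(ValueError):
            de.nb_wald_test(counts, design, "A", "A")


class TestBH:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            de.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal_p_identity(self):
        np.testing.assert_allclose(de.adjust_bh([0.3]), [0.3])
        np.testing.assert_allclose(de.adjust_bh([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                 max_size=60)
    )
    def test_matches_statsmodels_and_preserves_order(self, pvals):
        ours = de.adjust_bh(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        p = np.asarray(pvals)
        assert (ours >= p - 1e-15).all() and (ours <= 1).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(ours[order]) >= -1e-15).all()


class TestCalls:
    @pytest.mark.parametrize(
        "log2fc, p_adj, expected",
        [(1.5, 0.01, "up"), (0.9, 0.001, "ns"), (-2.0, 0.06, "ns"),
         (-1.0, 0.049, "down"), (1.0, 0.05, "ns")],
    )
    def test_threshold_rules(self, log2fc, p_adj, expected):
        df = pd.DataFrame({"log2fc": [log2fc], "p_adj": [p_adj]}, index=["g"])
        assert de.call_degs(df)["g"] == expected

    def test_summary_counts(self):
        df = pd.DataFrame(
            {"log2fc": [2, -2, 0.2], "p_adj": [0.01, 0.01, 0.01]},
            index=list("abc"),
        )
        call = de.call_degs(df)
        assert de.deg_summary(call) == (1, 1, 2)


class TestCalibrationAndPower:
    def test_null_fdr_controlled(self):
        """All-conserved simulation: <= 6% of genes at p_adj < 0.05."""
        cfg = simulate.SimConfig(
            n_genes=2000, time_points=1,
            class_proportions={"conserved": 1.0}, seed=23,
        )
        counts, samples, _ = simulate.simulate_triad_counts(cfg)
        res = de.de_comparison(counts, samples, "F", "FO", time_point="T1")
        assert (res["p_adj"] < 0.05).mean() <= 0.06

    def test_power_on_planted_fold_change(self):
        """Planted 4-fold parent contrasts are called with matching sign
        for >= 80% of genes."""
        cfg = simulate.SimConfig(
            n_genes=1000, time_points=1,
            class_proportions={"eldF": 1.0}, seed=29,
        )
        counts, samples, truth = simulate.simulate_triad_counts(cfg)
        res = de.de_comparison(counts, samples, "F", "M", time_point="T1")
        true_sign = np.sign(np.log2(truth["mu_M"] / truth["mu_F"]))
        expected = np.where(true_sign > 0, "up", "down")
        assert (res["call"].to_numpy() == expected).mean() >= 0.80
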