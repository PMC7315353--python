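import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exofeed.diffexpr import (
    bh_adjust,
    de_set_intersections,
    estimate_dispersion,
    nb_wald_test,
    run_de,
    size_factors_median_of_ratios,
)


def nb_matrix(rng, mean, alpha, n_features, n_libs):
    if alpha == 0:
        return rng.poisson(mean, size=(n_features, n_libs))
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mean), size=(n_features, n_libs))


class TestSizeFactors:
    def test_hand_worked_two_library_example(self):
        counts = pd.DataFrame([[100, 200], [50, 100]], columns=["l1", "l2"])
        sf = size_factors_median_of_ratios(counts)
        assert sf["l1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["l2"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_libraries_get_equal_factors(self):
        counts = pd.DataFrame({"l1": [10, 30, 5], "l2": [10, 30, 5]})
        sf = size_factors_median_of_ratios(counts)
        assert sf["l1"] == pytest.approx(sf["l2"])

    def test_doubling_a_library_doubles_its_factor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {"l1": rng.poisson(100, 50) + 1, "l2": rng.poisson(100, 50) + 1}
        )
        doubled = counts.assign(l2=2 * counts["l2"])
        sf, sf2 = size_factors_median_of_ratios(counts), size_factors_median_of_ratios(doubled)
        # factors are defined up to the per-feature geometric mean, so the
        # doubling shows up in the ratio between libraries
        assert (sf2["l2"] / sf2["l1"]) / (sf["l2"] / sf["l1"]) == pytest.approx(
            2.0, rel=1e-2
        )

    def test_requires_a_feature_positive_everywhere(self):
        counts = pd.DataFrame({"l1": [0, 5], "l2": [5, 0]})
        with pytest.raises(ValueError, match="filter"):
            size_factors_median_of_ratios(counts)


class TestDispersion:
    SF = pd.Series({"l1": 1.0, "l2": 1.0, "l3": 1.0})

    def test_constant_counts_have_zero_dispersion(self):
        counts = pd.DataFrame([[100, 100, 100]], columns=self.SF.index)
        assert estimate_dispersion(counts, self.SF).iloc[0] == 0.0

    def test_hand_worked_two_point_example(self):
        counts = pd.DataFrame([[50, 150]], columns=["l1", "l2"])
        sf = pd.Series({"l1": 1.0, "l2": 1.0})
        assert estimate_dispersion(counts, sf).iloc[0] == pytest.approx(0.49)

    def test_poisson_data_yields_near_zero_alpha(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(200, size=(1000, 6)), columns=[f"l{i}" for i in range(6)]
        )
        sf = pd.Series(1.0, index=counts.columns)
        assert float(estimate_dispersion(counts, sf).median()) <= 0.05

    def test_zero_mean_feature_excluded_as_nan(self):
        counts = pd.DataFrame([[0, 0, 0]], columns=self.SF.index)
        assert np.isnan(estimate_dispersion(counts, self.SF).iloc[0])


class TestNbWald:
    def _run(self, counts, alpha=None):
        labels = pd.Series(
            ["WT"] * 3 + ["KD"] * 3, index=[f"l{i}" for i in range(6)]
        )
        df = pd.DataFrame(counts, columns=labels.index)
        sf = pd.Series(1.0, index=labels.index)
        disp = (
            estimate_dispersion(df, sf)
            if alpha is None
            else pd.Series(alpha, index=df.index)
        )
        return nb_wald_test(df, sf, disp, labels, "KD", "WT")

    def test_null_feature_is_not_extreme(self):
        rng = np.random.default_rng(11)
        res = self._run(nb_matrix(rng, 200, 0.1, 200, 6))
        assert abs(float(res.log2FoldChange.median())) < 0.2
        assert float(res.pvalue.median()) > 0.2

    def test_fourfold_depletion_recovered(self):
        rng = np.random.default_rng(12)
        # closed form: SE(log2FC) = sqrt(sum_g 1/I_g)/ln2 ~ 0.295, so
        # P(|error| < 0.5) = P(|z| < 1.70) ~ 0.911; many features keep the
        # Monte-Carlo error well below that margin
        wt = nb_matrix(rng, 200, 0.05, 5000, 3)
        kd = nb_matrix(rng, 50, 0.05, 5000, 3)
        res = self._run(np.hstack([wt, kd]), alpha=0.05)
        close = (res.log2FoldChange + 2).abs() < 0.5
        assert close.mean() >= 0.9
        assert abs(float(res.log2FoldChange.median()) + 2) < 0.15

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(13)
        res = self._run(nb_matrix(rng, 200, 0.1, 5000, 6), alpha=0.1)
        assert abs(float(res.pvalue.mean()) - 0.5) < 0.03

    def test_all_zero_features_reported_na(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        res = self._run(counts)
        assert np.isnan(res.iloc[0].pvalue)
        assert np.isfinite(res.iloc[1].pvalue)

    def test_agrees_with_statsmodels_glm(self):
        """Independent oracle: the same NB likelihood fit by statsmodels."""
        import statsmodels.api as sm

        rng = np.random.default_rng(14)
        counts = np.hstack(
            [nb_matrix(rng, 300, 0.05, 20, 3), nb_matrix(rng, 100, 0.05, 20, 3)]
        )
        labels = pd.Series(["WT"] * 3 + ["KD"] * 3, index=[f"l{i}" for i in range(6)])
        df = pd.DataFrame(counts, columns=labels.index)
        sf = pd.Series(1.0, index=labels.index)
        disp = estimate_dispersion(df, sf)
        mine = nb_wald_test(df, sf, disp, labels, "KD", "WT")
        x = np.column_stack([np.ones(6), (labels == "KD").to_numpy(float)])
        for i in range(20):
            alpha = max(float(disp.iloc[i]), 1e-8)
            glm = sm.GLM(
                counts[i], x, family=sm.families.NegativeBinomial(alpha=alpha)
            ).fit()
            assert mine.log2FoldChange.iloc[i] == pytest.approx(
                glm.params[1] / np.log(2), abs=1e-3
            )
            assert mine.lfcSE.iloc[i] == pytest.approx(
                glm.bse[1] / np.log(2), rel=0.02
            )

    def test_empty_group_rejected(self):
        df = pd.DataFrame(np.ones((3, 3)), columns=["l0", "l1", "l2"])
        labels = pd.Series(["WT"] * 3, index=df.columns)
        sf = pd.Series(1.0, index=df.columns)
        with pytest.raises(ValueError):
            nb_wald_test(df, sf, sf * 0, labels, "KD", "WT")


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_equal_inputs_give_equal_outputs(self):
        adj = bh_adjust([0.2, 0.2, 0.2])
        assert adj[0] == adj[1] == adj[2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_entries_preserved_and_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m=2, not 3

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False),
            min_size=2,
            max_size=40,
        )
    )
    def test_monotone_and_dominates_raw_p(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        assert (np.asarray(adj) >= np.asarray(ps) - 1e-12).all()
        assert (np.asarray(adj) <= 1 + 1e-12).all()


class TestIntersections:
    def test_hand_enumerated_regions(self):
        out = de_set_intersections({"A": {"x", "y"}, "B": {"y", "z"}}, {"x", "y", "z", "w"})
        assert out == {("A",): 1, ("B",): 1, ("A", "B"): 1}

    def test_identical_sets_fully_shared(self):
        out = de_set_intersections({"A": {"x", "y"}, "B": {"x", "y"}}, {"x", "y"})
        assert out == {("A", "B"): 2}

    def test_disjoint_sets_share_nothing(self):
        out = de_set_intersections({"A": {"x"}, "B": {"y"}}, {"x", "y"})
        assert ("A", "B") not in out

    def test_foreign_features_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            de_set_intersections({"A": {"q"}}, {"x"})


class TestRunDe:
    def test_size_factor_anchor_changes_inference_under_global_shift(self):
        """With every feature depleted, anchored size factors see the shift."""
        rng = np.random.default_rng(21)
        stable = nb_matrix(rng, 500, 0.02, 50, 6)
        wt = nb_matrix(rng, 200, 0.02, 200, 3)
        kd = nb_matrix(rng, 50, 0.02, 200, 3)
        libs = [f"l{i}" for i in range(6)]
        counts = pd.DataFrame(
            np.vstack([np.hstack([wt, kd]), stable]),
            index=[f"f{i}" for i in range(200)] + [f"s{i}" for i in range(50)],
            columns=libs,
        )
        meta = pd.DataFrame(
            {"library_id": libs, "condition": ["WT"] * 3 + ["KD"] * 3}
        )
        anchored = run_de(
            counts, meta, "KD", size_factor_features=counts.index[200:]
        ).iloc[:200]
        naive = run_de(counts, meta, "KD").iloc[:200]
        assert anchored.significant.mean() >= 0.8
        assert abs(float(anchored.log2FoldChange.median()) + 2) < 0.3
        # unanchored median-of-ratios absorbs most of the uniform depletion
        assert naive.significant.mean() < anchored.significant.mean()

    def test_single_replicate_contrast_usable(self):
        """One knockdown library against replicated wild types still tests
        (dispersion comes from the replicated group)."""
        rng = np.random.default_rng(22)
        libs = ["w1", "w2", "w3", "k1"]
        wt = nb_matrix(rng, 400, 0.05, 100, 3)
        kd = np.vstack(
            [nb_matrix(rng, 100, 0.05, 20, 1), nb_matrix(rng, 400, 0.05, 80, 1)]
        )
        counts = pd.DataFrame(np.hstack([wt, kd]), columns=libs)
        meta = pd.DataFrame({"library_id": libs, "condition": ["WT"] * 3 + ["KD"]})
        res = run_de(counts, meta, "KD")
        assert res.pvalue.notna().all()
        assert abs(float(res.log2FoldChange.iloc[:20].median()) + 2) < 0.4
        assert abs(float(res.log2FoldChange.iloc[20:].median())) < 0.3
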