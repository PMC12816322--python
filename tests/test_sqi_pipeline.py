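import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sqindex as sq
from sqindex.reference import (
    EXAMPLE_EIGENVALUES,
    EXAMPLE_LOADINGS,
    EXAMPLE_MDS,
    example_redundancy_correlations,
)
from sqindex.sqi_pipeline import (
    LESS_IS_BETTER,
    MORE_IS_BETTER,
    MDSSelection,
    ScoreConfig,
    candidate_indicators,
    compute_sqi,
    correlation_matrix,
    indicator_weights,
    pca_correlation,
    prune_redundant,
    retain_components,
    score_indicator,
    sqi_from_samples,
    zscore_matrix,
)

from conftest import charpoly_eigenvalues, random_correlation_matrix


class TestZscore:
    def test_symmetric_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        Z, mean, sd = zscore_matrix(df, ["x"])
        assert np.allclose(Z["x"], [-1, 0, 1])
        assert mean["x"] == 2.0 and sd["x"] == 1.0

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="x"):
            zscore_matrix(df, ["x", "y"])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            zscore_matrix(pd.DataFrame({"x": [1.0, 2.0]}), ["x"])

    def test_moments_after_transform(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.gamma(2, 2, size=(40, 4)), columns=list("abcd"))
        Z, _, _ = zscore_matrix(df, list("abcd"))
        assert np.allclose(Z.mean(), 0, atol=1e-10)
        assert np.allclose(Z.std(ddof=1), 1, atol=1e-10)


class TestCorrelationMatrix:
    def test_identical_and_negated_columns(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        R = correlation_matrix(df)
        assert R.loc["a", "b"] == pytest.approx(1.0)
        assert R.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_elementwise_pearson_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        R = correlation_matrix(df)
        for i in "abcd":
            for j in "abcd":
                x, y = df[i] - df[i].mean(), df[j] - df[j].mean()
                r = (x * y).sum() / np.sqrt((x ** 2).sum() * (y ** 2).sum())
                assert R.loc[i, j] == pytest.approx(r, abs=1e-12)

    def test_warns_when_n_not_greater_than_p(self):
        df = pd.DataFrame(np.random.default_rng(2).standard_normal((3, 4)))
        with pytest.warns(UserWarning, match="singular"):
            correlation_matrix(df)


class TestPCACorrelation:
    def test_identity_matrix(self):
        R = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        res = pca_correlation(R)
        assert np.allclose(res.eigenvalues, 1.0)
        assert np.allclose(res.variance_pct, 100 / 3)

    def test_two_by_two_closed_form(self):
        R = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]], index=["a", "b"], columns=["a", "b"])
        res = pca_correlation(R)
        assert np.allclose(res.eigenvalues, [1.6, 0.4])

    def test_eigenvalues_sum_to_p_and_column_norms(self):
        rng = np.random.default_rng(3)
        R = random_correlation_matrix(rng, 6)
        res = pca_correlation(R)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)
        norms = (res.loadings ** 2).sum(axis=0).to_numpy()
        assert np.allclose(norms, res.eigenvalues, atol=1e-8)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-8)

    def test_spectral_reconstruction(self):
        rng = np.random.default_rng(4)
        R = random_correlation_matrix(rng, 5)
        res = pca_correlation(R)
        L = res.loadings.to_numpy()
        assert np.allclose(L @ L.T, R.to_numpy(), atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        res = pca_correlation(random_correlation_matrix(rng, 5))
        L = res.loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] >= 0

    def test_eigenvalues_match_charpoly_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            p = int(rng.integers(2, 7))
            R = random_correlation_matrix(rng, p)
            res = pca_correlation(R)
            oracle = charpoly_eigenvalues(R.to_numpy())
            assert np.allclose(res.eigenvalues, oracle, atol=1e-6)

    def test_non_psd_rejected(self):
        R = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="semi-definite"):
            pca_correlation(R)


class TestRetention:
    def test_worked_example_retains_five(self):
        residual = np.array([0.744, 0.0, 0.0, 0.0])  # remaining variance, all < 1
        eigs = np.concatenate([EXAMPLE_EIGENVALUES, residual])
        assert retain_components(eigs) == [0, 1, 2, 3, 4]

    def test_strict_inequality_at_threshold(self):
        with pytest.warns(UserWarning):
            assert retain_components(np.ones(4)) == []

    def test_simple_case(self):
        assert retain_components(np.array([2.0, 0.5])) == [0]


class TestCandidates:
    def test_worked_example_component_one(self):
        cands = candidate_indicators(EXAMPLE_LOADINGS, [0, 1, 2, 3, 4])
        assert cands[0] == ["som", "ap", "tn"]

    def test_worked_example_component_three_excludes_available_k(self):
        # |−0.661| fails 0.9 * 0.754 = 0.679
        cands = candidate_indicators(EXAMPLE_LOADINGS, [2])
        assert cands[2] == ["bd"]

    def test_available_k_enters_via_component_five(self):
        cands = candidate_indicators(EXAMPLE_LOADINGS, [4])
        assert cands[4] == ["ak"]

    def test_component_below_min_loading_gives_empty_set(self):
        L = pd.DataFrame({0: [0.4, 0.3]}, index=["a", "b"])
        assert candidate_indicators(L, [0]) == {0: []}


class TestWeights:
    def test_single_component_squares(self):
        L = pd.DataFrame({0: [0.8, 0.6]}, index=["a", "b"])
        w = indicator_weights(L, np.array([1.0]), [0])
        assert np.allclose(w, [0.64, 0.36])

    def test_single_indicator_gets_weight_one(self):
        w = indicator_weights(EXAMPLE_LOADINGS, EXAMPLE_EIGENVALUES,
                              [0, 1, 2, 3, 4], indicators=["som"])
        assert w["som"] == pytest.approx(1.0)

    def test_som_heads_fertility_cluster_in_worked_example(self):
        w = indicator_weights(EXAMPLE_LOADINGS, EXAMPLE_EIGENVALUES, [0, 1, 2, 3, 4])
        assert w["som"] > w["ap"] and w["som"] > w["tn"]

    def test_weights_sum_to_one_both_modes(self):
        for mode in ("communality", "as_printed"):
            w = indicator_weights(EXAMPLE_LOADINGS, EXAMPLE_EIGENVALUES,
                                  [0, 1, 2, 3, 4], mode=mode)
            assert w.sum() == pytest.approx(1.0, abs=1e-10)
            assert (w >= 0).all()


class TestPruning:
    def test_worked_example_minimum_data_set(self, study_selection):
        assert set(study_selection.mds) == set(EXAMPLE_MDS)
        assert study_selection.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert study_selection.audit  # pruning decisions are recorded

    def test_no_pruning_when_uncorrelated(self):
        R = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        w = pd.Series({"a": 0.6, "b": 0.4})
        sel = prune_redundant({0: ["a", "b"]}, R, w)
        assert sel.mds == ["a", "b"]

    def test_equal_weight_tie_breaks_on_loading(self):
        R = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"], columns=["a", "b"])
        w = pd.Series({"a": 0.5, "b": 0.5})
        L = pd.DataFrame({0: [0.6, 0.8]}, index=["a", "b"])
        sel = prune_redundant({0: ["a", "b"]}, R, w, L)
        assert sel.mds == ["b"]


class TestScoring:
    @pytest.mark.parametrize("x,direction,expected", [
        (0.0, MORE_IS_BETTER, 0.0), (10.0, MORE_IS_BETTER, 1.0),
        (5.0, MORE_IS_BETTER, 0.5), (5.0, LESS_IS_BETTER, 0.5),
        (0.0, LESS_IS_BETTER, 1.0), (10.0, LESS_IS_BETTER, 0.0),
    ])
    def test_endpoints_and_midpoint(self, x, direction, expected):
        assert score_indicator(x, 0.0, 10.0, direction) == pytest.approx(expected)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            score_indicator(1.0, 2.0, 2.0, MORE_IS_BETTER)


def _manual_selection(weights: dict) -> MDSSelection:
    w = pd.Series(weights)
    return MDSSelection(candidates={0: list(w.index)}, mds=list(w.index), weights=w)


class TestComputeSQI:
    def test_hand_summed_index(self):
        df = pd.DataFrame({
            "site_id": ["A"] * 3, "treatment": ["control"] * 3,
            "year": [2021] * 3, "season": ["wheat"] * 3,
            "x": [0.0, 5.0, 10.0], "y": [0.0, 2.5, 10.0],
        })
        sel = _manual_selection({"x": 0.6, "y": 0.4})
        cfg = ScoreConfig(directions={"x": MORE_IS_BETTER, "y": MORE_IS_BETTER})
        res = compute_sqi(df, sel, cfg)
        # middle row: scores (0.5, 0.25) with weights (0.6, 0.4)
        assert res.sqi.iloc[1] == pytest.approx(0.40)
        assert res.sqi.iloc[0] == pytest.approx(0.0)
        assert res.sqi.iloc[2] == pytest.approx(1.0)

    def test_index_bounded_and_consistent(self, trial_df, study_selection):
        res = compute_sqi(trial_df, study_selection)
        assert res.sqi.between(0, 1).all()
        recomputed = res.scores.mul(study_selection.weights, axis=1).sum(axis=1)
        assert np.allclose(recomputed, res.sqi, atol=1e-12)

    def test_directional_recovery_per_site(self, trial_df, study_selection):
        """Manure substitution lifts the index over control at every site."""
        res = compute_sqi(trial_df, study_selection)
        m = trial_df.assign(sqi=res.sqi).groupby(["site_id", "treatment"]).sqi.mean()
        for site in trial_df.site_id.unique():
            assert m[site, "30%M"] > m[site, "control"]

    def test_monotone_in_indicator_direction(self, trial_df, study_selection):
        res = compute_sqi(trial_df, study_selection)
        bumped = trial_df.copy()
        i = bumped.index[0]
        lo, hi = trial_df["som"].min(), trial_df["som"].max()
        bumped.loc[i, "som"] = min(hi, bumped.loc[i, "som"] * 1.05)
        res2 = compute_sqi(bumped, study_selection)
        assert res2.sqi.iloc[0] >= res.sqi.iloc[0] - 1e-12
        bumped.loc[i, "bd"] = min(trial_df["bd"].max(), bumped.loc[i, "bd"] * 1.05)
        res3 = compute_sqi(bumped, study_selection)
        assert res3.sqi.iloc[0] <= res2.sqi.iloc[0] + 1e-12

    def test_sample_order_invariance(self, trial_df, study_selection):
        res = compute_sqi(trial_df, study_selection)
        shuffled = trial_df.sample(frac=1, random_state=0)
        res2 = compute_sqi(shuffled, study_selection)
        assert np.allclose(res2.sqi.sort_index(), res.sqi, atol=1e-12)

    def test_per_season_year_scope(self, trial_df, study_selection):
        cfg = ScoreConfig(normalization_scope="per_season_year")
        res = compute_sqi(trial_df, study_selection, cfg)
        assert res.sqi.between(0, 1).all()

    def test_missing_indicator_rejected(self, study_selection):
        df = pd.DataFrame({"site_id": ["A"] * 3, "treatment": ["control"] * 3,
                           "year": [2021] * 3, "season": ["wheat"] * 3,
                           "som": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="absent"):
            compute_sqi(df, study_selection)


class TestEndToEnd:
    def test_pipeline_runs_and_orders_treatments(self, trial_df):
        res = sqi_from_samples(trial_df)
        assert res.selection.mds  # non-empty MDS
        assert res.sqi.sqi.between(0, 1).all()
        m = trial_df.assign(sqi=res.sqi.sqi).groupby("treatment").sqi.mean()
        assert m["30%M"] > m["control"]

    def test_permutation_leaves_selection_unchanged(self, trial_df):
        a = sqi_from_samples(trial_df)
        b = sqi_from_samples(trial_df.sample(frac=1, random_state=1).reset_index(drop=True))
        assert a.selection.mds == b.selection.mds
        assert np.allclose(a.pca.eigenvalues, b.pca.eigenvalues, atol=1e-10)


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=15, deadline=None)
def test_property_weights_normalized_for_random_psd(seed):
    rng = np.random.default_rng(seed)
    R = random_correlation_matrix(rng, 5)
    res = pca_correlation(R)
    retained = retain_components(res.eigenvalues) or [0]
    w = indicator_weights(res.loadings, res.eigenvalues, retained)
    assert w.sum() == pytest.approx(1.0, abs=1e-10)
    assert (w >= -1e-12).all()
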