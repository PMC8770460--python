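import numpy as np
import pandas as pd
import pytest

import immunoprog as ip
from conftest import gaussian_frame, outcome_series


def _planted_frame(seed, n=80, p=20, planted=("P0000",), shift=5.0):
    rng = np.random.default_rng(seed)
    X = gaussian_frame(rng, n, p)
    y01 = np.r_[np.ones(n // 2), np.zeros(n - n // 2)].astype(bool)
    for probe in planted:
        X.loc[y01, probe] += shift
    return X, outcome_series(y01, X.index)


class TestRankByFilters:
    def test_separating_probe_ranks_first_in_all_methods(self):
        X, y = _planted_frame(seed=0, shift=5.0)
        ranks = ip.rank_by_filters(X, y, n_trees=100, seed=0)
        row = ranks.set_index("probe").loc["P0000"]
        assert row["ranksum_rank"] == 1
        assert row["rf_importance_rank"] == 1
        assert row["mutual_info_rank"] == 1

    def test_constant_probe_gets_worst_rank(self):
        X, y = _planted_frame(seed=1)
        X["P0005"] = 3.0
        ranks = ip.rank_by_filters(X, y, n_trees=50, seed=0)
        row = ranks.set_index("probe").loc["P0005"]
        n = len(X.columns)
        assert row["ranksum_rank"] == n
        assert row["rf_importance_rank"] == n
        assert row["mutual_info_rank"] == n

    def test_rankings_are_permutations(self):
        X, y = _planted_frame(seed=2)
        ranks = ip.rank_by_filters(X, y, n_trees=50, seed=0)
        n = len(X.columns)
        for col in ("ranksum_rank", "rf_importance_rank", "mutual_info_rank"):
            assert sorted(ranks[col]) == list(range(1, n + 1))


class TestRfeStability:
    def test_seed_reproducibility(self):
        X, y = _planted_frame(seed=3, planted=("P0000", "P0001"), shift=2.0)
        r1 = ip.rfe_stability(X, y, n_iter=5, panel_size_grid=(6,), seed_base=0,
                              n_trees=30)
        r2 = ip.rfe_stability(X, y, n_iter=5, panel_size_grid=(6,), seed_base=0,
                              n_trees=30)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_probes_reach_top_ranks(self):
        """Three planted probes at 3-SD effect land in the top 5 of 20."""
        X, y = _planted_frame(
            seed=4, planted=("P0000", "P0001", "P0002"), shift=3.0
        )
        ranking = ip.rfe_stability(X, y, n_iter=25, panel_size_grid=(8,),
                                   seed_base=0, n_trees=50)
        top5 = set(ranking["probe"].iloc[:5])
        assert {"P0000", "P0001", "P0002"} <= top5

    def test_single_iteration_degeneracy(self):
        X, y = _planted_frame(seed=5)
        ranking = ip.rfe_stability(X, y, n_iter=1, panel_size_grid=(6,),
                                   seed_base=0, n_trees=30)
        assert set(ranking["frequency"].unique()) <= {0.0, 1.0}
        assert (ranking["frequency"] == 1.0).sum() == 6

    def test_duplicated_columns_have_similar_frequency(self):
        X, y = _planted_frame(seed=6, planted=("P0000",), shift=3.0)
        X["P9999"] = X["P0000"]  # exact duplicate, exchangeable with P0000
        ranking = ip.rfe_stability(X, y, n_iter=40, panel_size_grid=(8,),
                                   seed_base=0, n_trees=50)
        f = ranking.set_index("probe")["frequency"]
        assert abs(f["P0000"] - f["P9999"]) <= 0.15

    def test_requires_positive_iterations(self):
        X, y = _planted_frame(seed=7)
        with pytest.raises(ValueError):
            ip.rfe_stability(X, y, n_iter=0)


class TestSelectStable:
    def test_top_fraction_of_1600_probes_is_60(self):
        ranking = pd.DataFrame(
            {"probe": [f"P{i:05d}" for i in range(1600)],
             "frequency": np.linspace(1, 0, 1600),
             "mean_importance": np.linspace(1, 0, 1600),
             "rank": np.arange(1, 1601)}
        )
        k = round(0.0375 * 1600)
        assert k == 60
        assert len(ip.select_stable(ranking, k=k)) == 60

    def test_identity_and_empty(self):
        ranking = pd.DataFrame(
            {"probe": list("abc"), "frequency": [1, 0.5, 0.2],
             "mean_importance": [3, 2, 1], "rank": [1, 2, 3]}
        )
        assert ip.select_stable(ranking, k=3) == ["a", "b", "c"]
        assert ip.select_stable(ranking, k=0) == []

    def test_k_beyond_probes_rejected(self):
        ranking = pd.DataFrame(
            {"probe": ["a"], "frequency": [1.0], "mean_importance": [1.0],
             "rank": [1]}
        )
        with pytest.raises(ValueError):
            ip.select_stable(ranking, k=2)


class TestLassoCorroborate:
    def test_default_mixing_parameter(self):
        import inspect

        sig = inspect.signature(ip.lasso_corroborate)
        assert sig.parameters["elastic_net_alpha"].default == 0.9

    def test_planted_probe_selected_with_correct_sign(self):
        X, y = _planted_frame(seed=8, n=100, planted=("P0000",), shift=2.5)
        coefs = ip.lasso_corroborate(X, y, folds=5, repeats=2, seed=0)
        assert "P0000" in coefs.index
        # planted elevation is in the non-survivor (positive) class
        assert coefs["P0000"] > 0

    def test_infinite_penalty_empties_selection(self):
        from sklearn.linear_model import LogisticRegression

        X, y = _planted_frame(seed=9, n=60)
        yv = (y == ip.NON_SURVIVOR).astype(int)
        model = LogisticRegression(
            l1_ratio=0.9, C=1e-8, solver="saga", max_iter=5000
        ).fit(X.to_numpy(), yv)
        assert np.all(np.abs(model.coef_) < 1e-8)


class TestDifferentialReactivity:
    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(10)
        X = np.exp(gaussian_frame(rng, 100, 30) * 0.3)
        y01 = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        y = outcome_series(y01, X.index)
        X.loc[~y01, "P0000"] *= 4.0  # survivor mean 4x the non-survivor mean
        out = ip.differential_reactivity(X, y).set_index("probe")
        assert bool(out.loc["P0000", "pass"])
        assert out.loc["P0000", "fc"] > 2.0

    def test_label_permutation_null_rate(self):
        """Under permuted labels the expected pass count stays at or below
        q_max x n_probes (BH control)."""
        rng = np.random.default_rng(11)
        n_pass = 0
        n_probes = 40
        for rep in range(10):
            X = np.exp(gaussian_frame(rng, 60, n_probes) * 0.3)
            y = outcome_series(rng.permutation([1] * 30 + [0] * 30), X.index)
            n_pass += int(ip.differential_reactivity(X, y)["pass"].sum())
        assert n_pass / 10 <= 0.05 * n_probes

    def test_boundary_values_inclusive(self):
        """A probe at exactly FC = 2.0, and a q exactly equal to q_max, both
        pass (the cut-offs are inclusive)."""
        rng = np.random.default_rng(12)
        X = np.exp(gaussian_frame(rng, 40, 4) * 0.2)
        y01 = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        y = outcome_series(y01, X.index)
        # survivor mean exactly twice the non-survivor mean, groups separated
        X["P0004"] = np.where(~y01, 2.0, 1.0) + np.r_[
            np.linspace(-1e-9, 1e-9, 20), np.linspace(-1e-9, 1e-9, 20)
        ]
        out = ip.differential_reactivity(X, y).set_index("probe")
        assert out.loc["P0004", "fc"] == pytest.approx(2.0)
        assert bool(out.loc["P0004", "pass"])
        exact_q = float(out.loc["P0004", "q"])
        again = ip.differential_reactivity(X, y, q_max=exact_q).set_index("probe")
        assert bool(again.loc["P0004", "pass"])
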