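import numpy as np
import pandas as pd
import pytest

import immunoprog as ip
from immunoprog.survival import HIGH, LOW


def product_limit_oracle(times, events):
    """Independent hand-rolled Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[events])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


class TestRiskScores:
    def _model(self, coefs, intercept=0.0):
        probes = [f"P{j}" for j in range(len(coefs))]
        return ip.ModelCandidate(
            probes=tuple(probes), n=10, K=len(coefs) + 1, logL=0.0, aic=0.0,
            aicc=0.0,
            coefficients=pd.Series([intercept, *coefs], index=["intercept", *probes]),
        )

    def test_dot_product_arithmetic(self):
        model = self._model([1.0, -1.0])
        values = pd.DataFrame({"P0": [2.0], "P1": [1.0]}, index=["a"])
        assert ip.risk_scores(model, values)["a"] == pytest.approx(1.0)

    def test_zero_coefficients_give_intercept(self):
        model = self._model([0.0, 0.0], intercept=0.7)
        values = pd.DataFrame({"P0": [2.0, 5.0], "P1": [1.0, 3.0]})
        assert np.allclose(ip.risk_scores(model, values), 0.7)

    def test_missing_probe_named_in_error(self):
        model = self._model([1.0])
        values = pd.DataFrame({"Q0": [1.0]})
        with pytest.raises(KeyError, match="P0"):
            ip.risk_scores(model, values)


class TestOptimalCutoff:
    def test_separable_midpoint(self):
        scores = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"))
        labels = pd.Series(
            [ip.SURVIVOR, ip.SURVIVOR, ip.NON_SURVIVOR, ip.NON_SURVIVOR],
            index=scores.index,
        )
        assert ip.optimal_cutoff(scores, labels) == pytest.approx(0.5)

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=40), index=[f"S{i}" for i in range(40)])
        y01 = rng.uniform(size=40) < 1 / (1 + np.exp(-2 * scores.to_numpy()))
        labels = pd.Series(
            np.where(y01, ip.NON_SURVIVOR, ip.SURVIVOR), index=scores.index
        )
        cut = ip.optimal_cutoff(scores, labels)
        pred = scores >= cut
        sens = (pred & y01).sum() / y01.sum()
        spec = (~pred & ~y01).sum() / (~y01).sum()
        j_star = sens + spec - 1
        # brute force over a dense threshold sweep
        best = -np.inf
        for t in np.sort(scores.to_numpy()) - 1e-9:
            p = scores >= t
            j = (p & y01).sum() / y01.sum() + (~p & ~y01).sum() / (~y01).sum() - 1
            best = max(best, j)
        assert j_star == pytest.approx(best, abs=1e-12)

    def test_permuted_labels_give_small_j(self):
        rng = np.random.default_rng(1)
        js = []
        for rep in range(20):
            scores = pd.Series(rng.normal(size=60))
            y01 = rng.permutation([True] * 30 + [False] * 30)
            labels = pd.Series(np.where(y01, ip.NON_SURVIVOR, ip.SURVIVOR))
            cut = ip.optimal_cutoff(scores, labels)
            pred = scores >= cut
            js.append(
                (pred & y01).sum() / 30 + (~pred & ~y01).sum() / 30 - 1
            )
        assert np.mean(js) < 0.35  # optimistically biased but small on average

    def test_constant_scores_rejected(self):
        scores = pd.Series([1.0, 1.0], index=["a", "b"])
        labels = pd.Series([ip.SURVIVOR, ip.NON_SURVIVOR], index=scores.index)
        with pytest.raises(ValueError):
            ip.optimal_cutoff(scores, labels)


class TestKaplanMeier:
    def test_all_events_hand_computation(self):
        km = ip.km_estimate([1, 2, 3], [True, True, True])
        lookup = dict(zip(km.curve["time"], km.curve["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert km.median_survival == pytest.approx(2.0)

    def test_censored_hand_computation(self):
        km = ip.km_estimate([1, 2, 3], [True, False, True])
        lookup = dict(zip(km.curve["time"], km.curve["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[3.0] == pytest.approx(0.0)  # risk set of 1 at t=3

    def test_no_events_flat_curve_absent_median(self):
        km = ip.km_estimate([5, 6, 7], [False, False, False])
        assert (km.curve["survival"] == 1.0).all()
        assert km.median_survival is None

    def test_matches_product_limit_oracle(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(500, 30).round(0) + 1
        events = rng.uniform(size=30) < 0.7
        km = ip.km_estimate(times, events)
        oracle = product_limit_oracle(times, events)
        lookup = dict(zip(km.curve["time"], km.curve["survival"]))
        for t, s in oracle.items():
            assert lookup[t] == pytest.approx(s, abs=1e-12)

    def test_survival_probabilities_monotone(self):
        rng = np.random.default_rng(3)
        km = ip.km_estimate(rng.exponential(300, 50) + 1,
                            rng.uniform(size=50) < 0.6)
        s = km.curve["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert ((0 <= s) & (s <= 1)).all()


class TestLogrank:
    def test_duplicated_groups_give_null_statistic(self):
        times = [10, 20, 30, 40] * 2
        events = [True, True, False, True] * 2
        groups = ["a"] * 4 + ["b"] * 4
        stat, p = ip.logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_groups_significant(self):
        rng = np.random.default_rng(4)
        t_a = rng.exponential(100, 20) + 1
        t_b = rng.exponential(100, 20) + 1000
        stat, p = ip.logrank_test(
            np.r_[t_a, t_b], [True] * 40, ["a"] * 20 + ["b"] * 20
        )
        assert p < 0.01

    def test_six_patient_tabular_oracle(self):
        """Hand-computed O-E/V for times (1,2,3) vs (4,5,6), all events."""
        times = [1, 2, 3, 4, 5, 6]
        events = [True] * 6
        groups = ["a", "a", "a", "b", "b", "b"]
        # observed events in a: 3. expected: 3/6+2/5+1/4 = 1.15
        # V = sum n1*n2*d*(n-d)/(n^2*(n-1)) with d=1 each time
        o_minus_e = 3 - (3 / 6 + 2 / 5 + 1 / 4)
        v = (3 * 3) / 36 + (2 * 3) / 25 + (1 * 3) / 16
        expected = o_minus_e**2 / v
        stat, _ = ip.logrank_test(times, events, groups)
        assert stat == pytest.approx(expected, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ip.logrank_test([1, 2], [True, True], ["a", "a"])


class TestCoxBackward:
    def _simulate_cox(self, seed, n=500, hr=2.0, extra_noise=True):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        base = 1 / 500.0
        t = rng.exponential(1.0 / (base * hr**x))
        c = rng.exponential(1500.0, n)
        data = pd.DataFrame(
            {
                "time": np.minimum(t, c) + 0.1,
                "event": (t <= c).astype(int),
                "x": x,
            }
        )
        if extra_noise:
            data["z"] = rng.normal(size=n)
        return data

    def test_planted_hazard_ratio_recovered(self):
        data = self._simulate_cox(seed=5)
        table = ip.cox_backward(data, "time", "event", ["x", "z"])
        row = table.set_index("covariate").loc["x"]
        assert 1.7 <= row["HR"] <= 2.4
        assert row["CI_low"] <= 2.0 <= row["CI_high"]

    def test_independent_covariate_eliminated(self):
        eliminated = 0
        for rep in range(10):
            data = self._simulate_cox(seed=50 + rep, n=300)
            table = ip.cox_backward(data, "time", "event", ["x", "z"])
            eliminated += "z" not in set(table["covariate"])
        assert eliminated >= 9

    def test_null_covariate_ci_covers_one(self):
        data = self._simulate_cox(seed=6, n=400, hr=1.0, extra_noise=False)
        table = ip.cox_backward(data, "time", "event", ["x"], p_out=1.0)
        row = table.set_index("covariate").loc["x"]
        assert row["CI_low"] <= 1.0 <= row["CI_high"]


class TestStratify:
    def test_cutoff_learned_on_cohort1_only(self, normalized_cohort):
        values, ann = normalized_cohort
        y = ann["outcome"]
        model = ip.model_likelihood_aicc(
            values.loc[(ann["cohort"] == 1).to_numpy()],
            y.loc[(ann["cohort"] == 1).to_numpy()],
            ["P0000", "P0001"],
        )
        strat = ip.stratify(model, values, ann, train_mask=ann["cohort"] == 1)
        scores = ip.risk_scores(model, values)
        expected = ip.optimal_cutoff(
            scores[ann["cohort"] == 1], y[ann["cohort"] == 1]
        )
        assert strat.cutoff == expected
        assert set(strat.groups.unique()) <= {HIGH, LOW}
        # groups partition the samples
        assert len(strat.groups) == len(values)
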