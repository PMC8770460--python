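"""Risk scores, ROC-optimal dichotomization and survival stratification.

The final logistic model's linear predictor (intercept + sum of coefficient
times normalized intensity) is each patient's continuous risk score. The
training cohort's scores are dichotomized at the Youden-optimal ROC cut-off
into "high expressors" and "low expressors"; the cut-off is learned on
cohort 1 only and applied unchanged to cohort 2. Group survival is
summarized by Kaplan-Meier curves (with median survival and percentage
survival at a 5-year horizon of 1825 days), compared by the log-rank test,
and adjusted for clinical covariates in a multivariate Cox model with
stepwise backward elimination (Efron tie handling, Wald drop tests).

KM, log-rank and Cox fits are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .aicc import ModelCandidate
from .metrics import youden_operating_point

FIVE_YEARS = 1825.0

HIGH = "high"
LOW = "low"


def risk_scores(model: ModelCandidate, values: pd.DataFrame) -> pd.Series:
    """Logistic linear predictor per sample from the model coefficients."""
    coefs = model.coefficients
    missing = [p for p in model.probes if p not in values.columns]
    if missing:
        raise KeyError(f"probes missing from matrix: {missing}")
    X = values[list(model.probes)].to_numpy(dtype=float)
    beta = coefs[list(model.probes)].to_numpy()
    score = coefs["intercept"] + X @ beta
    return pd.Series(score, index=values.index, name="risk_score")


def optimal_cutoff(scores: pd.Series, labels, positive_label=None) -> float:
    """ROC-optimal (Youden) cut-off over midpoints of adjacent unique scores.

    Ties on J break toward higher specificity, then the lower cut-off.
    Constant scores raise, since no threshold separates anything.
    """
    from .simulate import NON_SURVIVOR

    positive = NON_SURVIVOR if positive_label is None else positive_label
    y = (pd.Series(labels, index=scores.index) == positive).to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    thr, _, _ = youden_operating_point(np.asarray(scores, dtype=float), y)
    return float(thr)


def dichotomize(scores: pd.Series, cutoff: float) -> pd.Series:
    """High/low expressor groups: high when score >= cutoff."""
    return pd.Series(
        np.where(scores >= cutoff, HIGH, LOW), index=scores.index, name="expression"
    )


@dataclass
class KMResult:
    curve: pd.DataFrame  # time, survival, at_risk
    median_survival: float | None
    horizon: float
    survival_at_horizon: float

    def survival_at(self, t: float) -> float:
        s = self.curve[self.curve["time"] <= t]["survival"]
        return float(s.iloc[-1]) if len(s) else 1.0


def km_estimate(times, events, horizon: float = FIVE_YEARS) -> KMResult:
    """Product-limit survival estimate with median and horizon survival (%).

    Median survival is the first time the curve reaches 0.5 or below; it is
    None when the curve never crosses 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty group")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    at_risk = np.array([(times >= t).sum() for t in event_times])
    curve = pd.DataFrame({"time": event_times, "survival": surv, "at_risk": at_risk})

    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    below = curve[curve["time"] <= horizon]["survival"]
    s_h = float(below.iloc[-1]) if len(below) else 1.0
    return KMResult(
        curve=curve, median_survival=median, horizon=horizon,
        survival_at_horizon=100.0 * s_h,
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square statistic and p across >= 2 groups."""
    groups = pd.Series(groups).astype(str)
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups.to_numpy(),
        np.asarray(events, dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class RiskStratification:
    """Per-sample scores and groups plus the group-level survival summaries."""

    scores: pd.Series
    cutoff: float
    groups: pd.Series
    km: dict[str, KMResult]
    logrank_statistic: float
    logrank_p: float
    cox_table: pd.DataFrame | None = field(default=None)


def cox_backward(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    p_out: float = 0.05,
) -> pd.DataFrame:
    """Multivariate Cox PH with stepwise backward elimination by Wald p.

    Categorical covariates must be pre-encoded numerically. Returns a table
    of retained covariates with hazard ratios, 95% Wald CIs and p-values.
    """
    if not data[event_col].astype(bool).any():
        raise ValueError("no events observed")
    current = list(covariates)
    for c in current:
        if data[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")
    fitter = None
    while True:
        fitter = CoxPHFitter()
        fitter.fit(
            data[[duration_col, event_col, *current]],
            duration_col=duration_col,
            event_col=event_col,
        )
        pvals = fitter.summary["p"]
        worst = pvals.idxmax()
        if pvals.max() <= p_out or len(current) == 1:
            break
        current.remove(worst)
    summ = fitter.summary
    out = pd.DataFrame(
        {
            "covariate": summ.index,
            "HR": np.exp(summ["coef"]),
            "CI_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "CI_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "p": summ["p"],
        }
    ).reset_index(drop=True)
    return out


def stratify(
    model: ModelCandidate,
    values: pd.DataFrame,
    annotation: pd.DataFrame,
    train_mask: pd.Series | None = None,
    horizon: float = FIVE_YEARS,
    cox_covariates: list[str] | None = None,
) -> RiskStratification:
    """Full risk stratification: scores -> cut-off -> KM / log-rank (/ Cox).

    The cut-off is learned on ``train_mask`` samples only (cohort 1) and
    applied to everyone; when no mask is given all samples train the
    cut-off.
    """
    scores = risk_scores(model, values)
    labels = annotation["outcome"].reindex(scores.index)
    if train_mask is None:
        train_mask = pd.Series(True, index=scores.index)
    cutoff = optimal_cutoff(scores[train_mask], labels[train_mask])
    groups = dichotomize(scores, cutoff)

    times = annotation["survival_time"].reindex(scores.index)
    events = annotation["event"].reindex(scores.index).astype(bool)
    km = {
        g: km_estimate(times[groups == g], events[groups == g], horizon=horizon)
        for g in (HIGH, LOW)
        if (groups == g).any()
    }
    if len(km) == 2:
        stat, p = logrank_test(times, events, groups)
    else:
        stat, p = float("nan"), float("nan")

    cox_table = None
    if cox_covariates:
        df = annotation.copy()
        df["panel_high"] = (groups == HIGH).astype(int)
        df = _encode_clinical(df)
        cox_table = cox_backward(
            df, "survival_time", "event", ["panel_high", *cox_covariates]
        )
    return RiskStratification(
        scores=scores, cutoff=cutoff, groups=groups, km=km,
        logrank_statistic=stat, logrank_p=p, cox_table=cox_table,
    )


def _encode_clinical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "gender" in df and df["gender"].dtype == object:
        df["gender"] = (df["gender"] == "male").astype(int)
    if "histology" in df and df["histology"].dtype == object:
        df["histology"] = (df["histology"] == "squamous").astype(int)
    for col in ("lymphovascular_invasion", "adjuvant_chemotherapy", "event"):
        if col in df:
            df[col] = df[col].astype(int)
    return df
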