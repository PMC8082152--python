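"""Survival analysis: Kaplan-Meier curves, log-rank tests, the
maximally-selected log-rank cutpoint, and Cox proportional-hazards fits.

KM estimation, the multi-group log-rank test and Cox regression delegate to
lifelines (Efron tie handling for Cox). The cutpoint search is implemented
here: every midpoint between consecutive distinct score values whose induced
high/low groups both satisfy a minimum size proportion is a candidate, and
the one maximizing the absolute standardized log-rank statistic wins. The
selected p-value carries maximal-selection optimism and is reported without
correction, which mirrors common practice but overstates significance — see
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMCurve",
    "CutpointResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "surv_cutpoint",
    "cox_fit",
]


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float  # |standardized log-rank| at the cutpoint
    labels: pd.Series  # sample -> "high" / "low"
    minprop: float


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: coef, hr, ci_lower, ci_upper, p
    log_likelihood: float
    ties: str = "efron"


def _clean(data: pd.DataFrame) -> pd.DataFrame:
    if "time" not in data.columns or "event" not in data.columns:
        raise ValueError("need 'time' and 'event' columns")
    d = data.loc[data["time"].notna() & data["event"].notna()]
    if d.empty:
        raise ValueError("no usable samples with time and event")
    return d


def km_estimate(data: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``data`` needs 'time' and 'event' columns. With censored-only input the
    curve is flat at 1.
    """
    d = _clean(data)
    kmf = KaplanMeierFitter()
    kmf.fit(d["time"], d["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    if len(times) == 0:
        return KMCurve(
            times=np.array([]), survival=np.array([]),
            at_risk=np.array([], dtype=int), events=np.array([], dtype=int),
        )
    surv = kmf.survival_function_at_times(times).to_numpy()
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
    )


def logrank_test(data: pd.DataFrame, group_col: str = "group") -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi-square, df, p).

    Zero events overall is handled as no evidence: statistic 0, p = 1.
    """
    d = _clean(data)
    if group_col not in d.columns:
        raise ValueError(f"no {group_col!r} column")
    groups = d[group_col]
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 non-empty groups")
    df = len(sizes) - 1
    if d["event"].sum() == 0:
        return 0.0, df, 1.0
    res = multivariate_logrank_test(d["time"], groups, d["event"])
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        return 0.0, df, 1.0
    return stat, df, float(res.p_value)


def _logrank_z(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O1 - E1)/sqrt(V1), with
    hypergeometric variance; 0 when the variance vanishes."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], in_group1[order]
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    o1 = e1 = v1 = 0.0
    # counts remaining at each distinct time
    for i, s in enumerate(start):
        stop = start[i + 1] if i + 1 < len(start) else n
        n_at_risk = n - s
        n1_at_risk = g[s:].sum()
        d_j = e[s:stop].sum()
        if d_j == 0:
            continue
        d1_j = (e[s:stop] * g[s:stop]).sum()
        o1 += d1_j
        e1 += d_j * n1_at_risk / n_at_risk
        if n_at_risk > 1:
            v1 += (
                d_j
                * (n1_at_risk / n_at_risk)
                * (1 - n1_at_risk / n_at_risk)
                * (n_at_risk - d_j)
                / (n_at_risk - 1)
            )
    if v1 <= 0:
        return 0.0
    return float((o1 - e1) / np.sqrt(v1))


def logrank_two_group(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float]:
    """Fast two-group log-rank: (chi-square, p). Used for large null
    simulations where per-call overhead matters."""
    z = _logrank_z(
        np.asarray(time, float), np.asarray(event, int), np.asarray(in_group1, bool)
    )
    chi2 = z * z
    return chi2, float(stats.chi2.sf(chi2, df=1))


def surv_cutpoint(
    score: pd.Series, data: pd.DataFrame, minprop: float = 0.1
) -> CutpointResult:
    """Maximally-selected log-rank dichotomization of a continuous score.

    Candidates are midpoints between consecutive distinct score values whose
    induced groups each hold at least ``minprop`` of the samples; the
    returned cutpoint maximizes |standardized log-rank| (ties: lower cut).
    Samples at or below the cutpoint are "low", above are "high".
    """
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    d = _clean(data)
    s = score.loc[d.index]
    if s.isna().any():
        raise ValueError("score contains missing values")
    vals = np.sort(s.unique())
    if len(vals) < 2:
        raise ValueError("all scores identical; no cutpoint exists")
    n = len(s)
    time = d["time"].to_numpy(dtype=float)
    event = d["event"].to_numpy(dtype=int)
    sc = s.to_numpy(dtype=float)

    best: tuple[float, float] | None = None
    for lo, hi in zip(vals[:-1], vals[1:]):
        cut = 0.5 * (lo + hi)
        high = sc > cut
        n_high = int(high.sum())
        if min(n_high, n - n_high) < minprop * n:
            continue
        z = abs(_logrank_z(time, event, high))
        if best is None or z > best[1] + 1e-12:
            best = (cut, z)
    if best is None:
        raise ValueError("no candidate cutpoint satisfies the minimum proportion")
    cut, z = best
    labels = pd.Series(np.where(sc > cut, "high", "low"), index=s.index, name="group")
    return CutpointResult(cutpoint=cut, statistic=z, labels=labels, minprop=minprop)


def cox_fit(data: pd.DataFrame, covariates: list[str]) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Categorical covariates are one-hot encoded with the first level as
    reference. Per covariate: coefficient, HR = exp(coef), Wald 95% CI and p.
    """
    d = _clean(data)
    if d["event"].sum() < 1:
        raise ValueError("need at least one event")
    missing = [c for c in covariates if c not in d.columns]
    if missing:
        raise ValueError(f"unknown covariates: {missing}")
    X = d[covariates].copy()
    cat = [c for c in covariates if not pd.api.types.is_numeric_dtype(X[c])]
    if cat:
        X = pd.get_dummies(X, columns=cat, drop_first=True, dtype=float)
    for c in X.columns:
        if X[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")
    frame = pd.concat([d[["time", "event"]], X], axis=1)

    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    return CoxResult(summary=out, log_likelihood=float(cph.log_likelihood_))
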