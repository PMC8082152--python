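"""Evaluation of the immune-cell score as an immunotherapy-response predictor.

Responders are complete/partial responses (CR/PR); stable and progressive
disease (SD/PD) are non-responders. AUC is the normalized Mann-Whitney U: the
probability that a random responder outscores a random non-responder, ties
counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .group_stats import wilcoxon_ranksum

__all__ = ["roc_auc", "compare_response_groups", "response_labels", "AUCResult"]

RESPONDER_LEVELS = ("CR", "PR")
NON_RESPONDER_LEVELS = ("SD", "PD")


@dataclass
class AUCResult:
    auc: float
    ci_lower: float
    ci_upper: float
    n_pos: int
    n_neg: int
    ci_method: str = "percentile bootstrap"


def response_labels(response: pd.Series) -> pd.Series:
    """Collapse CR/PR/SD/PD to binary responder (1) / non-responder (0)."""
    r = response.dropna()
    bad = r[~r.isin(RESPONDER_LEVELS + NON_RESPONDER_LEVELS)]
    if len(bad):
        raise ValueError(f"unknown response label {bad.iloc[0]!r}")
    return r.isin(RESPONDER_LEVELS).astype(int)


def _auc(score: np.ndarray, label: np.ndarray) -> float:
    n_pos = int(label.sum())
    n_neg = len(label) - n_pos
    ranks = rankdata(score)
    u = ranks[label == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    score: np.ndarray | pd.Series,
    label: np.ndarray | pd.Series,
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCResult:
    """AUC with a percentile-bootstrap 95% CI.

    ``label`` is 1 for responders, 0 for non-responders; both classes must be
    present.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    n_pos = int(label.sum())
    n_neg = len(label) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both responders and non-responders")
    auc = _auc(score, label)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 909]))
    boots = np.empty(n_boot)
    n = len(label)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lb = label[idx]
        if lb.sum() in (0, n):  # degenerate resample: redraw via skip
            boots[i] = auc
            continue
        boots[i] = _auc(score[idx], lb)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AUCResult(auc=auc, ci_lower=float(lo), ci_upper=float(hi),
                     n_pos=n_pos, n_neg=n_neg)


def compare_response_groups(
    score: pd.Series, label: pd.Series
) -> dict[str, float | str]:
    """Rank-sum comparison of scores between responders and non-responders.

    Returns medians, the direction of the difference, U and p.
    """
    score = score.loc[label.index]
    pos = score[label == 1].to_numpy()
    neg = score[label == 0].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both responders and non-responders")
    u, p = wilcoxon_ranksum(pos, neg)
    med_pos, med_neg = float(np.median(pos)), float(np.median(neg))
    if p >= 1.0 or med_pos == med_neg:
        direction = "none"
    elif med_pos > med_neg:
        direction = "responders higher"
    else:
        direction = "responders lower"
    return {
        "median_responders": med_pos,
        "median_non_responders": med_neg,
        "direction": direction,
        "U": float(u),
        "p": float(p),
        "n_responders": len(pos),
        "n_non_responders": len(neg),
    }
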