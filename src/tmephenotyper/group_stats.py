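"""Comparative statistics: moderated-t differential expression, multiple
testing, rank tests, correlations, mutation burden and copy-number burden.

The differential-expression test is the empirical-Bayes moderated t: per-gene
two-group contrasts whose variances are shrunk toward a common prior,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),
    t_g    = logFC_g / (s~_g * sqrt(1/n1 + 1/n2)),  df = d0 + d_g,

with the prior (d0, s0^2) estimated by matching moments of log s_g^2 when not
supplied. d0 = 0 recovers the ordinary pooled t; d0 -> inf fully shrinks to
the prior variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .io_formats import (
    CopyNumberTable,
    ExpressionMatrix,
    MutationTable,
    NONSYNONYMOUS_CLASSES,
)

logger = logging.getLogger("tmephenotyper")

__all__ = [
    "DEResult",
    "moderated_ttest",
    "bh_adjust",
    "kruskal_wallis",
    "wilcoxon_ranksum",
    "chi_squared",
    "spearman_corr",
    "tmb_per_sample",
    "cn_burden",
]


@dataclass
class DEResult:
    """Per-gene differential-expression table with the significance filters
    applied (adjusted p below threshold AND |logFC| above threshold)."""

    table: pd.DataFrame  # logfc, t, p, p_adj, significant
    d0: float
    s0_sq: float
    p_threshold: float
    logfc_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-8:
            break
    return y


def _fit_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior of the gene variances
    on the log scale (d0 = prior df, s0^2 = prior variance)."""
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df_resid / 2) + np.log(df_resid / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    target = e_var - float(polygamma(1, df_resid / 2))
    if target > 0:
        d0 = float(2 * _trigamma_inverse(target)[0])
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_ttest(
    x: ExpressionMatrix,
    groups: pd.Series | list[str],
    d0s0: tuple[float, float] | None = None,
    p_threshold: float = 0.05,
    logfc_threshold: float = 1.0,
    adjust: str = "bh",
) -> DEResult:
    """Empirical-Bayes moderated two-group t-test over all genes.

    ``groups`` must carry exactly two levels with >= 2 samples each; logFC is
    the difference of group means (positive = higher in the level that sorts
    first). Pass ``d0s0=(d0, s0^2)`` to fix the prior (d0=0 gives the
    ordinary pooled t).
    """
    groups = pd.Series(list(groups), index=x.sample_ids)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    m1 = (groups == levels[0]).to_numpy()
    m2 = (groups == levels[1]).to_numpy()
    n1, n2 = int(m1.sum()), int(m2.sum())
    if min(n1, n2) < 2:
        raise ValueError("both groups need at least 2 samples")

    vals = x.values.to_numpy(dtype=float)
    g1, g2 = vals[:, m1], vals[:, m2]
    logfc = g1.mean(axis=1) - g2.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (g2 - g2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if d0s0 is None:
        d0, s0_sq = _fit_prior(s2, df_resid)
    else:
        d0, s0_sq = float(d0s0[0]), float(d0s0[1])
        if d0 < 0 or s0_sq < 0:
            raise ValueError("prior hyperparameters must be non-negative")

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, logfc / np.where(denom > 0, denom, 1.0), 0.0)
        t = np.where((denom == 0) & (logfc != 0), np.sign(logfc) * np.inf, t)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where((denom == 0) & (logfc == 0), 1.0, p)

    if adjust == "bh":
        p_adj = bh_adjust(p)
    elif adjust == "bonferroni":
        p_adj = np.minimum(p * len(p), 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    sig = (p_adj < p_threshold) & (np.abs(logfc) > logfc_threshold)
    table = pd.DataFrame(
        {"logfc": logfc, "t": t, "p": p, "p_adj": p_adj, "significant": sig},
        index=x.values.index,
    )
    return DEResult(table, d0=d0, s0_sq=s0_sq,
                    p_threshold=p_threshold, logfc_threshold=logfc_threshold)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == g] for g in levels]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled
    midranks to group a (permutation distribution of U)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    mu = len(a) * len(b) / 2.0
    dev_obs = abs(u_obs - mu)
    total = hits = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def wilcoxon_ranksum(
    a: np.ndarray, b: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Mann-Whitney U (rank-sum) test: (U of group a, two-sided p).

    Exact permutation enumeration when both groups have <= ``exact_max_n``
    observations; otherwise normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if max(n1, n2) <= exact_max_n:
        return u, _exact_ranksum_p(a, b, u)
    # normal approximation with tie correction
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u - mu) / np.sqrt(var)
    return u, float(2 * stats.norm.sf(abs(z)))


def chi_squared(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def tmb_per_sample(
    muts: MutationTable,
    samples: list[str],
    nonsyn_classes: frozenset[str] | set[str] = NONSYNONYMOUS_CLASSES,
) -> pd.Series:
    """Tumor mutational burden: count of nonsynonymous records per sample.

    Samples absent from the table get 0; records with variant classes outside
    the declared vocabulary are excluded with a warning.
    """
    rec = muts.records
    known = rec["variant_class"].isin(muts.vocabulary)
    if (~known).any():
        logger.warning(
            "excluding %d records with unknown variant classes: %s",
            int((~known).sum()),
            sorted(rec.loc[~known, "variant_class"].unique()),
        )
        rec = rec.loc[known]
    nonsyn = rec[rec["variant_class"].isin(nonsyn_classes)]
    counts = nonsyn.groupby("sample_id").size()
    return counts.reindex(samples, fill_value=0).astype(int).rename("tmb")


def cn_burden(cn: CopyNumberTable) -> pd.DataFrame:
    """Per-sample copy-number burden: gene counts with gains (call > 0) and
    losses (call < 0), reported per focal/arm level and combined."""
    out = {}
    for level in ("focal", "arm"):
        sub = cn.calls.loc[cn.level == level]
        out[f"gain_{level}"] = (sub > 0).sum(axis=0)
        out[f"loss_{level}"] = (sub < 0).sum(axis=0)
    out["gain_total"] = (cn.calls > 0).sum(axis=0)
    out["loss_total"] = (cn.calls < 0).sum(axis=0)
    return pd.DataFrame(out)
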