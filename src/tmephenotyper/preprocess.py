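"""Expression preprocessing: log2 transform, quantile normalization, and
parametric empirical-Bayes batch adjustment (ComBat).

The default pipeline order is log2 -> quantile -> batch adjustment; each step
is independently callable and the order is configurable at the CLI level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

logger = logging.getLogger("tmephenotyper")

__all__ = ["log2_transform", "quantile_normalize", "combat_adjust"]


def log2_transform(x: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``y = log2(x + pseudocount)``; requires a raw-scale matrix."""
    if x.scale != "raw":
        raise ValueError(f"matrix is already on scale {x.scale!r}, expected 'raw'")
    vals = x.values.to_numpy(dtype=float)
    if (vals < 0).any():
        gene = x.gene_ids[int(np.where(vals < 0)[0][0])]
        raise ValueError(f"negative expression value at gene {gene!r}")
    out = np.log2(vals + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(out, index=x.values.index, columns=x.values.columns), scale="log2"
    )


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of mean order
    statistics.

    Each sample's k-th smallest value is replaced by the across-sample mean of
    k-th smallest values; ties within a sample receive the average of their
    tied order-statistic means, so the operation is idempotent and
    rank-preserving.
    """
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = x.values.to_numpy(dtype=float)
    sorted_vals = np.sort(vals, axis=0)
    target = sorted_vals.mean(axis=1)  # mean of order statistics

    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        # tied values share the average of their tied order-statistic means
        uniq, first = np.unique(np.sort(col), return_index=True)
        counts = np.diff(np.append(first, n))
        group_means = np.array(
            [target[f : f + c].mean() for f, c in zip(first, counts)]
        )
        out[:, j] = group_means[np.searchsorted(uniq, col)]
    return ExpressionMatrix(
        pd.DataFrame(out, index=x.values.index, columns=x.values.columns),
        scale=x.scale,
    )


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    z: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative solution for the empirical-Bayes batch effect estimates
    (posterior location gamma* and scale delta2*)."""
    n = (~np.isnan(z)).sum(axis=1)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = np.nansum((z - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    x: ExpressionMatrix,
    batch: pd.Series | list[str],
    parametric: bool = True,
) -> ExpressionMatrix:
    """Remove additive/multiplicative batch effects by empirical Bayes.

    Genes are standardized by grand mean and pooled variance; per-batch,
    per-gene location (gamma) and scale (delta^2) are estimated, shrunk toward
    batch-level priors (normal on gamma, inverse-gamma on delta^2 with
    moment-matched hyperparameters), removed, and the grand mean/pooled scale
    restored. Intercept-only design: no biological covariates are preserved
    explicitly, so keep batch/biology confounding moderate.

    Zero-variance genes are passed through unadjusted with a warning. The
    non-parametric prior variant is not implemented.
    """
    if not parametric:
        raise NotImplementedError("non-parametric ComBat priors are not implemented")
    batch = pd.Series(list(batch), index=x.sample_ids)
    levels = batch.unique().tolist()
    if len(levels) < 2:
        raise ValueError("need at least 2 batches")
    sizes = batch.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index[0]
        raise ValueError(f"batch {small!r} has fewer than 2 samples")

    vals = x.values.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    masks = {b: (batch == b).to_numpy() for b in levels}
    n_b = np.array([masks[b].sum() for b in levels], dtype=float)

    batch_means = np.stack([vals[:, masks[b]].mean(axis=1) for b in levels], axis=1)
    grand = batch_means @ (n_b / n_samples)
    # pooled variance of residuals around each sample's own batch mean
    fitted = np.empty_like(vals)
    for bi, b in enumerate(levels):
        fitted[:, masks[b]] = batch_means[:, [bi]]
    var_pooled = ((vals - fitted) ** 2).mean(axis=1)

    degenerate = var_pooled <= 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance genes passed through unadjusted", int(degenerate.sum())
        )
    ok = ~degenerate
    out = vals.copy()
    if ok.any():
        sd = np.sqrt(var_pooled[ok])
        z = (vals[ok] - grand[ok, None]) / sd[:, None]
        z_adj = np.empty_like(z)
        for bi, b in enumerate(levels):
            zb = z[:, masks[b]]
            g_hat = zb.mean(axis=1)
            d_hat = zb.var(axis=1, ddof=1)
            d_hat = np.maximum(d_hat, 1e-12)
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, bp = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, bp)
            z_adj[:, masks[b]] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
        out[ok] = z_adj * sd[:, None] + grand[ok, None]

    return ExpressionMatrix(
        pd.DataFrame(out, index=x.values.index, columns=x.values.columns),
        scale=x.scale,
    )
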