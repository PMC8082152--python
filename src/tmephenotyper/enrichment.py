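"""Single-sample gene-set enrichment (ssGSEA) scoring.

For one sample, genes are ranked by expression (rank N = highest, average
ranks for ties). Walking the gene list from highest to lowest rank, the
weighted in-set empirical CDF at step k is

    ECDF_in(k)  = sum_{g in G, reached by k} R_g^alpha / sum_{g in G} R_g^alpha

and the out-of-set ECDF is the unweighted fraction of non-members reached:

    ECDF_out(k) = #(out-set genes reached by k) / (N - |G|).

The enrichment score is the sum of the stepwise differences,
ES = sum_k [ECDF_in(k) - ECDF_out(k)]. High expression of set members early
in the walk pushes ECDF_in ahead of ECDF_out and the score up.

The walk order breaks expression ties by gene-id lexical order so scores are
bitwise reproducible; the rank *weights* still use average ranks, so the
score is invariant to any strictly increasing per-sample transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("tmephenotyper")

__all__ = [
    "ScoreMatrix",
    "ssgsea_score",
    "immune_stromal_scores",
    "cycle_step_scores",
]


@dataclass
class ScoreMatrix:
    """Sample x signature enrichment scores with a normalization tag."""

    values: pd.DataFrame  # samples x signatures
    normalization: str = "raw"  # or "minmax"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("score matrix contains non-finite values")
        if self.normalization == "minmax":
            v = self.values.to_numpy()
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("minmax-normalized scores must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.values.columns)


def _sample_es(
    expr: np.ndarray,
    gene_ids: np.ndarray,
    member_masks: dict[str, np.ndarray],
    alpha: float,
) -> dict[str, float]:
    """ES for every set in one sample. ``member_masks`` maps set name to a
    boolean membership vector over genes."""
    n = expr.shape[0]
    ranks = n + 1 - rankdata(-expr)  # average ranks, rank N = highest
    # walk order: decreasing expression, ties by gene id (lexical)
    order = np.lexsort((gene_ids, -expr))
    out: dict[str, float] = {}
    for name, mask in member_masks.items():
        m = mask[order]
        w = ranks[order] ** alpha
        w[~m] = 0.0
        n_in = int(mask.sum())
        cum_in = np.cumsum(w) / w.sum()
        cum_out = np.cumsum(~m) / (n - n_in)
        out[name] = float(np.sum(cum_in - cum_out))
    return out


def ssgsea_score(
    x: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> ScoreMatrix:
    """ssGSEA enrichment score of every set in every sample.

    Genes in a set but absent from the matrix are dropped (the overlap
    fraction is logged); a set with no overlapping genes, or covering every
    gene in the matrix, is an error. With ``normalize`` the whole matrix is
    linearly rescaled by its global range onto [0, 1].
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    gene_index = pd.Index(x.gene_ids)
    n = len(gene_index)
    masks: dict[str, np.ndarray] = {}
    for name, genes in sets.items():
        mask = gene_index.isin(genes)
        n_in = int(mask.sum())
        if n_in == 0:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if n_in == n:
            raise ValueError(
                f"gene set {name!r} covers every gene; out-of-set ECDF undefined"
            )
        if n_in < len(genes):
            logger.info(
                "gene set %s: overlap %d/%d genes", name, n_in, len(genes)
            )
        masks[name] = mask

    gene_ids = gene_index.to_numpy()
    vals = x.values.to_numpy(dtype=float)
    rows = {
        sample: _sample_es(vals[:, j], gene_ids, masks, alpha)
        for j, sample in enumerate(x.sample_ids)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")[list(masks)]
    df.index.name = "sample_id"
    if normalize:
        lo, hi = df.to_numpy().min(), df.to_numpy().max()
        if hi - lo <= 0:
            raise ValueError("cannot min-max normalize a constant score matrix")
        df = (df - lo) / (hi - lo)
        return ScoreMatrix(df, normalization="minmax")
    return ScoreMatrix(df, normalization="raw")


def immune_stromal_scores(
    x: ExpressionMatrix,
    immune_set: list[str],
    stromal_set: list[str],
    alpha: float = 0.25,
) -> ScoreMatrix:
    """ImmuneScore / StromalScore: ssGSEA on the two aggregate signatures.

    Higher score = more immune / stromal signal in the sample.
    """
    sets = GeneSetCollection(
        {"ImmuneScore": list(immune_set), "StromalScore": list(stromal_set)}
    )
    return ssgsea_score(x, sets, alpha=alpha)


def cycle_step_scores(
    x: ExpressionMatrix,
    step_sets: GeneSetCollection,
    alpha: float = 0.25,
) -> ScoreMatrix:
    """Scores for the seven cancer-immunity cycle steps (antigen release,
    presentation, priming, trafficking, infiltration, recognition, killing).

    ``step_sets`` must contain exactly seven sets named step1..step7.
    """
    expected = [f"step{i}" for i in range(1, 8)]
    names = step_sets.names()
    if sorted(names) != expected:
        raise ValueError(
            f"need exactly 7 sets labeled step1..step7, got {names}"
        )
    ordered = step_sets.subset(expected)
    return ssgsea_score(x, ordered, alpha=alpha)
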