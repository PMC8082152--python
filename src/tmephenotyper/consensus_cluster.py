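"""Resampled k-means consensus clustering of the cell-type score matrix.

Samples are repeatedly subsampled (default 80%) and clustered with k-means;
the consensus matrix records, for each pair of samples, the fraction of
co-sampled repetitions in which they landed in the same cluster. The number
of clusters is chosen by minimizing PAC (proportion of ambiguous clustering:
consensus entries far from both 0 and 1); the empirical consensus CDF and its
delta-area are reported as diagnostics. Final assignment cuts an
average-linkage tree on 1 - consensus, and labels are renamed A, B, C, ... in
order of ascending mean infiltration so that "A = coldest, last letter =
hottest" holds across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .enrichment import ScoreMatrix

__all__ = [
    "ConsensusResult",
    "ClusterAssignment",
    "kmeans_cluster",
    "consensus_matrix",
    "select_k",
    "assign_clusters",
    "consensus_cluster",
    "adjusted_rand_score",
]


@dataclass
class ClusterAssignment:
    """sample_id -> cluster label; labels are 'A', 'B', ... with 'A' the
    lowest-infiltration cluster when scores were supplied for ordering."""

    labels: pd.Series

    @property
    def k(self) -> int:
        return self.labels.nunique()


@dataclass
class ConsensusResult:
    """Per-k consensus matrices with their stability diagnostics."""

    consensus: dict[int, pd.DataFrame]
    pac: dict[int, float]
    delta_area: dict[int, float]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]
    chosen_k: int
    assignment: ClusterAssignment | None = None
    diagnostics: dict = field(default_factory=dict)


def _zscore_columns(df: pd.DataFrame) -> np.ndarray:
    vals = df.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (vals - vals.mean(axis=0)) / sd


def kmeans_cluster(
    scores: ScoreMatrix, k: int, n_init: int = 10, seed: int = 0,
    max_iter: int = 50,
) -> ClusterAssignment:
    """Euclidean k-means on the z-scored signature columns (k-means++,
    best of ``n_init`` restarts by within-cluster sum of squares)."""
    n = len(scores.sample_ids)
    if k < 1 or k > n:
        raise ValueError(f"k={k} invalid for {n} samples")
    z = _zscore_columns(scores.values)
    km = KMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter,
        random_state=int(seed) % (2**32), init="k-means++",
    ).fit(z)
    labels = pd.Series(km.labels_, index=scores.sample_ids, name="cluster")
    return ClusterAssignment(labels)


def consensus_matrix(
    scores: ScoreMatrix,
    k: int,
    reps: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Consensus co-clustering frequencies over subsampled k-means runs.

    consensus(i, j) = (#reps i and j co-clustered) / (#reps both sampled);
    pairs never co-sampled are set to 0 with a warning. The diagonal is 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    n = len(scores.sample_ids)
    m = int(np.floor(subsample_frac * n))
    if m < k:
        raise ValueError(f"subsample of {m} samples cannot support k={k}")

    z = _zscore_columns(scores.values)
    ss = np.random.SeedSequence([int(seed), k, 110])
    rng = np.random.default_rng(ss)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for rep in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(
            n_clusters=k, n_init=n_init, max_iter=max_iter,
            random_state=int(rng.integers(2**32)), init="k-means++",
        ).fit(z[idx])
        lab = km.labels_
        same = (lab[:, None] == lab[None, :]).astype(float)
        co_cluster[np.ix_(idx, idx)] += same
        co_sample[np.ix_(idx, idx)] += 1.0
    never = co_sample == 0
    if never.any() and reps > 1:
        import logging

        logging.getLogger("tmephenotyper").warning(
            "%d sample pairs never co-sampled; consensus set to 0",
            int((never.sum() - never.trace()) // 2),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(never, 0.0, co_cluster / np.where(never, 1.0, co_sample))
    np.fill_diagonal(cons, 1.0)
    cons = 0.5 * (cons + cons.T)  # exact symmetry
    return pd.DataFrame(cons, index=scores.sample_ids, columns=scores.sample_ids)


def _consensus_stats(cons: pd.DataFrame) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(PAC, CDF area, CDF x, CDF y) over the upper-triangle entries."""
    vals = cons.to_numpy()
    iu = np.triu_indices_from(vals, k=1)
    v = np.sort(vals[iu])
    pac = float(np.mean((v > 0.1) & (v < 0.9)))
    x = np.concatenate([[0.0], v, [1.0]])
    y = np.concatenate([[0.0], np.arange(1, len(v) + 1) / len(v), [1.0]])
    # area under the ECDF on [0, 1] via step integration
    area = float(np.sum(np.diff(x) * y[:-1]))
    return pac, area, x, y


def select_k(
    consensus: dict[int, pd.DataFrame],
) -> tuple[int, dict[int, float], dict[int, float], dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Choose k by minimal PAC; report delta-area of the consensus CDF too.

    Returns (chosen_k, pac_per_k, delta_area_per_k, cdf_per_k). Exact ties in
    PAC go to the larger k: when a finer partition is exactly as unambiguous
    as a coarser one, the finer one reflects additional stable structure
    (nested well-separated clusters give PAC 0 at several k).
    """
    ks = sorted(consensus)
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate k values")
    pac: dict[int, float] = {}
    area: dict[int, float] = {}
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in ks:
        vals = consensus[k].to_numpy()
        iu = np.triu_indices_from(vals, k=1)
        if np.allclose(vals[iu], vals[iu][0]):
            raise ValueError(f"degenerate consensus matrix at k={k}")
        pac[k], area[k], x, y = _consensus_stats(consensus[k])
        cdf[k] = (x, y)
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    chosen = min(ks, key=lambda k: (pac[k], -k))
    return chosen, pac, delta, cdf


def assign_clusters(
    consensus: pd.DataFrame,
    k: int,
    scores: ScoreMatrix | None = None,
) -> ClusterAssignment:
    """Cut an average-linkage tree of 1 - consensus at k clusters.

    If ``scores`` is given, cluster labels are renamed so 'A' has the lowest
    mean signature score (coldest) and the last letter the highest (hottest);
    otherwise labels follow cluster size.
    """
    n = consensus.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} invalid for {n} samples")
    dist = 1.0 - consensus.to_numpy()
    np.fill_diagonal(dist, 0.0)
    if k == 1:
        raw = np.zeros(n, dtype=int)
    else:
        tree = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(tree, t=k, criterion="maxclust") - 1
        if len(np.unique(raw)) != k:
            raise ValueError(
                f"consensus tree does not separate into {k} clusters"
            )
    samples = list(consensus.index)
    raw_s = pd.Series(raw, index=samples)
    if scores is not None:
        mean_score = scores.values.mean(axis=1)
        order = sorted(
            np.unique(raw), key=lambda c: mean_score[raw_s == c].mean()
        )
    else:
        order = sorted(np.unique(raw), key=lambda c: (-(raw_s == c).sum(), c))
    rename = {c: chr(ord("A") + i) for i, c in enumerate(order)}
    labels = raw_s.map(rename)
    labels.name = "cluster"
    return ClusterAssignment(labels)


def consensus_cluster(
    scores: ScoreMatrix,
    k_range: range | list[int] = range(2, 7),
    reps: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 50,
) -> ConsensusResult:
    """Full consensus-clustering pass: per-k consensus matrices, PAC-based k
    selection, and infiltration-ordered final assignment."""
    cons = {
        k: consensus_matrix(
            scores, k, reps=reps, subsample_frac=subsample_frac,
            seed=seed, n_init=n_init, max_iter=max_iter,
        )
        for k in k_range
    }
    chosen, pac, delta, cdf = select_k(cons)
    assignment = assign_clusters(cons[chosen], chosen, scores=scores)
    return ConsensusResult(
        consensus=cons, pac=pac, delta_area=delta, cdf=cdf,
        chosen_k=chosen, assignment=assignment,
    )
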