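"""Synthetic cohorts with planted immune-phenotype structure.

The generator emulates the statistical shape of a bulk-expression
immuno-phenotyping study: a gene universe in which disjoint marker sets tag
immune cell types; three phenotypes (A = cold, low infiltration of every cell
type; B = mixed, high infiltration of a designated minority of cell types;
C = hot, high infiltration of most cell types); optional per-batch location
shifts; survival times whose hazard is log-linear in a planted infiltration
score; and response labels whose log-odds are linear in the same score.

Everything is deterministic given a seed (numpy PCG64 streams spawned from a
single SeedSequence), so downstream recovery tests have an exact ground truth
to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    CopyNumberTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
)

__all__ = [
    "SyntheticTruth",
    "generate_signatures",
    "generate_cohort",
    "generate_mutations",
    "generate_copy_number",
]

PHENOTYPES = ("A", "B", "C")

#: number of cell types that phenotype B infiltrates highly (the "mixed"
#: cluster); the first ``N_MIXED_TYPES`` signatures are the designated subset.
N_MIXED_TYPES = 8

#: per-sample intensity noise around the phenotype mean (truncated at 0)
INTENSITY_SD = 0.25

#: Gaussian expression noise SD on the log2 scale
NOISE_SD = 1.0

#: baseline log2 expression level
BASELINE = 6.0


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic cohort."""

    phenotype: pd.Series  # sample -> {A,B,C}
    intensity: pd.DataFrame  # samples x cell types, >= 0
    de_genes: pd.Series  # planted DE gene -> true logFC (empty if none)
    batch: pd.Series  # sample -> batch label
    log_hazard_coef: float  # per SD of mean infiltration
    response_prob: pd.Series  # sample -> true responder probability
    extras: dict = field(default_factory=dict)

    @property
    def mean_infiltration(self) -> pd.Series:
        return self.intensity.mean(axis=1)


def generate_signatures(
    n_celltypes: int = 24,
    genes_per_set: int = 20,
    universe_size: int = 5000,
    seed: int = 0,
) -> tuple[GeneSetCollection, list[str]]:
    """Build ``n_celltypes`` disjoint marker sets within a gene universe.

    Returns the collection plus the full gene universe (marker genes first,
    then background). Gene ids are zero-padded so lexical order equals
    construction order.
    """
    if n_celltypes < 1 or genes_per_set < 1:
        raise ValueError("n_celltypes and genes_per_set must be positive")
    n_marker = n_celltypes * genes_per_set
    if n_marker > universe_size:
        raise ValueError(
            f"{n_celltypes} sets of {genes_per_set} genes exceed a "
            f"{universe_size}-gene universe"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 417]))
    width = len(str(universe_size))
    universe = [f"g{idx:0{width}d}" for idx in range(universe_size)]
    marker_idx = rng.choice(universe_size, size=n_marker, replace=False)
    sets = {}
    for t in range(n_celltypes):
        genes = [universe[i] for i in marker_idx[t * genes_per_set : (t + 1) * genes_per_set]]
        sets[f"celltype_{t + 1:02d}"] = sorted(genes)
    return GeneSetCollection(sets), universe


def _phenotype_means(celltypes: list[str]) -> pd.DataFrame:
    """Mean infiltration intensity per phenotype per cell type: C high for
    every type, A low, B high on the designated minority subset."""
    mu = pd.DataFrame(0.0, index=list(PHENOTYPES), columns=celltypes)
    mu.loc["C", :] = 1.0
    mu.loc["B", celltypes[:N_MIXED_TYPES]] = 1.0
    return mu


def _censoring_horizon(t: np.ndarray, fraction: float) -> float:
    """Administrative-censoring horizon c such that uniform(0, c) censoring
    yields approximately the requested censored fraction (bisection on the
    expected fraction given the drawn event times)."""
    if fraction <= 0:
        return float(np.inf)
    lo, hi = 1e-9, float(t.max()) * 50
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(np.minimum(t / mid, 1.0)))  # P(U(0,mid) < t_i)
        if frac > fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    n_samples: int = 150,
    phenotype_props: tuple[float, float, float] = (0.4, 0.35, 0.25),
    effect_size: float = 1.5,
    batch_shifts: list[float] | None = None,
    seed: int = 0,
    signatures: GeneSetCollection | None = None,
    universe: list[str] | None = None,
    log_hazard_coef: float = -0.43,
    censoring_fraction: float = 0.3,
    response_intercept: float = -1.0,
    response_slope: float = 1.0,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Simulate an expression cohort with three planted immune phenotypes.

    Marker-gene expression is ``BASELINE + noise + effect_size * intensity``
    where per-sample intensities are drawn around phenotype means; background
    genes are pure noise. Batch shifts (one per batch, samples split evenly)
    are added to every gene. Survival is exponential with log-hazard
    ``log_hazard_coef`` per SD of mean infiltration, censored administratively
    (uniform horizon calibrated to ``censoring_fraction``); response labels
    are Bernoulli with logit linear in the same standardized score.
    """
    props = np.asarray(phenotype_props, dtype=float)
    if len(props) != 3 or (props <= 0).any():
        raise ValueError("phenotype_props must be three positive proportions")
    if abs(props.sum() - 1) > 1e-8:
        raise ValueError("phenotype proportions must sum to 1")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_samples < 3 * len(PHENOTYPES):
        raise ValueError(f"need at least {3 * len(PHENOTYPES)} samples for 3 phenotypes")
    if batch_shifts is None:
        batch_shifts = [0.0]

    ss = np.random.SeedSequence([seed, 20210415])
    r_assign, r_int, r_expr, r_surv, r_resp = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    if signatures is None or universe is None:
        signatures, universe = generate_signatures(seed=seed)
    celltypes = signatures.names()

    # phenotype labels: deterministic counts (largest remainder), shuffled
    counts = np.floor(props * n_samples).astype(int)
    while counts.sum() < n_samples:
        counts[np.argmax(props * n_samples - counts)] += 1
    labels = np.repeat(list(PHENOTYPES), counts)
    r_assign.shuffle(labels)
    samples = [f"s{idx + 1:04d}" for idx in range(n_samples)]
    phenotype = pd.Series(labels, index=samples, name="phenotype")

    mu = _phenotype_means(celltypes)
    intensity = mu.loc[phenotype].to_numpy()
    intensity = intensity + r_int.normal(0.0, INTENSITY_SD, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    intensity = pd.DataFrame(intensity, index=samples, columns=celltypes)

    # expression: background noise everywhere, marker boost for set members
    n_genes = len(universe)
    expr = BASELINE + r_expr.normal(0.0, NOISE_SD, size=(n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(universe)}
    for t, genes in signatures.items():
        rows = [gene_pos[g] for g in genes]
        expr[rows, :] += effect_size * intensity[t].to_numpy()[None, :]

    # batch structure: samples split evenly over batches, shift added per batch
    n_batches = len(batch_shifts)
    batch_idx = np.arange(n_samples) % n_batches
    for b, shift in enumerate(batch_shifts):
        expr[:, batch_idx == b] += shift
    batch = pd.Series(
        [f"batch{b + 1}" for b in batch_idx], index=samples, name="batch"
    )

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=universe, columns=samples), scale="log2"
    )

    # survival: exponential, log-hazard linear in standardized mean intensity
    score = intensity.mean(axis=1).to_numpy()
    z = (score - score.mean()) / (score.std() if score.std() > 0 else 1.0)
    rate = 0.02 * np.exp(log_hazard_coef * z)  # baseline median OS ~ 35 months
    t_event = r_surv.exponential(1.0 / rate)
    horizon = _censoring_horizon(t_event, censoring_fraction)
    c = r_surv.uniform(0.0, horizon, size=n_samples)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)

    # response: Bernoulli with logit linear in the same score
    logit = response_intercept + response_slope * z
    p_resp = 1.0 / (1.0 + np.exp(-logit))
    responder = r_resp.uniform(size=n_samples) < p_resp
    fine = np.where(
        responder,
        np.where(r_resp.uniform(size=n_samples) < 0.4, "CR", "PR"),
        np.where(r_resp.uniform(size=n_samples) < 0.5, "SD", "PD"),
    )

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "response": fine,
                "batch": batch,
                "age": np.round(r_resp.normal(68, 9, size=n_samples)),
                "sex": r_resp.choice(["M", "F"], size=n_samples, p=[0.75, 0.25]),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    truth = SyntheticTruth(
        phenotype=phenotype,
        intensity=intensity,
        de_genes=pd.Series(dtype=float),
        batch=batch,
        log_hazard_coef=log_hazard_coef,
        response_prob=pd.Series(p_resp, index=samples),
        extras={"event_time": pd.Series(t_event, index=samples)},
    )
    return matrix, clinical, truth


def generate_mutations(
    n_samples: int,
    cluster_labels: pd.Series,
    mean_tmb_per_cluster: dict[str, float],
    seed: int = 0,
    universe: list[str] | None = None,
    silent_fraction: float = 0.3,
) -> MutationTable:
    """Poisson per-sample mutation counts with cluster-specific means.

    Each record draws a gene uniformly from the universe and a variant class
    (nonsynonymous with probability ``1 - silent_fraction``).
    """
    if any(m < 0 for m in mean_tmb_per_cluster.values()):
        raise ValueError("mean TMB must be >= 0")
    unknown = set(cluster_labels.index) - set(cluster_labels.index[:n_samples])
    if len(cluster_labels) != n_samples or unknown:
        raise ValueError("cluster_labels must cover exactly the cohort samples")
    missing = set(cluster_labels.unique()) - set(mean_tmb_per_cluster)
    if missing:
        raise ValueError(f"no TMB mean for clusters {sorted(missing)}")
    if universe is None:
        _, universe = generate_signatures(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77001]))
    nonsyn = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"]
    rows = []
    for sample, cluster in cluster_labels.items():
        n_mut = rng.poisson(mean_tmb_per_cluster[cluster])
        for _ in range(n_mut):
            gene = universe[rng.integers(len(universe))]
            if rng.uniform() < silent_fraction:
                vc = "Silent"
            else:
                vc = nonsyn[rng.integers(len(nonsyn))]
            rows.append((sample, gene, vc))
    df = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_class"])
    return MutationTable(df)


def generate_copy_number(
    cluster_labels: pd.Series,
    n_genes: int = 200,
    gain_rate_per_cluster: dict[str, float] | None = None,
    loss_rate_per_cluster: dict[str, float] | None = None,
    seed: int = 0,
) -> CopyNumberTable:
    """Copy-number call table with planted per-cluster gain/loss burden.

    Per sample, each gene is gained (call +1/+2) with its cluster's gain rate
    and lost (-1/-2) with its loss rate; half of genes are tagged focal, half
    arm. Defaults plant a burden ordering B > A > C.
    """
    gain_rate_per_cluster = gain_rate_per_cluster or {"A": 0.10, "B": 0.20, "C": 0.05}
    loss_rate_per_cluster = loss_rate_per_cluster or {"A": 0.10, "B": 0.20, "C": 0.05}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 88002]))
    genes = [f"cn_g{idx:04d}" for idx in range(n_genes)]
    samples = list(cluster_labels.index)
    calls = np.zeros((n_genes, len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        cl = cluster_labels[sample]
        u = rng.uniform(size=n_genes)
        g_rate = gain_rate_per_cluster[cl]
        l_rate = loss_rate_per_cluster[cl]
        gained = u < g_rate
        lost = (u >= g_rate) & (u < g_rate + l_rate)
        calls[gained, j] = rng.choice([1, 2], size=int(gained.sum()))
        calls[lost, j] = rng.choice([-1, -2], size=int(lost.sum()))
    level = pd.Series(
        ["focal" if i < n_genes // 2 else "arm" for i in range(n_genes)], index=genes
    )
    return CopyNumberTable(pd.DataFrame(calls, index=genes, columns=samples), level)


def plant_de_genes(
    matrix: ExpressionMatrix,
    group_a: list[str],
    n_de: int,
    logfc: float,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Shift ``n_de`` randomly chosen genes by +/- ``logfc`` in ``group_a``,
    returning the modified matrix and the planted gene -> true logFC map."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55003]))
    genes = matrix.gene_ids
    if n_de > len(genes):
        raise ValueError("more DE genes than genes in the matrix")
    chosen = rng.choice(len(genes), size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    values = matrix.values.copy()
    cols = [s for s in group_a if s in values.columns]
    for idx, sign in zip(chosen, signs):
        values.iloc[idx, [values.columns.get_loc(c) for c in cols]] += sign * logfc
    truth = pd.Series(signs * logfc, index=[genes[i] for i in chosen])
    return ExpressionMatrix(values, scale=matrix.scale), truth
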