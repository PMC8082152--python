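import numpy as np
import pandas as pd
import pytest

from tmephenotyper.enrichment import ScoreMatrix
from tmephenotyper.io_formats import ExpressionMatrix, GeneSetCollection
from tmephenotyper.synthetic_data import generate_cohort, generate_signatures


@pytest.fixture(scope="session")
def small_cohort():
    """One 60-sample synthetic cohort with planted 3-phenotype structure."""
    signatures, universe = generate_signatures(seed=11)
    expr, clinical, truth = generate_cohort(
        n_samples=60, effect_size=1.5, seed=11,
        signatures=signatures, universe=universe,
    )
    return {
        "signatures": signatures,
        "universe": universe,
        "expr": expr,
        "clinical": clinical,
        "truth": truth,
    }


@pytest.fixture()
def tiny_matrix():
    """4-gene, 2-sample matrix with a clean ranking in sample s1."""
    df = pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [1.0, 4.0, 2.0, 3.0]},
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(df, scale="log2")


@pytest.fixture()
def random_scores():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        rng.normal(size=(40, 8)),
        index=[f"s{i}" for i in range(40)],
        columns=[f"sig{j}" for j in range(8)],
    )
    return ScoreMatrix(df)


def brute_force_es(expr: dict, set_genes: set, alpha: float) -> float:
    """Independent positional-walk ssGSEA oracle.

    Ranks are recomputed from scratch (count-based average ranks, highest
    value = rank N), the walk enumerates genes in decreasing-value order with
    lexical tie-break, and both ECDFs are accumulated step by step.
    """
    n = len(expr)
    values = list(expr.values())

    def avg_rank(g):
        v = expr[g]
        less = sum(1 for u in values if u < v)
        ties = sum(1 for u in values if u == v)
        return less + (ties + 1) / 2.0

    walk = sorted(expr, key=lambda g: (-expr[g], g))
    denom_in = sum(avg_rank(g) ** alpha for g in set_genes)
    n_out = n - len(set_genes)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in walk:
        if g in set_genes:
            cum_in += avg_rank(g) ** alpha
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es
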