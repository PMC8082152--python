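"""Per-patient immune-cell score (ICscore) from the cell-type score matrix.

The score is the projection of each sample onto the first principal component
of the z-scored signature columns (correlation PCA). The sign of the
component is fixed so that the score correlates positively with the
per-sample mean of z-scored signatures: a high ICscore literally means high
overall immune infiltration. A trained model (column means/SDs, loadings,
orientation) can be projected onto new cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import ScoreMatrix

logger = logging.getLogger("tmephenotyper")

__all__ = ["ICScoreResult", "compute_icscore", "project_icscore"]


@dataclass
class ICScoreResult:
    """PC1-based infiltration score with the fitted projection model."""

    scores: pd.Series  # per-sample ICscore (zero mean on the training cohort)
    loadings: pd.Series  # unit-norm loading per signature
    variance_explained: float  # fraction of total variance on PC1
    orientation: int  # +1 or -1; applied sign
    means: pd.Series  # training column means (for projection)
    sds: pd.Series  # training column SDs

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signatures": list(self.loadings.index),
            "loadings": self.loadings.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "orientation": self.orientation,
            "variance_explained": self.variance_explained,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ICScoreResult":
        d = json.loads(Path(path).read_text())
        sig = d["signatures"]
        return cls(
            scores=pd.Series(dtype=float),
            loadings=pd.Series(d["loadings"], index=sig),
            variance_explained=d["variance_explained"],
            orientation=int(d["orientation"]),
            means=pd.Series(d["means"], index=sig),
            sds=pd.Series(d["sds"], index=sig),
        )


def compute_icscore(scores: ScoreMatrix) -> ICScoreResult:
    """Fit the PCA scoring model and score the training cohort.

    Zero-variance signature columns are dropped with a warning; at least two
    must survive. Scores have zero mean over the cohort by construction.
    """
    df = scores.values
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 signatures")
    if df.isna().any().any():
        raise ValueError("score matrix contains missing values")
    sds = df.std(axis=0, ddof=1)
    keep = sds > 0
    if (~keep).any():
        logger.warning(
            "dropping %d zero-variance signatures: %s",
            int((~keep).sum()), list(sds.index[~keep]),
        )
    df = df.loc[:, keep]
    if df.shape[1] < 2:
        raise ValueError("fewer than 2 signatures with non-zero variance")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    z = (df - means) / sds

    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    loadings = vt[0]
    raw = z.to_numpy() @ loadings
    var_explained = float(s[0] ** 2 / np.sum(s**2))

    # orient so ICscore tracks mean infiltration upward
    mean_z = z.mean(axis=1).to_numpy()
    corr = np.corrcoef(raw, mean_z)[0, 1] if np.std(raw) > 0 else 0.0
    orientation = -1 if corr < 0 else 1
    ic = pd.Series(orientation * raw, index=df.index, name="ICscore")

    return ICScoreResult(
        scores=ic,
        loadings=pd.Series(loadings, index=df.columns),
        variance_explained=var_explained,
        orientation=orientation,
        means=means,
        sds=sds,
    )


def project_icscore(model: ICScoreResult, new_scores: ScoreMatrix) -> pd.Series:
    """Score a new cohort with a fitted model: standardize by the model's
    stored means/SDs and project onto its stored, oriented loadings."""
    missing = [s for s in model.loadings.index if s not in new_scores.values.columns]
    if missing:
        raise ValueError(f"new score matrix lacks signatures: {missing}")
    z = (new_scores.values[model.loadings.index] - model.means) / model.sds
    raw = z.to_numpy() @ model.loadings.to_numpy()
    return pd.Series(model.orientation * raw, index=new_scores.values.index, name="ICscore")
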