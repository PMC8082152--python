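"""Readers, writers and in-memory containers for the pipeline's tabular formats.

Gene identifiers are treated as opaque strings throughout: the pipeline makes
no attempt to map between symbol and Entrez namespaces, which is
cohort-specific plumbing that belongs upstream of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tmephenotyper")

__all__ = [
    "GeneSetCollection",
    "ExpressionMatrix",
    "ClinicalTable",
    "MutationTable",
    "CopyNumberTable",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_mutations",
    "write_mutations",
    "read_copy_number",
    "write_copy_number",
    "align_samples",
    "COPY_NUMBER_CALLS",
    "DEFAULT_VARIANT_VOCABULARY",
    "NONSYNONYMOUS_CLASSES",
]

COPY_NUMBER_CALLS = (-2, -1, 0, 1, 2)

#: MAF-style variant classes the mutation tables may carry.
DEFAULT_VARIANT_VOCABULARY = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
    "Silent",
    "Intron",
    "3'UTR",
    "5'UTR",
)

#: Classes counted toward tumor mutational burden.
NONSYNONYMOUS_CLASSES = frozenset(DEFAULT_VARIANT_VOCABULARY[:9])


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class GeneSetCollection:
    """An ordered mapping from gene-set name to a list of member genes.

    Set names are unique, every set is non-empty, and duplicate genes within a
    set are collapsed (first occurrence wins).
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            if not name:
                raise ValueError("gene-set name must be non-empty")
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                if not g:
                    raise ValueError(f"gene set {name!r} contains an empty gene id")
                if g in seen:
                    logger.warning("gene set %s: duplicate gene %s collapsed", name, g)
                else:
                    seen[g] = None
            cleaned[name] = list(seen)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: list[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: list(self.sets[n]) for n in names})


@dataclass
class ExpressionMatrix:
    """A gene x sample real-valued expression matrix with a scale tag.

    ``scale`` tracks the units: ``"raw"`` (non-negative linear values),
    ``"log2"`` or ``"normalized"``. Operations that assume a particular scale
    check the tag rather than guessing from the values.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, samples].copy(), scale=self.scale)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations indexed by sample id.

    Canonical columns when present: ``time`` (survival months, > 0), ``event``
    (0/1), ``response`` (CR/PR/SD/PD), ``batch``; everything else is kept as
    an opaque covariate. Missing covariates are allowed (NaN); samples missing
    time or event are excluded from survival operations with a warning.
    """

    data: pd.DataFrame

    RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        if "time" in self.data.columns:
            t = pd.to_numeric(self.data["time"], errors="coerce")
            bad = t[t.notna() & (t <= 0)]
            if len(bad):
                raise ValueError(
                    f"non-positive survival time for sample {bad.index[0]!r}"
                )
            self.data["time"] = t
        if "event" in self.data.columns:
            e = pd.to_numeric(self.data["event"], errors="coerce")
            bad = e[e.notna() & ~e.isin([0, 1])]
            if len(bad):
                raise ValueError(f"event must be 0/1; sample {bad.index[0]!r}")
            self.data["event"] = e
        if "response" in self.data.columns:
            r = self.data["response"].dropna()
            bad = r[~r.isin(self.RESPONSE_LEVELS)]
            if len(bad):
                raise ValueError(
                    f"unknown response label {bad.iloc[0]!r} for {bad.index[0]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def survival_subset(self) -> pd.DataFrame:
        """Rows with usable time and event; logs how many were dropped."""
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise ValueError("clinical table has no time/event columns")
        ok = self.data["time"].notna() & self.data["event"].notna()
        n_drop = int((~ok).sum())
        if n_drop:
            logger.warning("dropping %d samples without time/event", n_drop)
        return self.data.loc[ok]


@dataclass
class MutationTable:
    """MAF-like records of (sample_id, gene_id, variant_class)."""

    records: pd.DataFrame  # columns: sample_id, gene_id, variant_class
    vocabulary: tuple[str, ...] = DEFAULT_VARIANT_VOCABULARY

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "variant_class"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        if self.records[list(required)].isna().any().any():
            raise ValueError("mutation table contains missing fields")


@dataclass
class CopyNumberTable:
    """Gene x sample integer copy-number calls in {-2..2} with a per-gene
    focal/arm level tag."""

    calls: pd.DataFrame  # genes x samples, int
    level: pd.Series  # per gene: "focal" or "arm"

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise ValueError("duplicate ids in copy-number table")
        vals = self.calls.to_numpy()
        if not np.isin(vals, COPY_NUMBER_CALLS).all():
            bad = vals[~np.isin(vals, COPY_NUMBER_CALLS)][0]
            raise ValueError(f"invalid copy-number call {bad!r}")
        if not self.level.index.equals(self.calls.index):
            raise ValueError("level tags must cover exactly the genes")
        if not self.level.isin(["focal", "arm"]).all():
            raise ValueError("level tag must be 'focal' or 'arm'")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``; description is discarded.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
            if not sets[name]:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_matrix(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a delimited gene x sample table; first column gene ids, header row
    sample ids. Returns a matrix tagged ``scale="raw"``."""
    path = Path(path)
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.isna().any().any():
        rows, cols = np.where(df.isna())
        raise FormatError(
            f"{path}: missing cell at gene {df.index[rows[0]]!r}, "
            f"sample {df.columns[cols[0]]!r}"
        )
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                gene = df.index[bad.isna()][0]
                raise FormatError(
                    f"{path}: non-numeric cell {df.loc[gene, col]!r} at "
                    f"gene {gene!r}, sample {col!r}"
                ) from None
        raise
    return ExpressionMatrix(values, scale="raw")


def write_matrix(x: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    x.values.to_csv(path, sep=sep, index_label="gene_id")


def read_clinical(path: str | Path, sep: str | None = None) -> ClinicalTable:
    path = Path(path)
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: no sample_id column")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path: str | Path, sep: str = "\t") -> None:
    c.data.to_csv(path, sep=sep, index_label="sample_id")


def read_mutations(path: str | Path, sep: str = "\t") -> MutationTable:
    """Read a minimal MAF-like table (Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification)."""
    df = pd.read_csv(path, sep=sep)
    rename = {
        "Tumor_Sample_Barcode": "sample_id",
        "Hugo_Symbol": "gene_id",
        "Variant_Classification": "variant_class",
    }
    df = df.rename(columns=rename)
    return MutationTable(df[["sample_id", "gene_id", "variant_class"]])


def write_mutations(m: MutationTable, path: str | Path, sep: str = "\t") -> None:
    out = m.records.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "gene_id": "Hugo_Symbol",
            "variant_class": "Variant_Classification",
        }
    )
    out.to_csv(path, sep=sep, index=False)


def read_copy_number(path: str | Path, sep: str = "\t") -> CopyNumberTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if "level" not in df.columns:
        raise FormatError(f"{path}: no 'level' column of focal/arm tags")
    level = df["level"]
    calls = df.drop(columns="level").astype(int)
    return CopyNumberTable(calls, level)


def write_copy_number(t: CopyNumberTable, path: str | Path, sep: str = "\t") -> None:
    out = t.calls.copy()
    out.insert(0, "level", t.level)
    out.to_csv(path, sep=sep, index_label="gene_id")


def align_samples(
    x: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both tables to their sample-id intersection (expression
    column order), logging how many samples each side loses."""
    shared = [s for s in x.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between expression and clinical tables")
    dropped = (len(x.sample_ids) - len(shared)) + (len(clinical.sample_ids) - len(shared))
    if dropped:
        logger.warning("sample alignment dropped %d unmatched samples", dropped)
    return x.subset_samples(shared), ClinicalTable(clinical.data.loc[shared].copy())
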