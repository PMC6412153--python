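"""Domain types, readers/writers and configuration.

The pipeline operates on three tables — a genes x samples TPM matrix, a
per-gene annotation (symbol, chromosome, coding biotype) and a per-donor
clinical metadata table using dbGaP-style variable names (SEX, AGE, MHT2D,
MHARTHTS, ...) — plus TSV result tables.  TSV is the canonical dialect;
GCT 1.2 (the format expression matrices are commonly distributed in) is
supported read-only.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("nervede")

__all__ = [
    "ParseError",
    "SchemaError",
    "ExpressionMatrix",
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_metadata",
    "write_metadata",
    "write_results",
    "read_results",
    "COHORT_FLAGS",
    "CLINICAL_FLAGS",
]


class ParseError(ValueError):
    """A file's contents violate the format or a matrix invariant."""


class SchemaError(ValueError):
    """A table is missing mandatory columns or holds out-of-range values."""


# Clinical history flags with yes/no/unknown values.  The first six define
# cohort membership and exclusions; the remainder are screened as potential
# confounders only.
COHORT_FLAGS = ["MHT1D", "MHT2D", "MHARTHTS", "MHRA", "MHSEPSIS"]
CLINICAL_FLAGS = COHORT_FLAGS + ["MHLUPUS", "MHCLLULTS", "MHSCLRDRM", "MHSRCDSS"]

MANDATORY_META = ["SAMPID", "SEX", "AGE"] + COHORT_FLAGS + ["LBHIV1NT"]

_SEX_MAP = {"male": "male", "m": "male", "1": "male",
            "female": "female", "f": "female", "2": "female"}
_FLAG_VALUES = {"yes", "no", "unknown"}
_HIV_VALUES = {"positive", "negative", "not performed"}


@dataclass
class ExpressionMatrix:
    """Dense genes x samples relative-abundance matrix in TPM units.

    Invariants: all values finite and non-negative; gene and sample
    identifiers unique; dimensions consistent.  Violations raise
    :class:`ParseError` at construction so no downstream stage ever sees a
    malformed matrix.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParseError("expression values must be a 2-D matrix")
        ng, ns = self.values.shape
        if ng != len(self.gene_ids) or ns != len(self.sample_ids):
            raise ParseError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ParseError(f"duplicate gene id(s): {sorted(dup)[:5]}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ParseError(f"duplicate sample id(s): {sorted(dup)[:5]}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"non-finite TPM at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ParseError(
                f"negative TPM at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        """Restrict to the given genes (by id list or boolean mask), keeping order."""
        if isinstance(genes, np.ndarray) and genes.dtype == bool:
            idx = np.flatnonzero(genes)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            missing = [g for g in genes if g not in pos]
            if missing:
                raise KeyError(f"unknown gene id(s): {missing[:5]}")
            idx = np.array([pos[g] for g in genes], dtype=int)
        return ExpressionMatrix([self.gene_ids[i] for i in idx], list(self.sample_ids),
                                self.values[idx, :])

    def subset_samples(self, samples: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        if isinstance(samples, np.ndarray) and samples.dtype == bool:
            idx = np.flatnonzero(samples)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            missing = [s for s in samples if s not in pos]
            if missing:
                raise KeyError(f"unknown sample id(s): {missing[:5]}")
            idx = np.array([pos[s] for s in samples], dtype=int)
        return ExpressionMatrix(list(self.gene_ids), [self.sample_ids[i] for i in idx],
                                self.values[:, idx])


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples TPM matrix.

    ``tsv``: first column gene ids, header row of sample ids.  ``gct``:
    GCT 1.2 with the two-line ``#1.2`` / ``n_genes n_samples`` preamble and a
    ``Description`` column that is ignored.
    """
    path = Path(path)
    if dialect == "tsv":
        df = _read_numeric_table(path, skiprows=0, drop_cols=[])
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ParseError(f"{path}: expected GCT preamble '#1.2', got {version!r}")
            shape_line = fh.readline().split()
            if len(shape_line) != 2:
                raise ParseError(f"{path}: malformed GCT shape line")
            ng, ns = (int(x) for x in shape_line)
        df = _read_numeric_table(path, skiprows=2, drop_cols=["Description"])
        if df.shape != (ng, ns):
            raise ParseError(
                f"{path}: GCT preamble declares {ng} x {ns} but table is "
                f"{df.shape[0]} x {df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        return ExpressionMatrix.from_dataframe(df)
    except ParseError as e:
        raise ParseError(f"{path}: {e}") from None


def _read_numeric_table(path: Path, skiprows: int, drop_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0, dtype=str)
    if df.columns.size == 0:
        raise ParseError(f"{path}: header row with sample ids missing")
    df = df.drop(columns=[c for c in drop_cols if c in df.columns])
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(f"{path}: non-numeric cell at gene {row!r}, column {col!r}")
        if vals.isna().any():
            row = df.index[vals.isna().argmax()]
            raise ParseError(f"{path}: missing TPM at gene {row!r}, column {col!r}")
        out[col] = vals.to_numpy()
    return pd.DataFrame(out, index=df.index.astype(str))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as canonical TSV (10 significant digits)."""
    matrix.to_dataframe().to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation table: gene_id, symbol, chromosome, is_coding."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "symbol", "chromosome", "is_coding"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: annotation missing column(s) {sorted(missing)}")
    dup = _duplicates(df["gene_id"])
    if dup:
        raise SchemaError(f"{path}: duplicate annotation row(s) for {sorted(dup)[:5]}")
    df = df.copy()
    df["is_coding"] = df["is_coding"].str.strip().str.lower().map(
        {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}
    )
    if df["is_coding"].isna().any():
        raise SchemaError(f"{path}: is_coding must be boolean-like")
    return df.set_index("gene_id", drop=False)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# clinical metadata


def read_metadata(path: str | Path, age_range: tuple[float, float] = (21.0, 70.0),
                  ) -> pd.DataFrame:
    """Read the per-donor clinical table.

    Flag strings are case-insensitive on read and stored normalized
    (``yes``/``no``/``unknown``; HIV serology ``positive``/``negative``/
    ``not performed``).  Unknown values are preserved as ``unknown``, never
    coerced.  Ages outside ``age_range`` (donor eligibility window) raise
    :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANDATORY_META if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing mandatory column(s) {missing}")
    return normalize_metadata(df, age_range=age_range, source=str(path))


def normalize_metadata(df: pd.DataFrame, age_range: tuple[float, float] = (21.0, 70.0),
                       source: str = "<metadata>") -> pd.DataFrame:
    df = df.copy()
    df["SAMPID"] = df["SAMPID"].astype(str)
    dup = _duplicates(df["SAMPID"])
    if dup:
        raise SchemaError(f"{source}: duplicate sample id(s) {sorted(dup)[:5]}")

    sex = df["SEX"].astype(str).str.strip().str.lower().map(_SEX_MAP)
    if sex.isna().any():
        bad = df.loc[sex.isna(), "SEX"].iloc[0]
        raise SchemaError(f"{source}: unrecognized SEX value {bad!r}")
    df["SEX"] = sex

    age = pd.to_numeric(df["AGE"], errors="coerce")
    if age.isna().any():
        raise SchemaError(f"{source}: non-numeric AGE")
    lo, hi = age_range
    if ((age < lo) | (age > hi)).any():
        bad = age[(age < lo) | (age > hi)].iloc[0]
        raise SchemaError(f"{source}: AGE {bad} outside plausible range [{lo}, {hi}]")
    df["AGE"] = age

    for col in CLINICAL_FLAGS:
        if col not in df.columns:
            continue
        vals = df[col].astype(str).str.strip().str.lower()
        vals = vals.replace({"nan": "unknown", "": "unknown", "unk": "unknown"})
        bad = ~vals.isin(_FLAG_VALUES)
        if bad.any():
            raise SchemaError(f"{source}: column {col} has value {vals[bad].iloc[0]!r}")
        df[col] = vals

    if "LBHIV1NT" in df.columns:
        vals = (df["LBHIV1NT"].astype(str).str.strip().str.lower()
                .str.replace("_", " ", regex=False))
        vals = vals.replace({"nan": "not performed", "": "not performed"})
        bad = ~vals.isin(_HIV_VALUES)
        if bad.any():
            raise SchemaError(f"{source}: LBHIV1NT has value {vals[bad].iloc[0]!r}")
        df["LBHIV1NT"] = vals

    for col in ("BMI", "HGHT", "WGHT"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.set_index("SAMPID", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# result tables

#: canonical column order of the per-gene DE result table
DE_COLUMNS = [
    "gene_id", "p50", "q50", "fc50", "dir50", "sig50",
    "p75", "q75", "fc75", "dir75", "sig75",
    "ssmd", "call", "direction_conflict", "n_used_50", "n_used_75",
]


def write_results(de: pd.DataFrame, path: str | Path) -> None:
    """Write a DE result table with deterministic column order.

    Round-trip precision is 10 significant digits; an empty result set yields
    a header-only file.
    """
    cols = [c for c in DE_COLUMNS if c in de.columns]
    cols += [c for c in de.columns if c not in cols]
    de.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g",
                           lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" in df.columns:
        df["gene_id"] = df["gene_id"].astype(str)
        df = df.set_index("gene_id", drop=False)
    return df


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study defaults.

    Attributes
    ----------
    expr_median_min, expr_max_min
        Abundance filter: a gene counts as expressed in a group when its
        median TPM >= 0.5 AND its maximum TPM >= 1.0 there.
    entropy_variable_pct, entropy_testable_pct
        Normalized-entropy percentiles: >= 90th flags highly variable genes
        (used for the sample PCA), < 75th flags non-ubiquitous genes kept
        for DE testing.
    alpha, fold_threshold
        Per-level BH FDR threshold and minimum quantile fold change.
    ssmd_epsilon, fold_epsilon
        Smoothing constants added in the SSMD formula and to quantiles in
        fold ratios (guards division by zero for absent transcripts).
    outlier_sd, outlier_components, outlier_standardize
        PCA outlier rule: standardized Euclidean norm over the top
        components >= this many standard deviations.
    corr_r_threshold, corr_alpha
        Age-correlation significance: |R| > 0.20 and BH q <= alpha.
    entropy_scope_testable
        Which samples the DE-filter entropy is computed on: "bsl" (default)
        or "all".
    expressed_pooled
        If True the cross-cohort abundance filter pools all samples; the
        per-cohort alternative is available for sensitivity checks.
    """

    expr_median_min: float = 0.5
    expr_max_min: float = 1.0
    entropy_variable_pct: float = 90.0
    entropy_testable_pct: float = 75.0
    alpha: float = 0.05
    fold_threshold: float = 1.2
    ssmd_epsilon: float = 0.001
    fold_epsilon: float = 0.001
    fold_at_own_level: bool = True
    upper_threshold: str = "shared"
    exact_max_group: int = 10
    outlier_sd: float = 2.0
    outlier_components: int = 2
    outlier_standardize: bool = True
    corr_r_threshold: float = 0.20
    corr_alpha: float = 0.05
    age_min: float = 21.0
    age_max: float = 70.0
    pca_log_transform: bool = True
    pca_standardize: bool = True
    entropy_scope_testable: str = "bsl"
    expressed_pooled: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
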