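"""Coding-TPM renormalization, cohort assignment, confound screening and
entropy-based gene selection.

The analysis restricts itself to validated coding genes: because bulk
rRNA-depleted libraries carry a variable proportion of non-polyA reads, TPMs
of coding genes are re-constrained to sum to one million per sample before
any comparison.  Donors are then partitioned from clinical history into a
baseline cohort (BSL), a chronic-joint-pain cohort (CJP, arthritis or
rheumatoid arthritis) and a Type-II-diabetes cohort (T2D), with exclusions
for sepsis, HIV infection, Type I diabetes, or joint pain combined with
Type II diabetes.

Gene selection uses two devices: an abundance filter (expressed genes) and a
normalized Shannon entropy score e_i in [0, 1] of each gene's TPM
distribution across samples — 1 for perfectly ubiquitous expression, 0 for
single-sample expression.  Highly variable genes (e_i at or above the 90th
percentile) feed the sample PCA; DE testing keeps non-ubiquitous genes
(e_i strictly below the 75th percentile of expressed coding genes), chosen
agnostic to sex.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import CLINICAL_FLAGS, ExpressionMatrix, SchemaError

log = logging.getLogger("nervede")

__all__ = [
    "renormalize_coding",
    "assign_cohorts",
    "confound_summary",
    "filter_expressed",
    "normalized_entropy",
    "select_variable",
    "select_nonubiquitous",
]

TPM_TOTAL = 1_000_000.0


def renormalize_coding(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                       ) -> ExpressionMatrix:
    """Drop non-coding genes and rescale each sample's coding TPMs to 1e6.

    Every gene in ``matrix`` must have an annotation row; a sample with
    all-zero coding expression is an error (it cannot be renormalized).
    The operation is idempotent up to floating-point round-off.
    """
    missing = [g for g in matrix.gene_ids if g not in annotation.index]
    if missing:
        raise SchemaError(f"genes without annotation: {missing[:5]}")
    coding = np.array([bool(annotation.at[g, "is_coding"]) for g in matrix.gene_ids])
    sub = matrix.subset_genes(coding)
    totals = sub.values.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = sub.sample_ids[int(np.argmax(zero))]
        raise ValueError(f"sample {bad!r} has all-zero coding expression")
    values = sub.values * (TPM_TOTAL / totals)[None, :]
    log.info("renormalize_coding: kept %d/%d coding genes over %d samples",
             sub.n_genes, matrix.n_genes, sub.n_samples)
    return ExpressionMatrix(sub.gene_ids, sub.sample_ids, values)


def _flag(meta: pd.DataFrame, col: str) -> pd.Series:
    """Yes/no view of a clinical flag; unknown/missing treated as 'no' for
    cohort logic (history-based inclusion cannot act on absent records)."""
    if col not in meta.columns:
        return pd.Series(False, index=meta.index)
    return meta[col] == "yes"


def assign_cohorts(meta: pd.DataFrame) -> pd.DataFrame:
    """Partition donors into BSL / CJP / T2D / EXCLUDED.

    Exclusions (in precedence order, reason records the first that fires):
    sepsis, HIV-positive serology, Type I diabetes, and the combination of
    chronic joint pain (MHARTHTS or MHRA) with Type II diabetes.  Of the
    remaining donors, arthritis flags define CJP, MHT2D defines T2D, and
    everyone else is BSL.  A "not performed" HIV test does not exclude.
    """
    sepsis = _flag(meta, "MHSEPSIS")
    hiv = meta["LBHIV1NT"] == "positive" if "LBHIV1NT" in meta.columns else \
        pd.Series(False, index=meta.index)
    t1d = _flag(meta, "MHT1D")
    arthritis = _flag(meta, "MHARTHTS") | _flag(meta, "MHRA")
    t2d = _flag(meta, "MHT2D")

    cohort = pd.Series("BSL", index=meta.index, dtype=object)
    reason = pd.Series("", index=meta.index, dtype=object)

    cohort[t2d] = "T2D"
    cohort[arthritis] = "CJP"
    for mask, why in [
        (arthritis & t2d, "joint_pain_and_T2D"),
        (t1d, "type_I_diabetes"),
        (hiv, "HIV_positive"),
        (sepsis, "sepsis"),
    ]:
        cohort[mask] = "EXCLUDED"
        reason[mask] = why

    out = pd.DataFrame({
        "sample_id": meta["SAMPID"],
        "cohort": cohort,
        "sex": meta["SEX"],
        "exclusion_reason": reason,
    })
    counts = out.groupby(["cohort", "sex"]).size()
    log.info("assign_cohorts: %s", counts.to_dict())
    return out


_NUMERIC_VARS = ["AGE", "BMI", "HGHT", "WGHT"]


def confound_summary(assignments: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort, per-sex summary of the screened clinical variables.

    Numeric variables report mean and sample standard deviation; categorical
    flags (including HIV serology and race) report level percentages.
    Returns a tidy table (cohort, sex, variable, statistic, value, n).
    """
    merged = meta.join(assignments.set_index("sample_id")[["cohort"]], how="inner")
    rows: list[dict] = []
    cohorts = sorted(merged["cohort"].unique())
    for cohort in cohorts:
        for sex in ("male", "female"):
            grp = merged[(merged["cohort"] == cohort) & (merged["SEX"] == sex)]
            n = len(grp)
            rows.append({"cohort": cohort, "sex": sex, "variable": "cohort_size",
                         "statistic": "count", "value": float(n), "n": n})
            for var in _NUMERIC_VARS:
                if var not in merged.columns:
                    continue
                vals = grp[var].dropna()
                mean = float(vals.mean()) if len(vals) else np.nan
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
                rows.append({"cohort": cohort, "sex": sex, "variable": var,
                             "statistic": "mean", "value": mean, "n": n})
                rows.append({"cohort": cohort, "sex": sex, "variable": var,
                             "statistic": "sd", "value": sd, "n": n})
            cat_vars = [c for c in CLINICAL_FLAGS if c in merged.columns]
            for var in cat_vars + [c for c in ("LBHIV1NT", "RACE") if c in merged.columns]:
                levels = sorted(merged[var].dropna().astype(str).unique())
                for level in levels:
                    pct = 100.0 * float((grp[var].astype(str) == level).mean()) if n else 0.0
                    rows.append({"cohort": cohort, "sex": sex, "variable": var,
                                 "statistic": f"pct[{level}]", "value": pct, "n": n})
    return pd.DataFrame(rows)


def filter_expressed(matrix: ExpressionMatrix,
                     groups: Mapping[str, Sequence[str]] | None = None,
                     median_min: float = 0.5, max_min: float = 1.0) -> pd.Series:
    """Flag genes passing the conservative abundance filter.

    A gene fails in a group when its median TPM < ``median_min`` OR its
    maximum TPM < ``max_min`` there; it is filtered out only if it fails in
    *every* group (so a gene robustly expressed in one sex — e.g. Y-linked —
    stays testable).  ``groups=None`` pools all samples into one group, the
    cross-cohort variant of the filter.
    """
    if groups is None:
        groups = {"all": list(matrix.sample_ids)}
    expressed = np.zeros(matrix.n_genes, dtype=bool)
    for name, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"empty sample group {name!r}")
        sub = matrix.subset_samples(list(samples))
        med = np.median(sub.values, axis=1)
        mx = sub.values.max(axis=1)
        expressed |= (med >= median_min) & (mx >= max_min)
    log.info("filter_expressed: %d/%d genes expressed", int(expressed.sum()),
             matrix.n_genes)
    return pd.Series(expressed, index=matrix.gene_ids, name="expressed")


def normalized_entropy(matrix: ExpressionMatrix) -> pd.Series:
    """Normalized Shannon entropy of each gene's TPM share across samples.

    e_i = -(1 / log2 N) * sum_j p_ij log2 p_ij with p_ij the gene's TPM in
    sample j divided by its row sum, and 0 log 0 := 0.  All-zero rows score 0
    by the same convention.  Scale-invariant per gene and permutation-
    invariant in samples.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("entropy requires at least 2 samples")
    t = matrix.values
    row = t.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row > 0, t / np.where(row > 0, row, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    e = -plogp.sum(axis=1) / np.log2(n)
    e = np.clip(e, 0.0, 1.0)
    return pd.Series(e, index=matrix.gene_ids, name="entropy")


def select_variable(entropy: pd.Series, expressed: pd.Series,
                    pct: float = 90.0) -> pd.Series:
    """Highly variable genes: expressed AND entropy >= the given percentile
    of entropies over expressed genes (ties at the threshold included)."""
    expressed = expressed.reindex(entropy.index, fill_value=False)
    if not expressed.any():
        return pd.Series(False, index=entropy.index, name="variable")
    thr = np.percentile(entropy[expressed], pct)
    mask = expressed & (entropy >= thr)
    log.info("select_variable: %d genes at entropy >= %.4f (p%.0f)",
             int(mask.sum()), thr, pct)
    return mask.rename("variable")


def select_nonubiquitous(entropy: pd.Series, expressed: pd.Series,
                         pct: float = 75.0) -> pd.Series:
    """Testable genes: expressed AND entropy strictly below the given
    percentile of entropies over expressed (coding) genes."""
    expressed = expressed.reindex(entropy.index, fill_value=False)
    if not expressed.any():
        return pd.Series(False, index=entropy.index, name="testable")
    thr = np.percentile(entropy[expressed], pct)
    mask = expressed & (entropy < thr)
    if not mask.any():
        log.warning("select_nonubiquitous: no gene below the p%.0f entropy "
                    "threshold (all entropies tied?)", pct)
    log.info("select_nonubiquitous: %d genes at entropy < %.4f (p%.0f)",
             int(mask.sum()), thr, pct)
    return mask.rename("testable")


def sex_groups(assignments: pd.DataFrame, cohort: str = "BSL",
               ) -> dict[str, list[str]]:
    """Male/female sample lists of one cohort, a convenience for the filter
    and test stages."""
    sub = assignments[assignments["cohort"] == cohort]
    return {sex: list(sub.loc[sub["sex"] == sex, "sample_id"])
            for sex in ("male", "female")}
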