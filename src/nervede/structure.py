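"""Sample-level population structure: PCA, outlier screening and
age–expression correlation.

PCA is run on log2(TPM+1)-transformed, per-gene standardized expression over
a selected gene set (highly variable genes for cohort QC; the sex-DE gene
set for the age analysis).  Outliers are samples whose per-component
standardized score norm over the top two components is two or more standard
deviations from the origin.  Age associations are Pearson correlations —
per principal component, and per gene separately within each sex — with
significance requiring |R| > 0.20 and a Benjamini–Hochberg q <= 0.05;
Y-chromosomal genes are not tested in the female sub-cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_model import ExpressionMatrix
from .quantile_de import bh_adjust

log = logging.getLogger("nervede")

__all__ = [
    "PcaOutput",
    "pca_samples",
    "detect_outliers",
    "age_correlation_genes",
    "age_correlation_components",
]


@dataclass
class PcaOutput:
    """PCA of samples: scores (samples x PCs), loadings (genes x PCs) and
    per-component variance fractions (non-increasing, summing to <= 1)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if (vf < -1e-12).any() or np.any(np.diff(vf) > 1e-9):
            raise ValueError("variance fractions must be non-negative and "
                             "non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to <= 1")
        self.variance_fraction = vf


def pca_samples(matrix: ExpressionMatrix, gene_mask: pd.Series | None = None,
                log_transform: bool = True, standardize: bool = True,
                n_components: int | None = None) -> PcaOutput:
    """PCA of samples over the selected genes.

    Zero-variance genes are dropped (with a log note) since they carry no
    structure and break standardization.  Component signs follow the
    largest-magnitude-loading-positive convention, so results are
    deterministic.
    """
    if gene_mask is not None:
        mask = gene_mask.reindex(matrix.gene_ids, fill_value=False).to_numpy(bool)
        matrix = matrix.subset_genes(mask)
    if matrix.n_genes < 2:
        raise ValueError("PCA requires at least 2 selected genes")
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")

    X = matrix.values.T.astype(float)  # samples x genes
    if log_transform:
        X = np.log2(X + 1.0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.info("pca_samples: dropped %d zero-variance gene(s)",
                 int((~keep).sum()))
    X = X[:, keep]
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 genes with variance after transform")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    max_comp = min(X.shape[0] - 1, X.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x PCs

    # deterministic signs: make the largest-|loading| entry positive
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1

    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaOutput(
        scores=pd.DataFrame(scores, index=pd.Index(matrix.sample_ids, name="sample_id"),
                            columns=cols),
        loadings=pd.DataFrame(loadings, index=pd.Index(genes, name="gene_id"),
                              columns=cols),
        variance_fraction=pca.explained_variance_ratio_,
    )


def detect_outliers(pca: PcaOutput, cohorts: pd.Series | None = None,
                    n_components: int = 2, sd_threshold: float = 2.0,
                    standardize: bool = True,
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Flag samples far from the origin of the top score dimensions.

    A sample is an outlier when sqrt(sum_c (score_c / sd_c)^2) over the top
    ``n_components`` components is >= ``sd_threshold``, sd_c being each
    component's score standard deviation (scores are centered by
    construction).  With ``standardize=False`` raw score distances are
    compared against ``sd_threshold`` times the RMS component sd.  Returns
    the per-sample table and per-cohort outlier fractions (a single 'all'
    fraction when no cohort labels are given).
    """
    k = min(n_components, pca.scores.shape[1])
    S = pca.scores.iloc[:, :k].to_numpy()
    sd = S.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance component among the top components")
    if standardize:
        dist = np.sqrt(((S / sd) ** 2).sum(axis=1))
        flag = dist >= sd_threshold
    else:
        dist = np.sqrt((S ** 2).sum(axis=1))
        flag = dist >= sd_threshold * np.sqrt((sd ** 2).mean())
    table = pd.DataFrame({
        "sample_id": pca.scores.index,
        "distance": dist,
        "outlier": flag,
    }).set_index("sample_id", drop=False)
    if cohorts is None:
        fractions = pd.Series({"all": float(flag.mean())}, name="outlier_fraction")
    else:
        lab = cohorts.reindex(pca.scores.index)
        fractions = table.groupby(lab)["outlier"].mean().rename("outlier_fraction")
    log.info("detect_outliers: %d/%d samples flagged; fractions %s",
             int(flag.sum()), len(flag), fractions.round(3).to_dict())
    return table, fractions


def _pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson R of X (features x n) against y (n,), with two-sided
    p from the exact t transform (identical to scipy.stats.pearsonr)."""
    n = y.size
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc ** 2).sum())
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.where(sx > 0, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p = np.where(np.isnan(r), np.nan,
                 np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2)))
    return r, p


def age_correlation_genes(matrix: ExpressionMatrix, metadata: pd.DataFrame,
                          genes: pd.Series | list[str], sex: str,
                          annotation: pd.DataFrame | None = None,
                          alpha: float = 0.05, r_threshold: float = 0.20,
                          ) -> pd.DataFrame:
    """Per-gene Pearson correlation of TPM with donor age within one sex.

    BH is applied across the tested genes; a gene is significant when
    |R| > ``r_threshold`` and q <= ``alpha``.  In the female run
    Y-chromosomal genes are excluded (requires ``annotation``).  Constant
    genes get R = NaN and are reported not significant with a reason.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if isinstance(genes, pd.Series):
        gene_list = [g for g, keep in genes.items() if keep]
    else:
        gene_list = list(genes)
    if sex == "female" and annotation is not None:
        gene_list = [g for g in gene_list
                     if str(annotation.at[g, "chromosome"]) != "Y"]
    sel = metadata[metadata["SEX"] == sex]
    samples = [s for s in matrix.sample_ids if s in sel.index]
    if len(samples) < 3:
        raise ValueError(f"need >= 3 {sex} samples, got {len(samples)}")
    sub = matrix.subset_genes(gene_list).subset_samples(samples)
    age = sel.loc[samples, "AGE"].to_numpy(dtype=float)

    r, p = _pearson_with_p(sub.values, age)
    tested = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested], _ = bh_adjust(p[tested], alpha)
    significant = tested & (np.abs(r) > r_threshold) & (q <= alpha)
    reason = np.where(tested, "", "constant_gene")
    out = pd.DataFrame({
        "gene_id": sub.gene_ids,
        "sex": sex,
        "R": r, "p": p, "q": q,
        "significant": significant,
        "reason": reason,
        "n": len(samples),
    }).set_index("gene_id", drop=False)
    log.info("age_correlation_genes[%s]: %d/%d significant over %d samples",
             sex, int(significant.sum()), len(gene_list), len(samples))
    return out


def age_correlation_components(pca: PcaOutput, metadata: pd.DataFrame,
                               alpha: float = 0.05, r_threshold: float = 0.20,
                               ) -> pd.DataFrame:
    """Pearson correlation of each principal component's scores with age."""
    samples = list(pca.scores.index)
    missing = [s for s in samples if s not in metadata.index]
    if missing:
        raise KeyError(f"metadata missing for sample(s) {missing[:5]}")
    age = metadata.loc[samples, "AGE"].to_numpy(dtype=float)
    r, p = _pearson_with_p(pca.scores.to_numpy().T, age)
    q, _ = bh_adjust(p, alpha)
    return pd.DataFrame({
        "component": pca.scores.columns,
        "R": r, "p": p, "q": q,
        "significant": (np.abs(r) > r_threshold) & (q <= alpha),
        "variance_fraction": pca.variance_fraction[:len(r)],
    }).set_index("component", drop=False)
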