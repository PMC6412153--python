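"""End-to-end orchestration: simulate -> preprocess -> DE -> structure ->
report, with every intermediate written as deterministic TSV.

The stage order mirrors the analysis: coding-TPM renormalization, cohort
assignment and confound screening; cross-cohort QC (pooled abundance
filter, all-cohort entropy, PCA of highly variable genes, outlier
fractions per cohort); baseline-cohort DE (per-sex abundance filter,
BSL entropy, non-ubiquitous gene selection, two-level quantile test); and
the age analysis (PCA over the sex-DE genes, component- and gene-level
Pearson correlations per sex).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import preprocess, structure
from .annotate import build_report
from .io_model import ExpressionMatrix, PipelineConfig, write_annotation, \
    write_expression, write_metadata, write_results
from .quantile_de import TestConfig, run_de
from .synthetic import SimulationConfig, generate_cohort

log = logging.getLogger("nervede")

__all__ = ["run_all", "analyze"]

_FLOAT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT, lineterminator="\n")


def analyze(expression: ExpressionMatrix, metadata: pd.DataFrame,
            annotation: pd.DataFrame, config: PipelineConfig | None = None,
            truth: pd.DataFrame | None = None) -> dict:
    """Run all analysis stages in memory; returns a dict of result tables."""
    cfg = config or PipelineConfig()
    out: dict = {}

    coding = preprocess.renormalize_coding(expression, annotation)
    cohorts = preprocess.assign_cohorts(metadata)
    out["cohorts"] = cohorts
    out["confounds"] = preprocess.confound_summary(cohorts, metadata)
    out["renormalized"] = coding

    # --- cross-cohort QC on non-excluded samples
    kept = cohorts[cohorts["cohort"] != "EXCLUDED"]["sample_id"].tolist()
    qc = coding.subset_samples(kept)
    groups = None if cfg.expressed_pooled else {
        c: cohorts.loc[(cohorts["cohort"] == c), "sample_id"].tolist()
        for c in ("BSL", "CJP", "T2D")
        if (cohorts["cohort"] == c).any()
    }
    expressed_all = preprocess.filter_expressed(qc, groups, cfg.expr_median_min,
                                                cfg.expr_max_min)
    entropy_all = preprocess.normalized_entropy(qc)
    variable = preprocess.select_variable(entropy_all, expressed_all,
                                          cfg.entropy_variable_pct)
    out["entropy_all"] = entropy_all
    out["variable"] = variable
    if variable.sum() >= 2:
        pca_qc = structure.pca_samples(qc, variable, cfg.pca_log_transform,
                                       cfg.pca_standardize)
        cohort_labels = cohorts.set_index("sample_id")["cohort"]
        outlier_table, outlier_frac = structure.detect_outliers(
            pca_qc, cohort_labels, cfg.outlier_components, cfg.outlier_sd,
            cfg.outlier_standardize)
        out["pca_qc"] = pca_qc
        out["outliers"] = outlier_table
        out["outlier_fractions"] = outlier_frac

    # --- baseline-cohort DE
    bsl_groups = preprocess.sex_groups(cohorts, "BSL")
    bsl_samples = bsl_groups["male"] + bsl_groups["female"]
    bsl = coding.subset_samples(bsl_samples)
    expressed_bsl = preprocess.filter_expressed(bsl, bsl_groups,
                                                cfg.expr_median_min, cfg.expr_max_min)
    entropy_src = bsl if cfg.entropy_scope_testable == "bsl" else qc
    entropy_bsl = preprocess.normalized_entropy(entropy_src)
    testable = preprocess.select_nonubiquitous(entropy_bsl, expressed_bsl,
                                               cfg.entropy_testable_pct)
    out["entropy_bsl"] = entropy_bsl
    out["testable"] = testable

    tcfg = TestConfig(alpha=cfg.alpha, fold_threshold=cfg.fold_threshold,
                      epsilon=cfg.ssmd_epsilon, fold_epsilon=cfg.fold_epsilon,
                      fold_at_own_level=cfg.fold_at_own_level,
                      upper_threshold=cfg.upper_threshold,
                      exact_max_group=cfg.exact_max_group)
    sex_labels = metadata["SEX"]
    de = run_de(bsl.subset_genes(testable.to_numpy(bool)), sex_labels, tcfg)
    out["de"] = de

    # --- age analysis on the sex-DE gene set
    de_genes = de.index[de["call"] != "none"].tolist()
    if len(de_genes) >= 2:
        mask = pd.Series(False, index=bsl.gene_ids)
        mask.loc[de_genes] = True
        pca_de = structure.pca_samples(bsl, mask, cfg.pca_log_transform,
                                       cfg.pca_standardize)
        out["pca_de"] = pca_de
        out["age_components"] = structure.age_correlation_components(
            pca_de, metadata, cfg.corr_alpha, cfg.corr_r_threshold)
        for sex in ("male", "female"):
            out[f"age_genes_{sex}"] = structure.age_correlation_genes(
                bsl, metadata, de_genes, sex, annotation,
                cfg.corr_alpha, cfg.corr_r_threshold)

    entropy_for_report = entropy_bsl.reindex(de.index)
    report, counts = build_report(de, annotation, entropy_for_report, truth)
    out["report"] = report
    out["counts"] = counts
    return out


def run_all(sim_config: SimulationConfig, out_dir: str | Path,
            config: PipelineConfig | None = None) -> dict:
    """Simulate a cohort, run every stage and write all tables under
    ``out_dir``.  Identical seeds produce byte-identical outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    expression, metadata, annotation, truth = generate_cohort(sim_config)
    write_expression(expression, out_dir / "expression.tsv")
    write_metadata(metadata, out_dir / "metadata.tsv")
    write_annotation(annotation, out_dir / "annotation.tsv")
    _write(truth, out_dir / "truth.tsv")

    res = analyze(expression, metadata, annotation, config, truth)

    _write(res["cohorts"], out_dir / "cohorts.tsv")
    _write(res["confounds"], out_dir / "confounds.tsv")
    write_expression(res["renormalized"], out_dir / "renormalized.tsv")
    _write(res["entropy_all"].rename("entropy").rename_axis("gene_id").reset_index(),
           out_dir / "entropy_all.tsv")
    _write(res["entropy_bsl"].rename("entropy").rename_axis("gene_id").reset_index(),
           out_dir / "entropy_bsl.tsv")
    _write(res["testable"].rename("testable").rename_axis("gene_id").reset_index(),
           out_dir / "testable.tsv")
    write_results(res["de"], out_dir / "de_results.tsv")
    if "pca_qc" in res:
        _write(res["pca_qc"].scores.reset_index(), out_dir / "pca_qc_scores.tsv")
        _write(pd.DataFrame({
            "component": res["pca_qc"].scores.columns,
            "variance_fraction": res["pca_qc"].variance_fraction,
        }), out_dir / "pca_qc_variance.tsv")
        _write(res["outliers"], out_dir / "outliers.tsv")
        _write(res["outlier_fractions"].reset_index(), out_dir / "outlier_fractions.tsv")
    if "pca_de" in res:
        _write(res["pca_de"].scores.reset_index(), out_dir / "pca_de_scores.tsv")
        _write(res["age_components"], out_dir / "age_components.tsv")
        _write(res["age_genes_male"], out_dir / "age_genes_male.tsv")
        _write(res["age_genes_female"], out_dir / "age_genes_female.tsv")
    _write(res["report"], out_dir / "report.tsv")
    with open(out_dir / "counts.json", "w") as fh:
        json.dump(res["counts"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run_all: wrote results to %s", out_dir)
    return res
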