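#!/usr/bin/env python
"""Population structure and age correlation.

Two PCA views: (a) all non-excluded samples over highly variable genes
(entropy at/above the 90th percentile) with standardized-norm outlier
fractions per cohort; (b) baseline samples over the sex-DE gene set, whose
top components separate the sexes, with Pearson age correlations per
component and per gene within each sex (Y-linked genes are not tested in
females).
"""

import argparse
import logging
import sys
from pathlib import Path

import pandas as pd

from nervede import (PipelineConfig, read_annotation, read_expression,
                     read_metadata, read_results)
from nervede.preprocess import filter_expressed, normalized_entropy, \
    select_variable, sex_groups
from nervede.structure import (age_correlation_components,
                               age_correlation_genes, detect_outliers,
                               pca_samples)

logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                    format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--prep-dir", type=Path, default=Path("results/preprocess"))
    ap.add_argument("--de-dir", type=Path, default=Path("results/de"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/structure"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig()

    coding = read_expression(args.prep_dir / "renormalized.tsv")
    cohorts = pd.read_csv(args.prep_dir / "cohorts.tsv", sep="\t", dtype=str)
    metadata = read_metadata(args.sim_dir / "metadata.tsv")
    annotation = read_annotation(args.sim_dir / "annotation.tsv")
    de = read_results(args.de_dir / "de_results.tsv")

    # (a) cohort-level QC
    kept = cohorts[cohorts["cohort"] != "EXCLUDED"]["sample_id"].tolist()
    qc = coding.subset_samples(kept)
    expressed = filter_expressed(qc, None, cfg.expr_median_min, cfg.expr_max_min)
    entropy = normalized_entropy(qc)
    variable = select_variable(entropy, expressed, cfg.entropy_variable_pct)
    pca_qc = pca_samples(qc, variable, cfg.pca_log_transform, cfg.pca_standardize)
    labels = cohorts.set_index("sample_id")["cohort"]
    outliers, fractions = detect_outliers(pca_qc, labels, cfg.outlier_components,
                                          cfg.outlier_sd)
    outliers.to_csv(args.out_dir / "outliers.tsv", sep="\t", index=False,
                    float_format="%.6g", lineterminator="\n")
    fractions.reset_index().to_csv(args.out_dir / "outlier_fractions.tsv",
                                   sep="\t", index=False, float_format="%.6g",
                                   lineterminator="\n")
    print(f"variable genes for QC PCA: {int(variable.sum())}")
    print(f"top-2 variance fraction: {pca_qc.variance_fraction[:2].sum():.3f}")
    print("outlier fractions per cohort:")
    print(fractions.round(3).to_string())

    # (b) sex-DE-gene PCA on the baseline cohort + age correlations
    de_genes = de.index[de["call"] != "none"].tolist()
    groups = sex_groups(cohorts, "BSL")
    bsl = coding.subset_samples(groups["male"] + groups["female"])
    mask = pd.Series(False, index=bsl.gene_ids)
    mask.loc[de_genes] = True
    pca_de = pca_samples(bsl, mask, cfg.pca_log_transform, cfg.pca_standardize)
    pca_de.scores.reset_index().to_csv(args.out_dir / "pca_de_scores.tsv",
                                       sep="\t", index=False,
                                       float_format="%.6g", lineterminator="\n")
    comp = age_correlation_components(pca_de, metadata, cfg.corr_alpha,
                                      cfg.corr_r_threshold)
    comp.to_csv(args.out_dir / "age_components.tsv", sep="\t", index=False,
                float_format="%.6g", lineterminator="\n")
    print(f"sex-DE-gene PCA over {len(de_genes)} genes; top-2 variance "
          f"fraction {pca_de.variance_fraction[:2].sum():.3f}")
    print("component-age correlations (top 6):")
    print(comp.head(6)[["component", "R", "q", "significant"]]
          .to_string(index=False))

    for sex in ("male", "female"):
        res = age_correlation_genes(bsl, metadata, de_genes, sex, annotation,
                                    cfg.corr_alpha, cfg.corr_r_threshold)
        res.to_csv(args.out_dir / f"age_genes_{sex}.tsv", sep="\t", index=False,
                   float_format="%.6g", lineterminator="\n")
        sig = res[res["significant"]]
        print(f"{sex}: {len(sig)}/{len(res)} genes significantly "
              f"age-correlated (|R| > {cfg.corr_r_threshold}, "
              f"q <= {cfg.corr_alpha}); "
              f"{int((sig['R'] < 0).sum())} negative")


if __name__ == "__main__":
    main()
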