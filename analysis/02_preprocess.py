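#!/usr/bin/env python
"""Requantify and stratify the cohort.

Re-constrains coding-gene TPMs to sum to one million per sample, assigns
donors to the baseline (BSL), chronic-joint-pain (CJP) and Type-II-diabetes
(T2D) cohorts with the clinical exclusion rules, and summarizes the
potentially confounding clinical variables per cohort and sex.
"""

import argparse
import logging
import sys
from pathlib import Path

from nervede import (assign_cohorts, confound_summary, read_annotation,
                     read_expression, read_metadata, renormalize_coding,
                     write_expression)

logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                    format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/preprocess"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    expression = read_expression(args.in_dir / "expression.tsv")
    annotation = read_annotation(args.in_dir / "annotation.tsv")
    metadata = read_metadata(args.in_dir / "metadata.tsv")

    coding = renormalize_coding(expression, annotation)
    cohorts = assign_cohorts(metadata)
    confounds = confound_summary(cohorts, metadata)

    write_expression(coding, args.out_dir / "renormalized.tsv")
    cohorts.to_csv(args.out_dir / "cohorts.tsv", sep="\t", index=False,
                   lineterminator="\n")
    confounds.to_csv(args.out_dir / "confounds.tsv", sep="\t", index=False,
                     float_format="%.6g", lineterminator="\n")

    sizes = cohorts.groupby(["cohort", "sex"]).size()
    print(f"kept {coding.n_genes}/{expression.n_genes} coding genes")
    print("cohort sizes:")
    print(sizes.to_string())
    age = confounds[(confounds["variable"] == "AGE")
                    & (confounds["cohort"] == "BSL")]
    print("BSL age summary:")
    print(age[["sex", "statistic", "value"]].to_string(index=False))


if __name__ == "__main__":
    main()
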