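# nervede

Quantile-level sex-differential expression analysis for bulk
peripheral-nerve transcriptomes.

Bulk RNA-seq of human tibial nerve from population donor cohorts shows
robust sex differences in gene expression, many of them confined to
*subsets* of donors of one sex — a signature an ordinary median-level test
misses. `nervede` implements the complete analysis for such cohorts:

* **Requantification** — TPMs of coding genes re-constrained to sum to 10⁶
  per sample, removing variable non-polyA content.
* **Cohort assignment** — baseline (BSL), chronic-joint-pain (CJP) and
  Type-II-diabetes (T2D) cohorts from clinical metadata, with exclusions
  (sepsis, HIV, Type I diabetes, joint pain + T2D), plus a per-cohort
  confound summary.
* **Gene selection** — an abundance filter (median TPM ≥ 0.5 and max ≥ 1.0
  in at least one sex) and a normalized Shannon-entropy score
  eᵢ = −(1/log₂N) Σⱼ pᵢⱼ log₂ pᵢⱼ: highly variable genes (eᵢ ≥ 90th
  percentile) for QC PCA, non-ubiquitous genes (eᵢ < 75th percentile) for
  testing.
* **Two-level quantile DE test** — Wilcoxon rank-sum between the sexes at
  the median (full sub-cohorts) and at the upper quartile (values at or
  above the sub-cohort medians), each controlled by Benjamini–Hochberg at
  FDR 0.05 with a ≥1.2-fold gate at the tested quantile; upper-quartile
  calls are reported as *additional* to median-level calls. Effect sizes
  are strictly standardized mean differences
  sᵢ = (μ_F − μ_M + ε)/√(σ_F² + σ_M² + ε), ε = 0.001.
* **Population structure** — PCA of samples over selected genes,
  standardized-norm outlier screening (≥2 SD from the origin of the top
  two components), and Pearson age–expression correlation per component
  and per gene within each sex (significant when |R| > 0.20 and q ≤ 0.05;
  Y genes untested in females).
* **Annotation** — intersection of DE calls with user-supplied gene lists
  (pain genes, scored neural-proportion lists).

The real donor data are controlled-access, so the package ships a
first-class **synthetic cohort generator** (`nervede.synthetic`) that
reproduces the study's statistical structure — 168/80 male/female baseline
donors, log-normal TPM noise, whole-population and subset-only sex
effects, Y-linked and X-escape genes, sex-specific age slopes — with
ground-truth labels, so every stage is validated by recovery, calibration
and FDR experiments. See `docs/methods.md` for the model and its
limitations.

## Worked example

The analysis is organised as numbered drivers over the library
(`analysis/01_simulate.py` … `06_operating_characteristics.py`), writing
under `results/`. Running them in order with the default seed:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_differential_expression.py
```

prints, among other things:

```
simulated 2000 genes x 333 samples (seed 1)
gene classes: {'null': 1664, 'median_DE': 200, 'subset_DE': 100, 'age_corr': 20, 'y_linked': 8, 'x_escape': 8}
kept 1800/2000 coding genes
expressed genes: 1800; testable after entropy filter: 1350
calls: {'male_50': 163, 'female_50': 133, 'male_75': 2, 'female_75': 2} (total 300)
fraction of calls on truly null genes: 0.000
```

Reading this: of 2000 simulated genes, the 200 non-coding ones are dropped
by requantification, the entropy filter removes the most ubiquitously
expressed quarter, and the two-level test on the 168/80 baseline
sub-cohorts calls 300 genes — 296 at the median level plus 4 additional at
the upper quartile, none of them truly null. (At 2-fold effects and noise
σ = 0.5 most subset genes already shift the median enough to be caught at
the 50th level; the upper-quartile level becomes the dominant detector in
the low-noise regime, as `06_operating_characteristics.py` shows.)
`04_population_structure.py` adds PCA/outlier QC and the age analysis, and
`05_annotate_report.py` intersects the calls with (synthetic stand-in)
gene lists and writes the master report:

```
outlier fractions per cohort:
BSL    0.109
CJP    0.143
T2D    0.150
pain-list overlap: 103/300 called genes (34.3%)
```

`06_operating_characteristics.py` characterises the procedure itself over
fresh cohorts:

```
combined empirical FDR: 0.0362 over 20 cohorts (mean discoveries 207.6, mean false 7.5)
detection frequencies (mean over seeds):
           det50  det75  called75
median_DE  0.969  0.008     0.000
subset_DE  0.053  0.952     0.934
```

— injected median-level effects (1.5-fold) are found at the median level
97% of the time; subset effects (2-fold in 40% of one sex's donors, low
noise) are found at the upper quartile 95% of the time while the
median-level fold gate correctly withholds the median call.

A `nervede` CLI mirrors the stages (`simulate`, `preprocess`, `de`,
`structure`, `annotate`, `run-all`); `nervede run-all --seed 7 --out-dir
out/` runs everything end to end and is byte-reproducible for a fixed
seed.

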