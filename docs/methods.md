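# Methods

`nervede` implements a quantile-level, nonparametric analysis of sex
differences in bulk peripheral-nerve transcriptomes, together with a
synthetic cohort generator that makes every stage testable without access
to controlled donor data. This note documents the model, the tunable
parameters, the numerical choices, and what the synthetic validation does
and does not show.

## Input model and requantification

The analysis operates on a genes × samples matrix of relative abundance in
TPM (transcripts per million) and a per-donor clinical table using
dbGaP-style variable names (`SEX`, `AGE`, `MHT2D`, `MHARTHTS`, `MHSEPSIS`,
`LBHIV1NT`, ...). Because rRNA-depleted total-RNA libraries carry a
variable proportion of non-polyA reads, analysis is limited to annotated
coding genes, whose TPMs are re-constrained to sum to 10⁶ per sample
(`renormalize_coding`; relative tolerance 1e−9, idempotent). A sample with
all-zero coding expression is an error, not a silent repair, as is any
negative, missing or non-finite TPM on read.

## Cohorts and confound screening

Donors are partitioned from recorded clinical history
(`assign_cohorts`): excluded if they have sepsis, a positive HIV test,
Type I diabetes, or chronic joint pain *together with* Type II diabetes;
otherwise CJP (arthritis or rheumatoid arthritis), T2D (Type II diabetes),
or BSL (baseline). Unknown/missing flags count as "no" for cohort logic —
history-based rules cannot act on absent records — but are reported in the
per-cohort, per-sex confound summary (means and sample SDs for age, BMI,
height, weight; level percentages for categorical flags). An HIV test
recorded as "not performed" does not exclude.

## Gene selection

Two filters precede testing:

* **Abundance.** A gene fails in a group when its median TPM < 0.5 *or*
  its maximum TPM < 1.0; it is removed only if it fails in **every** group
  (both sexes for the DE filter, the pooled samples for the cross-cohort
  variant). This keeps genes robustly expressed in one sex only —
  e.g. Y-linked genes — testable. Comparisons are strict (`<`), so a gene
  sitting exactly at median 0.5 / max 1.0 is kept.
* **Normalized entropy.** For gene *i* with TPM *t₍ᵢⱼ₎* over *N* samples,
  *eᵢ* = −(1/log₂N) Σⱼ pᵢⱼ log₂ pᵢⱼ with pᵢⱼ = tᵢⱼ/Σₖtᵢₖ and 0·log 0 := 0;
  all-zero rows score 0. *eᵢ* ∈ [0,1] is scale-invariant per gene and
  permutation-invariant in samples; 1 means perfectly ubiquitous
  expression. Highly **variable** genes (entropy at or above the 90th
  percentile of expressed genes, ties included) drive the QC PCA; DE
  testing keeps **non-ubiquitous** genes (entropy strictly below the 75th
  percentile of expressed coding genes), a sex-agnostic selection.
  Percentiles use linear interpolation; both the sample scope of each
  entropy (baseline-only vs all cohorts) and the comparison conventions
  are config fields.

## The two-level quantile test

For each retained gene, male and female baseline sub-cohorts are compared
by the Wilcoxon rank-sum test at two quantile levels:

* **Median (50th).** The full sub-cohorts.
* **Upper quartile (75th).** Only values at or above the sub-cohort
  medians, i.e. above a **shared threshold**: the larger of the two group
  medians. Comparing each group's values above its *own* median is
  available (`upper_threshold="own"`) but is anticonservative — the two
  group-specific random thresholds inflate the null variance of the
  rank-sum statistic (measured ≈18% of null genes at p < 0.05 at cohort
  sizes 168/80, versus ≈4–5% for the shared threshold) — so the calibrated
  shared-threshold form is the default. If one group falls entirely below
  the shared threshold the conditional test is undefined and the gene
  carries p = 1 at this level; such complete separations are already
  maximal median-level signals.

The upper-quartile test is the device for *subset effects*: expression
shifts confined to a fraction of one sex's donors move that group's upper
tail long before its median.

P-value computation: exact null distribution for small groups (minimum
group size ≤ 10; scipy's exact method for untied data, full enumeration of
mid-rank assignments when ties are present and C(n, n_min) ≤ 10⁵),
otherwise the normal approximation with mid-ranks, tie-corrected variance
and continuity correction. The matrix-scale path is a vectorised
implementation of the same approximation, cross-checked against scipy per
row in the tests. Ties matter in practice: absent transcripts produce runs
of zeros.

Each level's p-vector is adjusted with the Benjamini–Hochberg step-up
procedure (via statsmodels) jointly over all tested genes — one procedure
per level, direction read off afterwards. A gene is **significant at a
level** when q ≤ α (default 0.05) and its fold change *at that level's own
quantile* is ≥ 1.2 with a non-tied direction; fold changes are
(Q_high + ε)/(Q_low + ε) with a pseudo-quantity ε = 0.001 guarding zero
quantiles. The final call set partitions as median-level calls plus the
genes *additional* at the upper quartile (a gene significant at both
levels is reported at the median level); per-level flags are also kept, and
conflicting raw directions across levels are flagged. Because the two
levels reuse overlapping data, the union call set's false discovery rate
lies between the single-level α and 2α; the reproduction script measures
it directly (≈0.03–0.04 under the benchmark conditions, comfortably below
the 0.1 bound).

Effect sizes are strictly standardized mean differences,
sᵢ = (μ_F − μ_M + ε)/√(σ_F² + σ_M² + ε), with ε = 0.001 in numerator and
denominator, sample SDs, and covariance taken as zero; sᵢ > 0 means higher
female mean abundance.

## Population structure and age

PCA of samples (scikit-learn, full SVD) runs on log₂(TPM+1)-transformed,
per-gene standardized expression; raw-TPM PCA would be dominated by a few
high-abundance genes. Zero-variance genes are dropped with a log note, and
component signs follow the largest-magnitude-loading-positive convention,
so results are deterministic. Outliers are samples whose standardized
Euclidean norm over the top two components — √Σ(score_c/sd_c)² — is ≥ 2;
per-cohort outlier fractions are reported, and an unstandardized variant
is a config switch.

Age associations are Pearson correlations with BH adjustment:
per principal component of the sex-DE-gene PCA, and per gene separately
within each sex (the same |R| > 0.20 and q ≤ 0.05 thresholds in both
sexes; Y-chromosomal genes are not tested in females; constant genes are
reported untested with a reason). P-values use the exact t-transform of R.

## Annotation and report

DE calls are intersected with user-supplied symbol lists (e.g.
pain-associated genes) and score-thresholded lists (e.g. neural-proportion
scores ≥ 0.5). Matching is exact on uppercased symbols; duplicate list
entries are dropped with a warning and listed-but-unscored genes are
excluded with a warning rather than guessed. Annotation adds columns only
— report counts always equal the call partition. The repository ships no
licensed database content; the analysis drivers construct clearly-labelled
synthetic stand-in lists.

## The synthetic cohort generator

`generate_cohort` emulates the donor and effect structure the analysis
assumes: a baseline cohort of 168 male / 80 female donors (plus optional
11/10 arthritis, 44/16 diabetes and a few excluded donors so the clinical
rules are exercised), ages truncated-normal (mean 51, SD 13, on the 21–70
eligibility window), and per-sex height/weight/BMI/race distributions
matching the screened clinical table. Expression is modelled in TPM space
— the quantity the analysis actually sees — as
baseline × effects × exp(N(0, σ_noise)) with:

* baseline log-abundance N(1.5, 1.5²) (natural log), ~3–4 decades of
  dynamic range;
* median-level DE genes (default 10% of genes at 2-fold, direction
  random), subset-only genes (5% at 2-fold in a random fraction π = 0.4 of
  one sex's donors, membership drawn independently per gene), Y-linked
  genes exactly zero in females, X-escape genes modestly (1.3-fold)
  female-biased, and age-correlated genes with per-sex log-linear slopes
  (defaults: −0.02/yr in females, 0 in males);
* log-normal noise σ_noise = 0.5 (natural log) by default; no dispersion
  estimates exist for the emulated tissue's TPMs, so this is an artifact
  choice reported with all results;
* per-sample closure: every column is renormalized to sum to 10⁶ over all
  generated genes, emulating upstream quantifier output (the coding-only
  re-constraining remains a pipeline stage);
* one seeded generator for all draws — identical configs are
  bitwise-reproducible.

Two fidelity constraints matter at desk scale and are deliberate design
choices. First, effect classes are assigned only to genes below the 90th
percentile of baseline abundance: because TPM columns are closed, sex
effects on transcriptome-dominating genes would make every nominally null
gene genuinely sex-shifted, a compositional coupling that is negligible in
real tissue where sex-DE genes are modest-abundance regulatory/signalling
genes. Second, the baseline tail is tempered (ln-SD 1.5) so that no
handful of genes carries most of the transcriptome mass; at a few thousand
genes a heavier tail would turn the closure into a noisy per-sample size
factor shared across genes — cross-gene dependence that real closed TPM
matrices do not exhibit.

What the generator does **not** model: read-level sampling, library-size
artifacts, batch effects, gene–gene correlation beyond closure, disease
effects in the CJP/T2D cohorts, or overlap between effect classes (each
gene has exactly one). Consequently, passing recovery tests demonstrate
the procedure's behaviour under clean effect structure, not robustness to
correlated expression programs or technical confounding; and the QC PCA on
synthetic data spreads variance thinly across components rather than
concentrating it as strongly correlated real transcriptomes do.

## Validation experiments and problem sizes

`nervede.validation` provides the Monte-Carlo characterisations used by
the test suite and by `scripts/acceptance.py`:

* **Combined FDR** (`fdr_experiment`): 100 cohorts of 2000 genes ×
  (168+80) donors, σ_noise 0.5, 10% true 2-fold median effects; empirical
  FDR = mean over cohorts of FP/max(1, discoveries) in the union call set.
* **Recovery** (`detection_experiment`): median-level genes at 1.5-fold
  under σ_noise 0.5 (detected at the median level ≳95%), and subset genes
  (π = 0.4, 2-fold) under low noise σ_noise 0.1, the regime where the
  median-level fold gate (median ratio ≈ 1.10 < 1.2) correctly withholds
  the median call while the upper-quartile test carries it (detected
  ≳95%). At σ_noise 0.5 a π = 0.4 subset shift is an upper-tail signal of
  AUC ≈ 0.65 — below any BH cutoff that controls FDR — so the low-noise
  setting is the informative one for the conditional test.
* **Null calibration**: all-null cohorts (BH rejections ≈ 0 per level) and
  sex-label permutations of a fixed cohort (Kolmogorov–Smirnov uniformity
  of median-level p-values).

These sizes were chosen so each experiment is a routine desk-scale run;
the acceptance script completes its 100-cohort sweep in about a minute on
one core.

## Known limitations

* The shared-threshold upper-quartile test is slightly conservative
  (≈4% null rejection at nominal 5%); the own-median variant is retained
  only for sensitivity analysis and should not be used for inference.
* The empirical FDR bound is demonstrated under independent genes;
  strongly co-expressed gene modules in real data would make BH control
  per level hold on average but increase its variability.
* Symbol-based list intersection performs no alias resolution.
* The headline gene counts of any real-cohort analysis (e.g. numbers of
  median-level vs additional upper-quartile calls) depend on the actual
  data's effect-size distribution; the synthetic experiments validate
  operating characteristics, not those counts.
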