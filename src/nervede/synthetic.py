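"""Synthetic two-sex nerve cohorts with ground truth.

The real study data (a controlled-access donor transcriptome resource)
cannot be redistributed, so every downstream stage is exercised on simulated
cohorts that reproduce the statistical structure the analysis assumes:

* baseline gene abundance drawn long-tailed on the log scale;
* log-normal multiplicative measurement noise (the analysis operates
  entirely in TPM space, so noise is modelled there, not at read counts);
* whole-population sex-fold-change genes (median-level effects);
* subset-only sex effects, present in a random fraction pi of one sex's
  donors — the signature the upper-quartile test is designed to catch;
* Y-linked genes absent in females and X-escape genes modestly
  female-biased (canonical positive controls);
* genes whose log-abundance is linear in donor age with sex-specific
  slopes;
* a baseline cohort of 168 male / 80 female donors, with optional
  arthritis (11/10), Type-II-diabetes (44/16) and excluded donors so the
  cohort-assignment rules are exercised end to end.

Because TPM columns are closed (they sum to one million), sex effects on
high-abundance genes would shift *every* other gene's relative abundance
between the sexes and make nominally null genes genuinely sex-biased.  In
real tissue the sex-differential genes are regulatory/signalling genes of
modest abundance whose combined mass footprint is far below a percent of
the transcriptome, so this compositional coupling is negligible.  The
generator preserves that property: effect classes are assigned only to
genes below a configurable baseline-abundance quantile (default the 90th
percentile; with the long-tailed baseline the excluded top decile holds
most of the transcriptome mass).

Each sample's TPM column is renormalized to sum to one million over all
generated genes (coding and non-coding), emulating the upstream
quantification output the pipeline ingests; the coding-only re-constraining
is left to the preprocessing stage.  A truth table labels every gene with
its class and effect parameters for recovery tests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, normalize_metadata

log = logging.getLogger("nervede")

__all__ = ["SimulationConfig", "generate_cohort", "generate_null_permutation"]

TRUTH_CLASSES = ("null", "median_DE", "subset_DE", "y_linked", "x_escape", "age_corr")


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the emulated study's conditions.

    Cohort sizes follow the study (BSL 168 male / 80 female; CJP 11/10;
    T2D 44/16), ages a truncated normal with mean ~51, sd ~13 on the
    21–70 eligibility window.  ``sigma_noise`` is the standard deviation of
    the additive natural-log noise.  Effect magnitudes are multiplicative
    folds; age slopes are natural-log TPM per year.
    """

    n_male: int = 168
    n_female: int = 80
    n_genes: int = 2000
    frac_median_de: float = 0.10
    median_fold: float = 2.0
    frac_subset_de: float = 0.05
    subset_fold: float = 2.0
    subset_pi: float = 0.4
    n_y_linked: int = 8
    n_x_escape: int = 8
    x_escape_fold: float = 1.3
    n_age_corr: int = 20
    age_slope_male: float = 0.0
    age_slope_female: float = -0.02
    sigma_noise: float = 0.5
    frac_noncoding: float = 0.10
    effect_max_abundance_quantile: float = 0.9
    baseline_log_mean: float = 1.5   # natural-log TPM before renormalization
    # ln-sd 1.5 spans ~3-4 decades of abundance while keeping the top gene's
    # mass share small; heavier tails at a few thousand genes would turn the
    # TPM closure into a noisy per-sample size factor shared by all genes,
    # a structure real closed TPM matrices do not have
    baseline_log_sd: float = 1.5
    age_mean: float = 51.0
    age_sd: float = 13.0
    age_min: float = 21.0
    age_max: float = 70.0
    n_cjp_male: int = 11
    n_cjp_female: int = 10
    n_t2d_male: int = 44
    n_t2d_female: int = 16
    n_excluded: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_median_de", "frac_subset_de", "frac_noncoding"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.subset_pi <= 1:
            raise ValueError("subset_pi must lie in (0, 1]")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        n_special = (round(self.frac_median_de * self.n_genes)
                     + round(self.frac_subset_de * self.n_genes)
                     + self.n_y_linked + self.n_x_escape + self.n_age_corr
                     + round(self.frac_noncoding * self.n_genes))
        if n_special > self.n_genes:
            raise ValueError(
                f"config requests {n_special} special genes but only "
                f"{self.n_genes} genes total")


def generate_cohort(config: SimulationConfig,
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(expression, metadata, annotation, truth)``.  A single seeded
    generator drives every draw, so identical configs give bitwise-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    donors = _make_donors(config, rng)
    n_samples = len(donors)
    ng = config.n_genes

    gene_ids = [f"G{i:05d}" for i in range(ng)]
    symbols = [f"SYN{i:05d}" for i in range(ng)]

    # --- baseline abundance, long-tailed on the log scale
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=ng)

    # --- gene classes: effect classes land on coding genes of modest
    # abundance (below the configured baseline quantile) so that their
    # combined mass footprint stays small and closure keeps nulls null;
    # non-coding genes are plain nulls outside the coding universe
    n_noncoding = round(config.frac_noncoding * ng)
    n_median = round(config.frac_median_de * ng)
    n_subset = round(config.frac_subset_de * ng)
    n_effect = (n_median + n_subset + config.n_y_linked + config.n_x_escape
                + config.n_age_corr)
    cap = np.quantile(base, config.effect_max_abundance_quantile)
    eligible = np.flatnonzero(base < cap)
    if n_effect > eligible.size:
        raise ValueError(
            f"config requests {n_effect} effect genes but only {eligible.size} "
            f"genes lie below the abundance quantile")
    order = rng.permutation(eligible)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = order[cursor:cursor + k]
        cursor += k
        return out

    median_idx = take(n_median)
    subset_idx = take(n_subset)
    y_idx = take(config.n_y_linked)
    x_idx = take(config.n_x_escape)
    age_idx = take(config.n_age_corr)
    remaining = np.setdiff1d(np.arange(ng), order[:cursor])
    noncoding_idx = rng.permutation(remaining)[:n_noncoding]

    is_coding = np.ones(ng, dtype=bool)
    is_coding[noncoding_idx] = False
    chromosome = np.array([str(1 + i % 22) for i in range(ng)], dtype=object)
    chromosome[y_idx] = "Y"
    chromosome[x_idx] = "X"

    gene_class = np.full(ng, "null", dtype=object)
    gene_class[median_idx] = "median_DE"
    gene_class[subset_idx] = "subset_DE"
    gene_class[y_idx] = "y_linked"
    gene_class[x_idx] = "x_escape"
    gene_class[age_idx] = "age_corr"

    direction = np.full(ng, "none", dtype=object)
    fold = np.ones(ng)
    pi = np.zeros(ng)
    slope_m = np.zeros(ng)
    slope_f = np.zeros(ng)

    # --- log-scale expression model
    logv = np.tile(base[:, None], (1, n_samples)).astype(float)
    male = (donors["SEX"] == "male").to_numpy()
    female = ~male
    age = donors["AGE"].to_numpy(dtype=float)

    log_fold = np.log(config.median_fold)
    for i in median_idx:
        up_male = bool(rng.integers(0, 2))
        direction[i] = "male_up" if up_male else "female_up"
        fold[i] = config.median_fold
        logv[i, male if up_male else female] += log_fold

    log_sub = np.log(config.subset_fold)
    for i in subset_idx:
        up_male = bool(rng.integers(0, 2))
        direction[i] = "male_up" if up_male else "female_up"
        fold[i] = config.subset_fold
        pi[i] = config.subset_pi
        sex_mask = male if up_male else female
        carriers = sex_mask & (rng.random(n_samples) < config.subset_pi)
        logv[i, carriers] += log_sub

    direction[y_idx] = "male_up"
    fold[y_idx] = np.inf

    direction[x_idx] = "female_up"
    fold[x_idx] = config.x_escape_fold
    for i in x_idx:
        logv[i, female] += np.log(config.x_escape_fold)

    centered_age = age - config.age_mean
    for i in age_idx:
        slope_m[i] = config.age_slope_male
        slope_f[i] = config.age_slope_female
        logv[i, male] += config.age_slope_male * centered_age[male]
        logv[i, female] += config.age_slope_female * centered_age[female]

    if config.sigma_noise > 0:
        logv += rng.normal(0.0, config.sigma_noise, size=logv.shape)
    values = np.exp(logv)
    values[np.ix_(y_idx, np.flatnonzero(female))] = 0.0  # absent transcripts

    # per-sample TPM constraint over all generated genes
    totals = values.sum(axis=0)
    values *= 1_000_000.0 / totals[None, :]

    expression = ExpressionMatrix(gene_ids, list(donors["SAMPID"]), values)
    annotation = pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": symbols,
        "chromosome": chromosome,
        "is_coding": is_coding,
    }).set_index("gene_id", drop=False)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "class": gene_class,
        "direction": direction,
        "fold": fold,
        "pi": pi,
        "slope_male": slope_m,
        "slope_female": slope_f,
    }).set_index("gene_id", drop=False)

    log.info("generate_cohort: %d genes x %d samples (seed %d); classes %s",
             ng, n_samples, config.seed,
             {c: int((gene_class == c).sum()) for c in TRUTH_CLASSES})
    return expression, donors, annotation, truth


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are far enough from the
    mean that acceptance is high)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


_RACES = ["White", "African American/Black", "Asian", "Unknown"]
_RACE_P = [0.863, 0.091, 0.024, 0.022]


def _make_donors(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Donor table: BSL males/females first, then CJP, T2D and excluded
    donors with the corresponding clinical flags set."""
    rows: list[dict] = []

    def add(n: int, sex: str, group: str, flags: dict[str, str] | None = None) -> None:
        ages = _truncated_normal(rng, config.age_mean, config.age_sd,
                                 config.age_min, config.age_max, n)
        hght_mean, hght_sd = (69.8, 3.1) if sex == "male" else (64.8, 2.8)
        wght_mean, wght_sd = (188.8, 32.3) if sex == "male" else (163.6, 26.8)
        for k in range(n):
            row = {
                "SAMPID": f"{group}-{sex[0].upper()}{k:03d}",
                "SEX": sex,
                "AGE": round(float(ages[k]), 1),
                "RACE": _RACES[rng.choice(len(_RACES), p=_RACE_P)],
                "BMI": round(float(np.clip(rng.normal(27.2, 3.9), 18.5, 35.0)), 1),
                "HGHT": round(float(rng.normal(hght_mean, hght_sd)), 1),
                "WGHT": round(float(rng.normal(wght_mean, wght_sd)), 1),
                "MHT1D": "no", "MHT2D": "no", "MHARTHTS": "no", "MHRA": "no",
                "MHSEPSIS": "no", "MHLUPUS": "no", "MHCLLULTS": "no",
                "MHSCLRDRM": "no",
                "MHSRCDSS": "yes" if (sex == "male" and rng.random() < 0.012) else "no",
                "LBHIV1NT": "not performed" if rng.random() < (0.054 if sex == "male" else 0.025)
                            else "negative",
            }
            row.update(flags or {})
            rows.append(row)

    add(config.n_male, "male", "BSL")
    add(config.n_female, "female", "BSL")
    add(config.n_cjp_male, "male", "CJP", {"MHARTHTS": "yes"})
    add(config.n_cjp_female, "female", "CJP", {"MHRA": "yes"})
    add(config.n_t2d_male, "male", "T2D", {"MHT2D": "yes"})
    add(config.n_t2d_female, "female", "T2D", {"MHT2D": "yes"})
    excl_flags = [{"MHSEPSIS": "yes"}, {"MHT1D": "yes"}, {"LBHIV1NT": "positive"},
                  {"MHARTHTS": "yes", "MHT2D": "yes"}]
    for k in range(config.n_excluded):
        sex = "male" if k % 2 == 0 else "female"
        add(1, sex, f"EXC{k}", excl_flags[k % len(excl_flags)])

    df = pd.DataFrame(rows)
    return normalize_metadata(df, age_range=(config.age_min, config.age_max),
                              source="<synthetic>")


def generate_null_permutation(metadata: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Return a copy of the metadata with sex labels permuted uniformly at
    random (all other fields untouched) — the null for label-based tests.

    A single-sex table is returned unchanged with a warning (no permutation
    can break an association that cannot exist).
    """
    out = metadata.copy()
    sexes = out["SEX"].to_numpy()
    if len(set(sexes)) < 2:
        log.warning("generate_null_permutation: single-sex metadata, "
                    "returned unchanged")
        return out
    rng = np.random.default_rng(seed)
    out["SEX"] = rng.permutation(sexes)
    return out


def config_from_dict(raw: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation key(s) {sorted(unknown)}")
    return SimulationConfig(**raw)
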