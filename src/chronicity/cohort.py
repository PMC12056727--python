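"""Synthetic longitudinal cohort generator with known ground truth.

Emulates a late-middle-aged observational cohort followed with serial MRI
(white matter hyperintensity volume, mL), amyloid PET (PiB DVR) and a
cognitive battery: ~240 subjects, baseline ages 45-80, biennial-ish visits,
2-5 MRI and 2-6 PET observations per subject.  Each subject carries a true
age of cerebrovascular (V) and amyloid (A) biomarker onset; observed values
follow monotone post-onset accumulation curves with pre-onset measurement
noise around a sub-threshold floor.  Onset ages of the two markers can be
coupled through a Gaussian copula with a single correlation parameter, and
cognition declines quadratically with age at group-dependent rates.

The generator is the ground-truth bench for the whole pipeline: every
downstream stage (thresholding, onset-age estimation, mixed models) has a
recoverable target in the returned truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "WmhGrowth",
    "DvrGrowth",
    "CognitionModel",
    "CohortConfig",
    "generate_cohort",
    "truth_summary",
    "wmh_curve",
    "dvr_curve",
]

#: onset age assigned to subjects who never become positive (beyond age 120)
NEVER_POSITIVE_ONSET = 150.0


@dataclass(frozen=True)
class WmhGrowth:
    """Post-onset WMH accumulation: exponential in raw mL (log-linear).

    ``value(dt) = max(floor, threshold * exp(log_rate * dt))`` where ``dt``
    is years from onset.  The default rate reaches twice the positivity
    threshold ten years after onset.  ``a_positive_rate_multiplier``
    scales the growth rate for subjects who are truly amyloid positive,
    giving a configurable A-on-V effect (1.0 = independence).
    """

    threshold: float = 2.06          # mL, positivity cutoff the curve crosses at dt=0
    log_rate: float = math.log(2.0) / 10.0   # per year on the log-mL scale
    floor: float = 1.0               # mL, pre-onset noise-floor level
    a_positive_rate_multiplier: float = 1.0


@dataclass(frozen=True)
class DvrGrowth:
    """Post-onset amyloid accumulation: logistic from floor to ceiling.

    The sigmoid crosses ``threshold`` exactly at dt=0 (years from onset).
    """

    threshold: float = 1.19
    floor: float = 1.0
    ceiling: float = 2.5
    steepness: float = 0.12          # per year; ~0.02 DVR/yr near threshold


@dataclass(frozen=True)
class CognitionModel:
    """Quadratic-in-(age-60) cognitive decline with additive A/V effects.

    The fixed-effect mean for a subject in group g is::

        z = intercept + slope_g * (age-60) + quad_g * (age-60)^2
            + sex_effect*sex + reading_effect*reading_z + practice_effect*n_prior

    with ``slope_g = base_slope + a_slope_effect*A+ + v_slope_effect*V+``
    (and analogously for the quadratic term), so the dual-positive group
    declines fastest by construction.  Random intercepts and age slopes are
    correlated bivariate normal; residuals are iid normal per test score.
    """

    intercept: float = 0.0
    base_slope: float = -0.005       # z/yr at age 60, biomarker-negative
    base_quad: float = -0.0005       # z/yr^2
    a_slope_effect: float = -0.020
    v_slope_effect: float = -0.010
    a_quad_effect: float = -0.0010
    v_quad_effect: float = -0.0005
    sex_effect: float = 0.10
    reading_effect: float = 0.30     # per SD of reading score
    practice_effect: float = 0.08    # per prior exposure
    resid_sd: float = 0.25
    re_intercept_sd: float = 0.50
    re_slope_sd: float = 0.020
    re_corr: float = 0.30


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 240
    baseline_age_range: tuple[float, float] = (45.0, 80.0)
    visit_interval: tuple[float, float] = (2.4, 0.8)    # (mean, jitter) years
    n_visits_wmh: tuple[int, int] = (2, 5)
    n_visits_pib: tuple[int, int] = (2, 6)
    n_visits_cognition: tuple[int, int] = (3, 7)
    v_onset_range: tuple[float, float] = (51.8, 78.7)
    a_onset_range: tuple[float, float] = (40.8, 76.2)
    onset_coupling_rho: float = 0.0
    fraction_never_positive_v: float = 0.55
    fraction_never_positive_a: float = 0.50
    noise_sd_wmh: float = 0.12       # SD of log-mL measurement noise
    noise_sd_dvr: float = 0.05       # SD of DVR measurement noise
    wmh_growth: WmhGrowth = field(default_factory=WmhGrowth)
    dvr_growth: DvrGrowth = field(default_factory=DvrGrowth)
    cognition: CognitionModel = field(default_factory=CognitionModel)
    seed: int = 0

    def validate(self) -> None:
        def _ordered(name: str, pair) -> None:
            lo, hi = pair
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"{name} must be an ordered finite (low, high) pair, got {pair!r}")

        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        _ordered("baseline_age_range", self.baseline_age_range)
        _ordered("v_onset_range", self.v_onset_range)
        _ordered("a_onset_range", self.a_onset_range)
        for name in ("n_visits_wmh", "n_visits_pib", "n_visits_cognition"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name}: impossible visit schedule (min {lo}, max {hi})")
        if not -1.0 <= self.onset_coupling_rho <= 1.0:
            raise ValueError("onset_coupling_rho must lie in [-1, 1]")
        mean, jitter = self.visit_interval
        if not np.isfinite(mean) or mean <= 0 or jitter < 0 or jitter >= mean:
            raise ValueError("visit_interval must have mean > jitter >= 0")
        for name in ("noise_sd_wmh", "noise_sd_dvr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for frac in (self.fraction_never_positive_v, self.fraction_never_positive_a):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction_never_positive must lie in [0, 1]")
        if not np.isfinite(self.wmh_growth.log_rate) or self.wmh_growth.log_rate <= 0:
            raise ValueError("wmh_growth.log_rate must be a finite positive rate")
        if self.dvr_growth.floor >= self.dvr_growth.threshold or self.dvr_growth.threshold >= self.dvr_growth.ceiling:
            raise ValueError("dvr_growth must satisfy floor < threshold < ceiling")

    def to_dict(self) -> dict:
        return asdict(self)


def wmh_curve(dt: np.ndarray, growth: WmhGrowth, rate_multiplier: float = 1.0) -> np.ndarray:
    """Noiseless adjusted-WMH value (mL) at ``dt`` years from V onset."""
    dt = np.asarray(dt, dtype=float)
    v = growth.threshold * np.exp(growth.log_rate * rate_multiplier * dt)
    return np.maximum(growth.floor, v)


def dvr_curve(dt: np.ndarray, growth: DvrGrowth) -> np.ndarray:
    """Noiseless PiB DVR at ``dt`` years from A onset (logistic through threshold)."""
    dt = np.asarray(dt, dtype=float)
    span = growth.ceiling - growth.floor
    # shift so the sigmoid crosses the threshold exactly at dt = 0
    t0 = math.log(span / (growth.threshold - growth.floor) - 1.0) / growth.steepness
    return growth.floor + span / (1.0 + np.exp(-growth.steepness * (dt - t0)))


def _visit_ages(rng: np.random.Generator, baseline: float, n: int, interval: tuple[float, float]) -> np.ndarray:
    mean, jitter = interval
    gaps = mean + rng.uniform(-jitter, jitter, size=n - 1) if n > 1 else np.empty(0)
    return np.round(baseline + np.concatenate([[0.0], np.cumsum(gaps)]), 2)


def _draw_onsets(rng: np.random.Generator, cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bivariate onset ages via Gaussian copula with uniform marginals on the configured ranges."""
    n = cfg.n_subjects
    rho = cfg.onset_coupling_rho
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n, method="cholesky")
    u = norm.cdf(z)
    v_lo, v_hi = cfg.v_onset_range
    a_lo, a_hi = cfg.a_onset_range
    onset_v = v_lo + u[:, 0] * (v_hi - v_lo)
    onset_a = a_lo + u[:, 1] * (a_hi - a_lo)
    never_v = rng.random(n) < cfg.fraction_never_positive_v
    never_a = rng.random(n) < cfg.fraction_never_positive_a
    onset_v = np.where(never_v, NEVER_POSITIVE_ONSET, onset_v)
    onset_a = np.where(never_a, NEVER_POSITIVE_ONSET, onset_a)
    return onset_v, onset_a, never_v, never_a


# raw-score scales (offset, scale) for the cognitive battery; the pipeline
# standardizes them internally, so the scales are arbitrary by design
_TEST_SCALES = {
    "pacc3_mem": (50.0, 10.0),
    "pacc3_exec": (100.0, 15.0),
    "pacc3_speed": (40.0, 8.0),
    "ef": (0.0, 1.0),
    "imm_mem": (25.0, 6.0),
    "del_mem": (12.0, 4.0),
}


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns
    -------
    visits : DataFrame
        Long format, one row per biomarker observation:
        ``subject, modality ('wmh'|'pib'), age_at_scan, value``.
    covariates : DataFrame
        One row per subject: ``subject, sex, reading, education``.
    cognition : DataFrame
        One row per cognitive visit: ``subject, age_at_visit,
        practice_count`` plus raw test scores (three PACC3 contributors and
        one test per secondary composite).
    truth : DataFrame
        One row per subject with true onset ages, never-positive flags,
        true positivity at last scan per biomarker, the four-level A/V
        group, and the true linear/quadratic cognitive coefficients.

    All randomness derives from ``config.seed`` through per-subject spawned
    bit streams, so identical configs give bit-identical tables.
    """
    config.validate()
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_subjects + 1)
    rng0 = np.random.default_rng(streams[0])

    onset_v, onset_a, never_v, never_a = _draw_onsets(rng0, cfg)
    sex = rng0.integers(0, 2, size=cfg.n_subjects)
    reading = np.round(rng0.normal(105.0, 10.0, size=cfg.n_subjects), 1)
    education = rng0.integers(12, 21, size=cfg.n_subjects)
    reading_z = (reading - 105.0) / 10.0

    cg = cfg.cognition
    re_cov = np.array([
        [cg.re_intercept_sd**2, cg.re_corr * cg.re_intercept_sd * cg.re_slope_sd],
        [cg.re_corr * cg.re_intercept_sd * cg.re_slope_sd, cg.re_slope_sd**2],
    ])

    visit_rows: list[dict] = []
    cog_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(streams[i + 1])
        sid = f"S{i:04d}"
        baseline = rng.uniform(*cfg.baseline_age_range)
        a_pos_ever = not never_a[i]
        rate_mult = cfg.wmh_growth.a_positive_rate_multiplier if a_pos_ever else 1.0

        ages_w = _visit_ages(rng, baseline, int(rng.integers(cfg.n_visits_wmh[0], cfg.n_visits_wmh[1] + 1)), cfg.visit_interval)
        ages_p = _visit_ages(rng, baseline + rng.uniform(-0.5, 0.5), int(rng.integers(cfg.n_visits_pib[0], cfg.n_visits_pib[1] + 1)), cfg.visit_interval)
        ages_p = np.maximum(ages_p, 0.0)

        wmh_true = wmh_curve(ages_w - onset_v[i], cfg.wmh_growth, rate_mult)
        wmh_obs = wmh_true * np.exp(rng.normal(0.0, cfg.noise_sd_wmh, size=ages_w.size))
        dvr_true = dvr_curve(ages_p - onset_a[i], cfg.dvr_growth)
        dvr_obs = dvr_true + rng.normal(0.0, cfg.noise_sd_dvr, size=ages_p.size)

        for a, v in zip(ages_w, wmh_obs):
            visit_rows.append({"subject": sid, "modality": "wmh", "age_at_scan": a, "value": v})
        for a, v in zip(ages_p, dvr_obs):
            visit_rows.append({"subject": sid, "modality": "pib", "age_at_scan": a, "value": v})

        v_pos_last = ages_w[-1] >= onset_v[i]
        a_pos_last = ages_p[-1] >= onset_a[i]
        group = f"A{'+' if a_pos_last else '-'}V{'+' if v_pos_last else '-'}"

        slope = cg.base_slope + (cg.a_slope_effect if a_pos_last else 0.0) + (cg.v_slope_effect if v_pos_last else 0.0)
        quad = cg.base_quad + (cg.a_quad_effect if a_pos_last else 0.0) + (cg.v_quad_effect if v_pos_last else 0.0)

        n_cog = int(rng.integers(cfg.n_visits_cognition[0], cfg.n_visits_cognition[1] + 1))
        ages_c = _visit_ages(rng, baseline, n_cog, cfg.visit_interval)
        b0, b1 = rng.multivariate_normal([0.0, 0.0], re_cov, method="cholesky")
        for visit_idx, age in enumerate(ages_c):
            ac = age - 60.0
            mean_z = (cg.intercept + slope * ac + quad * ac**2
                      + cg.sex_effect * sex[i] + cg.reading_effect * reading_z[i]
                      + cg.practice_effect * visit_idx)
            latent = mean_z + b0 + b1 * ac
            row = {"subject": sid, "age_at_visit": age, "practice_count": visit_idx}
            for test, (off, scale) in _TEST_SCALES.items():
                row[test] = off + scale * (latent + rng.normal(0.0, cg.resid_sd))
            cog_rows.append(row)

        truth_rows.append({
            "subject": sid,
            "onset_age_v": onset_v[i],
            "onset_age_a": onset_a[i],
            "never_positive_v": bool(never_v[i]),
            "never_positive_a": bool(never_a[i]),
            "v_positive_last": bool(v_pos_last),
            "a_positive_last": bool(a_pos_last),
            "group": group,
            "cog_slope_at60": slope,
            "cog_quad": quad,
        })

    visits = pd.DataFrame(visit_rows).sort_values(["subject", "modality", "age_at_scan"], kind="mergesort").reset_index(drop=True)
    covariates = pd.DataFrame({
        "subject": [f"S{i:04d}" for i in range(cfg.n_subjects)],
        "sex": sex,
        "reading": reading,
        "education": education,
    })
    cognition = pd.DataFrame(cog_rows)
    truth = pd.DataFrame(truth_rows)
    return visits, covariates, cognition, truth


def truth_summary(truth: pd.DataFrame) -> dict:
    """Summarize the ground truth: onset medians, A-before-V gap, group counts.

    The gap is defined as (A onset - V onset) among subjects positive for
    both biomarkers at their last scan; negative gaps mean amyloid onset
    precedes cerebrovascular onset.  Quartiles use linear interpolation.
    With no dual-positive subjects the gap entries are NaN, not an error.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    v_pos = truth["onset_age_v"] < NEVER_POSITIVE_ONSET
    a_pos = truth["onset_age_a"] < NEVER_POSITIVE_ONSET
    dual = truth[truth["v_positive_last"] & truth["a_positive_last"]]
    gap = (dual["onset_age_a"] - dual["onset_age_v"]).to_numpy()
    if gap.size:
        q1, med, q3 = np.percentile(gap, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    return {
        "n_subjects": int(len(truth)),
        "median_onset_v": float(truth.loc[v_pos, "onset_age_v"].median()) if v_pos.any() else float("nan"),
        "median_onset_a": float(truth.loc[a_pos, "onset_age_a"].median()) if a_pos.any() else float("nan"),
        "n_dual_positive": int(len(dual)),
        "gap_median": float(med),
        "gap_q1": float(q1),
        "gap_q3": float(q3),
        "group_counts": truth["group"].value_counts().to_dict(),
    }
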