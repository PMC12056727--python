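"""Sampled iterative local approximation (SILA) of biomarker onset timing.

Learns a biomarker value-versus-time curve from longitudinal observations
in three steps: (1) discrete sampling of the first-order relationship
between the rate of biomarker change and the biomarker level (per-subject
least-squares slope at the subject's mean level); (2) kernel smoothing of
rate over level; (3) Euler integration of the smoothed rate field with the
initial condition time = 0 years at the positivity threshold.  Solving the
resulting monotone curve for the value observed at a reference observation
(the last scan) yields a per-subject time-from-threshold; age of biomarker
onset is the reference age minus that time, and chronicity at any scan is
age at scan minus onset age.  Within a subject the time between
observations is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateSample",
    "RateCurve",
    "ValueTimeCurve",
    "estimate_subject_rates",
    "build_rate_curve",
    "integrate_rate_curve",
    "estimate_time_from_threshold",
    "truncate_chronicity",
    "fit_sila",
]


@dataclass(frozen=True)
class RateSample:
    """One subject's contribution to the rate-vs-level field."""

    subject: str
    level: float        # subject mean biomarker value
    rate: float         # within-subject OLS slope, units/year
    n_obs: int


@dataclass(frozen=True)
class RateCurve:
    """Smoothed rate of change as a function of biomarker level."""

    grid: np.ndarray           # ascending biomarker values spanning the observed range
    rate: np.ndarray           # smoothed rate at each grid point, >= rate_floor
    rate_floor: float
    clamped_fraction: float    # fraction of grid points lifted to the floor

    def rate_at(self, value) -> np.ndarray:
        return np.interp(value, self.grid, self.rate)


@dataclass(frozen=True)
class ValueTimeCurve:
    """Monotone biomarker value versus years from threshold (t = 0 at threshold)."""

    times: np.ndarray          # ascending, years from threshold
    values: np.ndarray         # strictly increasing biomarker values
    threshold: float
    t_min: float
    t_max: float

    def value_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.values)

    def time_at(self, value) -> np.ndarray:
        """Inverse of the curve by monotone interpolation (values are increasing)."""
        return np.interp(value, self.values, self.times)


def estimate_subject_rates(visits: pd.DataFrame, subject_col: str = "subject",
                           age_col: str = "age_at_scan",
                           value_col: str = "value") -> list[RateSample]:
    """Per-subject rate-vs-level samples from longitudinal observations.

    Each subject with >= 2 observations contributes one sample: the ordinary
    least-squares slope of value on age, located at the subject's mean
    value.  Single-observation subjects are excluded from curve training
    (they remain eligible for individual timing estimation).
    """
    samples: list[RateSample] = []
    for sid, grp in visits.groupby(subject_col, sort=True):
        if len(grp) < 2:
            continue
        ages = grp[age_col].to_numpy(dtype=float)
        vals = grp[value_col].to_numpy(dtype=float)
        slope = np.polyfit(ages, vals, 1)[0]
        samples.append(RateSample(subject=str(sid), level=float(vals.mean()),
                                  rate=float(slope), n_obs=len(grp)))
    if not samples:
        raise ValueError("no subject has >= 2 observations; cannot train the rate curve")
    return samples


def build_rate_curve(samples: list[RateSample], grid_size: int = 200,
                     bandwidth: float = 0.10, rate_floor: float = 1e-4) -> RateCurve:
    """Smooth the rate-vs-level samples onto an ascending level grid.

    Tri-cube kernel-weighted mean of rate over level with bandwidth
    expressed as a fraction of the observed value range; the smoothed rate
    is clamped to ``rate_floor`` (> 0) so the integrated value-time curve is
    guaranteed strictly increasing and hence invertible.
    """
    if len(samples) < 5:
        raise ValueError("need at least 5 rate samples to smooth")
    if rate_floor <= 0:
        raise ValueError("rate_floor must be positive")
    levels = np.array([s.level for s in samples])
    rates = np.array([s.rate for s in samples])
    span = levels.max() - levels.min()
    if span <= 0:
        raise ValueError("rate samples span a zero value range")
    h = bandwidth * span
    grid = np.linspace(levels.min(), levels.max(), grid_size)
    d = np.abs(grid[:, None] - levels[None, :]) / h
    w = np.where(d < 1.0, (1.0 - d**3) ** 3, 0.0)
    wsum = w.sum(axis=1)
    if np.any(wsum <= 0):
        raise ValueError("bandwidth too small: some grid points have no support; "
                         "increase the bandwidth")
    smoothed = (w @ rates) / wsum
    clamped = smoothed < rate_floor
    return RateCurve(grid=grid, rate=np.maximum(smoothed, rate_floor),
                     rate_floor=rate_floor,
                     clamped_fraction=float(clamped.mean()))


def integrate_rate_curve(curve: RateCurve, threshold: float,
                         step: float = 0.01, t_horizon: float = 100.0) -> ValueTimeCurve:
    """Euler-integrate the rate field into a value-versus-time curve.

    Starting from the initial condition (t = 0, value = threshold), forward
    Euler advances ``dv = rate(v) * dt`` until the value reaches the top of
    the level grid, and backward Euler retreats until it reaches the bottom;
    the valid time range (t_min, t_max) spans the modelled values.
    ``t_horizon`` bounds the integration in each direction: where the
    smoothed rate sits on the floor (no data-informed change), traversing
    the remaining value range would take arbitrarily long, and times beyond
    the horizon carry no information — observations outside the resulting
    value range are clamped and flagged downstream.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if t_horizon <= 0:
        raise ValueError("t_horizon must be positive")
    lo, hi = curve.grid[0], curve.grid[-1]
    if not lo <= threshold <= hi:
        raise ValueError(f"threshold {threshold} outside modelled value range [{lo}, {hi}]")

    def march(direction: int) -> tuple[list[float], list[float]]:
        ts, vs = [], []
        t, v = 0.0, float(threshold)
        while ((v < hi) if direction > 0 else (v > lo)) and abs(t) < t_horizon:
            t += direction * step
            v += direction * step * float(curve.rate_at(v))
            ts.append(t)
            vs.append(v)
        return ts, vs

    tf, vf = march(+1)
    tb, vb = march(-1)
    times = np.array(tb[::-1] + [0.0] + tf)
    values = np.array(vb[::-1] + [threshold] + vf)
    if not np.all(np.diff(values) > 0):
        raise AssertionError("integrated curve is not strictly increasing; "
                             "rate_floor should make this impossible")
    return ValueTimeCurve(times=times, values=values, threshold=float(threshold),
                          t_min=float(times[0]), t_max=float(times[-1]))


def estimate_time_from_threshold(visits: pd.DataFrame, curve: ValueTimeCurve,
                                 subject_col: str = "subject",
                                 age_col: str = "age_at_scan",
                                 value_col: str = "value") -> pd.DataFrame:
    """Per-observation time from threshold and per-subject onset age.

    The reference observation is the subject's last scan.  Its value is
    solved against the value-time curve (monotone interpolation); values
    outside the modelled range are clamped to the curve's time range and
    flagged.  Every other observation's time from threshold is the
    reference time minus the age difference to the reference, so
    within-subject spacing in time equals spacing in age exactly.  Onset
    age = reference age - reference time from threshold.

    Returns a long table: ``subject, age_at_scan, value, time_from_threshold,
    onset_age, is_reference, below_modelled_range, above_modelled_range``.
    """
    if visits.empty:
        raise ValueError("no observations to estimate")
    out_rows = []
    vmin, vmax = curve.values[0], curve.values[-1]
    for sid, grp in visits.groupby(subject_col, sort=True):
        grp = grp.sort_values(age_col)
        ages = grp[age_col].to_numpy(dtype=float)
        vals = grp[value_col].to_numpy(dtype=float)
        ref_age, ref_val = ages[-1], vals[-1]
        below = bool(ref_val < vmin)
        above = bool(ref_val > vmax)
        t_ref = float(curve.time_at(ref_val))     # np.interp clamps outside the range
        onset = ref_age - t_ref
        t_obs = t_ref - (ref_age - ages)
        for age, val, t in zip(ages, vals, t_obs):
            out_rows.append({
                subject_col: str(sid),
                age_col: age,
                value_col: val,
                "time_from_threshold": t,
                "onset_age": onset,
                "is_reference": bool(age == ref_age),
                "below_modelled_range": below,
                "above_modelled_range": above,
            })
    return pd.DataFrame(out_rows)


def truncate_chronicity(values, floor: float = -20.0):
    """Floor chronicities for display/grouping (e.g. 'years positive' plots).

    Biomarker-negative subjects can receive very negative extrapolated
    times; plots truncate these at -20 years.  Never applied to the
    chronicity table used for modelling on the chronicity scale.
    """
    return np.maximum(np.asarray(values, dtype=float), floor)


def fit_sila(visits: pd.DataFrame, threshold: float, *, grid_size: int = 200,
             bandwidth: float = 0.10, rate_floor: float = 1e-4,
             step: float = 0.01, t_horizon: float = 100.0, log_scale: bool = False,
             subject_col: str = "subject", age_col: str = "age_at_scan",
             value_col: str = "value") -> tuple[ValueTimeCurve, pd.DataFrame]:
    """Train the value-time curve and estimate all subjects in one call.

    Training uses every subject with >= 2 scans regardless of positivity;
    estimation covers all subjects.  With ``log_scale`` the curve is learned
    on the natural-log value scale (threshold transformed accordingly) and
    the returned chronicity table still reports the original values.
    """
    work = visits[[subject_col, age_col, value_col]].copy()
    thr = threshold
    if log_scale:
        work[value_col] = np.log(work[value_col])
        thr = np.log(threshold)
    samples = estimate_subject_rates(work, subject_col, age_col, value_col)
    # widen the bandwidth geometrically if sparse levels leave grid points
    # unsupported (small cohorts); build_rate_curve itself stays strict
    bw = bandwidth
    while True:
        try:
            rc = build_rate_curve(samples, grid_size=grid_size, bandwidth=bw,
                                  rate_floor=rate_floor)
            break
        except ValueError as e:
            if "bandwidth too small" not in str(e) or bw >= 1.0:
                raise
            bw = min(1.0, bw * 1.5)
    vtc = integrate_rate_curve(rc, thr, step=step, t_horizon=t_horizon)
    chron = estimate_time_from_threshold(work, vtc, subject_col, age_col, value_col)
    if log_scale:
        chron[value_col] = np.exp(chron[value_col])
    return vtc, chron
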