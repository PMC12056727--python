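"""SILA contract: rate sampling, smoothing, Euler integration, inversion."""

import numpy as np
import pandas as pd
import pytest

from chronicity.sila import (
    RateCurve,
    RateSample,
    build_rate_curve,
    estimate_subject_rates,
    estimate_time_from_threshold,
    fit_sila,
    integrate_rate_curve,
    truncate_chronicity,
)


def _visits(rows):
    return pd.DataFrame(rows, columns=["subject", "age_at_scan", "value"])


# ---------------------------------------------------------------------------
# rate sampling


def test_two_point_rate_is_exact_slope():
    v = _visits([("S1", 60.0, 1.0), ("S1", 62.0, 1.2)])
    [s] = estimate_subject_rates(v)
    assert s.rate == pytest.approx(0.1)
    assert s.level == pytest.approx(1.1)
    assert s.n_obs == 2


def test_flat_series_rate_zero():
    v = _visits([("S1", 60.0, 2.0), ("S1", 64.0, 2.0)])
    [s] = estimate_subject_rates(v)
    assert s.rate == pytest.approx(0.0, abs=1e-12)


def test_single_observation_subject_excluded():
    v = _visits([("S1", 60.0, 1.0), ("S1", 62.0, 1.2), ("S2", 70.0, 2.5)])
    samples = estimate_subject_rates(v)
    assert [s.subject for s in samples] == ["S1"]


def test_all_single_observation_errors():
    v = _visits([("S1", 60.0, 1.0), ("S2", 61.0, 1.1)])
    with pytest.raises(ValueError):
        estimate_subject_rates(v)


# ---------------------------------------------------------------------------
# smoothing


def _samples(levels, rates):
    return [RateSample(f"S{i}", float(l), float(r), 2)
            for i, (l, r) in enumerate(zip(levels, rates))]


def test_constant_rate_field_smooths_to_constant():
    levels = np.linspace(1.0, 3.0, 50)
    curve = build_rate_curve(_samples(levels, np.full(50, 0.1)))
    assert np.allclose(curve.rate, 0.1)


def test_linear_rate_field_recovered_within_five_percent():
    levels = np.linspace(1.0, 3.0, 400)
    curve = build_rate_curve(_samples(levels, 0.05 * levels))
    interior = slice(20, 180)       # exclude boundary-bias zones
    truth = 0.05 * curve.grid[interior]
    assert np.all(np.abs(curve.rate[interior] - truth) / truth < 0.05)


def test_negative_rates_clamped_to_floor():
    levels = np.linspace(1.0, 3.0, 50)
    curve = build_rate_curve(_samples(levels, np.full(50, -0.2)), rate_floor=1e-4)
    assert np.all(curve.rate >= 1e-4)
    assert curve.clamped_fraction == 1.0


def test_bandwidth_too_small_errors():
    levels = np.concatenate([np.full(5, 1.0), np.full(5, 3.0)])
    with pytest.raises(ValueError, match="bandwidth"):
        build_rate_curve(_samples(levels, np.full(10, 0.1)), bandwidth=0.01)


def test_too_few_samples_errors():
    with pytest.raises(ValueError):
        build_rate_curve(_samples([1.0, 2.0], [0.1, 0.1]))


# ---------------------------------------------------------------------------
# Euler integration


def _curve(grid, rate, floor=1e-4):
    rate = np.maximum(np.asarray(rate, dtype=float), floor)
    return RateCurve(grid=np.asarray(grid, dtype=float), rate=rate,
                     rate_floor=floor, clamped_fraction=0.0)


def test_constant_rate_linear_oracle():
    grid = np.linspace(1.4, 2.6, 200)
    vtc = integrate_rate_curve(_curve(grid, np.full(200, 0.1)), threshold=2.0, step=1e-3)
    t = np.linspace(-5.0, 5.0, 101)
    assert np.max(np.abs(vtc.value_at(t) - (2.0 + 0.1 * t))) <= 1e-6


def test_proportional_rate_exponential_oracle():
    grid = np.linspace(1.0, 3.5, 300)
    vtc = integrate_rate_curve(_curve(grid, 0.05 * grid), threshold=2.0, step=1e-3)
    t = np.linspace(0.0, 10.0, 101)
    assert np.max(np.abs(vtc.value_at(t) - 2.0 * np.exp(0.05 * t))) <= 1e-3


def test_value_at_zero_is_threshold():
    grid = np.linspace(1.0, 3.0, 100)
    vtc = integrate_rate_curve(_curve(grid, np.full(100, 0.08)), threshold=1.7)
    assert vtc.value_at(0.0) == pytest.approx(1.7, abs=1e-12)


def test_integrated_curve_strictly_increasing():
    grid = np.linspace(1.0, 3.0, 100)
    vtc = integrate_rate_curve(_curve(grid, np.full(100, -0.5)), threshold=2.0)
    assert np.all(np.diff(vtc.values) > 0)


def test_threshold_outside_grid_errors():
    grid = np.linspace(1.0, 3.0, 100)
    with pytest.raises(ValueError):
        integrate_rate_curve(_curve(grid, np.full(100, 0.1)), threshold=5.0)


def test_horizon_caps_time_range():
    grid = np.linspace(1.0, 3.0, 100)
    vtc = integrate_rate_curve(_curve(grid, np.full(100, 1e-4)), threshold=2.0,
                               t_horizon=50.0)
    assert vtc.t_min >= -50.1 and vtc.t_max <= 50.1


# ---------------------------------------------------------------------------
# inversion / individual estimation


@pytest.fixture(scope="module")
def linear_curve():
    grid = np.linspace(1.4, 2.6, 200)
    return integrate_rate_curve(_curve(grid, np.full(200, 0.1)), threshold=2.0, step=1e-3)


def test_reference_inversion_linear_curve(linear_curve):
    v = _visits([("S1", 66.0, 2.1), ("S1", 70.0, 2.5)])
    out = estimate_time_from_threshold(v, linear_curve)
    ref = out[out["is_reference"]].iloc[0]
    assert ref["time_from_threshold"] == pytest.approx(5.0, abs=0.01)
    assert ref["onset_age"] == pytest.approx(65.0, abs=0.01)


def test_reference_at_threshold_gets_time_zero(linear_curve):
    v = _visits([("S1", 68.0, 1.8), ("S1", 70.0, 2.0)])
    out = estimate_time_from_threshold(v, linear_curve)
    ref = out[out["is_reference"]].iloc[0]
    assert ref["time_from_threshold"] == pytest.approx(0.0, abs=1e-12)
    assert ref["onset_age"] == pytest.approx(70.0)


def test_earlier_observation_chronicity_by_spacing(linear_curve):
    v = _visits([("S1", 66.0, 2.1), ("S1", 70.0, 2.5)])
    out = estimate_time_from_threshold(v, linear_curve)
    early = out[~out["is_reference"]].iloc[0]
    assert early["time_from_threshold"] == pytest.approx(1.0, abs=0.01)


def test_out_of_range_values_clamped_and_flagged(linear_curve):
    v = _visits([("S1", 60.0, 0.5), ("S1", 64.0, 0.6),
                 ("S2", 60.0, 5.0), ("S2", 64.0, 6.0)])
    out = estimate_time_from_threshold(v, linear_curve)
    low = out[out["subject"] == "S1"]
    high = out[out["subject"] == "S2"]
    assert low["below_modelled_range"].all()
    assert high["above_modelled_range"].all()
    assert low[low["is_reference"]]["time_from_threshold"].iloc[0] == pytest.approx(
        linear_curve.t_min)
    assert high[high["is_reference"]]["time_from_threshold"].iloc[0] == pytest.approx(
        linear_curve.t_max)


def test_within_subject_spacing_preserved_exactly(linear_curve):
    ages = [61.37, 63.81, 66.02, 70.55]
    v = _visits([("S1", a, 1.9 + 0.1 * i) for i, a in enumerate(ages)])
    out = estimate_time_from_threshold(v, linear_curve).sort_values("age_at_scan")
    t = out["time_from_threshold"].to_numpy()
    assert np.allclose(np.diff(t), np.diff(ages), rtol=0, atol=1e-12)


def test_empty_series_errors(linear_curve):
    with pytest.raises(ValueError):
        estimate_time_from_threshold(_visits([]), linear_curve)


def test_truncate_chronicity_floor():
    assert truncate_chronicity(-35.0) == -20.0
    assert truncate_chronicity(-5.0) == -5.0
    assert truncate_chronicity(3.0) == 3.0
    assert np.array_equal(truncate_chronicity([-25.0, 0.0]), [-20.0, 0.0])


# ---------------------------------------------------------------------------
# end-to-end properties of fit_sila


def _noiseless_cohort(n=60, seed=0):
    """Subjects observed on a shared exponential trajectory, no noise."""
    rng = np.random.default_rng(seed)
    rows, onsets = [], {}
    for i in range(n):
        sid = f"S{i:03d}"
        onset = rng.uniform(55.0, 75.0)
        onsets[sid] = onset
        ages = np.sort(rng.uniform(onset - 8.0, onset + 12.0, size=3))
        for a in ages:
            rows.append((sid, a, 2.0 * np.exp(0.05 * (a - onset))))
    return _visits(rows), onsets


def test_noiseless_round_trip_recovers_onsets():
    visits, onsets = _noiseless_cohort()
    _, chron = fit_sila(visits, threshold=2.0)
    est = chron[chron["is_reference"]].set_index("subject")["onset_age"]
    err = np.array([est[s] - o for s, o in onsets.items()])
    # smoother bias is the only error source on noiseless shared-curve data
    assert np.median(np.abs(err)) <= 0.5
    assert np.max(np.abs(err)) <= 2.0


def test_age_shift_invariance():
    visits, _ = _noiseless_cohort(seed=3)
    shifted = visits.copy()
    shifted["age_at_scan"] = shifted["age_at_scan"] + 7.0
    _, a = fit_sila(visits, threshold=2.0)
    _, b = fit_sila(shifted, threshold=2.0)
    assert np.allclose(b["onset_age"], a["onset_age"] + 7.0, atol=1e-9)
    assert np.allclose(b["time_from_threshold"], a["time_from_threshold"], atol=1e-9)


def test_log_scale_reports_original_values():
    visits, _ = _noiseless_cohort(seed=5)
    _, chron = fit_sila(visits, threshold=2.0, log_scale=True)
    merged = chron.merge(visits, on=["subject", "age_at_scan"], suffixes=("", "_orig"))
    assert np.allclose(merged["value"], merged["value_orig"], rtol=1e-12)
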