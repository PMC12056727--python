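"""Mixed-model engine contract: fitting, AICc, pruning, slopes, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronicity import lmm
from chronicity.lmm import ModelFit, ModelSpec, Term, polynomial_terms

# ---------------------------------------------------------------------------
# helpers


def simulate(rng, n_subj=60, n_vis=4, beta=(1.0, 0.5, 0.2, -0.1),
             re_sd=(0.5, 0.1), re_corr=0.3, resid=0.3, interaction=True):
    """Long table from y = b0 + b1 t + b2 g + b3 t*g + u0 + u1 t + e."""
    cov = np.array([[re_sd[0] ** 2, re_corr * re_sd[0] * re_sd[1]],
                    [re_corr * re_sd[0] * re_sd[1], re_sd[1] ** 2]])
    rows = []
    for i in range(n_subj):
        g = float(i % 2)
        u0, u1 = rng.multivariate_normal([0, 0], cov)
        for t in range(n_vis):
            mu = beta[0] + beta[1] * t + beta[2] * g + (beta[3] * t * g if interaction else 0.0)
            rows.append({"subject": f"S{i:03d}", "t": float(t), "g": g,
                         "y": mu + u0 + u1 * t + rng.normal(0, resid)})
    return pd.DataFrame(rows)


FULL_TERMS = (Term(0), Term(1), Term(0, ("g",)), Term(1, ("g",)))
FULL_SPEC = ModelSpec("y", "t", FULL_TERMS, frozenset({"Intercept", "time", "g"}))


def make_fit(terms, llf_ml, k_params, n_obs=500, params=None):
    """Minimal ModelFit for arithmetic-level tests (no fitting involved)."""
    names = [t.name for t in terms]
    p = pd.Series(params if params is not None else np.zeros(len(names)), index=names)
    one = pd.Series(np.ones(len(names)), index=names)
    eye = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    return ModelFit(spec=ModelSpec("y", "t", tuple(terms)), params=p, bse=one,
                    pvalues=one, cov_fixed=eye, re_cov=np.eye(2), resid_var=1.0,
                    llf_reml=llf_ml, llf_ml=llf_ml, n_obs=n_obs, n_groups=50,
                    k_params=k_params, converged=True)


# ---------------------------------------------------------------------------
# terms


def test_term_names_and_order():
    assert Term(0).name == "Intercept"
    assert Term(1).name == "time"
    assert Term(2, ("g",)).name == "time^2:g"
    assert Term(2, ("g",)).order == 3


def test_term_hierarchy():
    assert Term(1, ("g",)).contains(Term(1))
    assert Term(1, ("g",)).contains(Term(0, ("g",)))
    assert not Term(1).contains(Term(0, ("g",)))


def test_polynomial_terms_structure():
    names = [t.name for t in polynomial_terms(2, status="g", covariates=("c",))]
    assert names == ["Intercept", "g", "time", "time:g", "time^2", "time^2:g", "c"]


# ---------------------------------------------------------------------------
# fitting


def test_fit_recovers_known_coefficients_across_replicates():
    rng = np.random.default_rng(11)
    beta = np.array([1.0, 0.5, 0.2, -0.1])
    hits = total = 0
    for _ in range(60):
        fit = lmm.fit_lmm(FULL_SPEC, simulate(rng), ml_refit=False)
        within = np.abs(fit.params.to_numpy() - beta) <= 3.0 * fit.bse.to_numpy()
        hits += int(within.sum())
        total += within.size
    assert hits / total >= 0.95


def test_exact_linear_outcome_zero_residual():
    rows = [{"subject": f"S{i}", "t": float(t), "y": 2.0 + 0.3 * t}
            for i in range(30) for t in range(4)]
    fit = lmm.fit_lmm(ModelSpec("y", "t", (Term(0), Term(1))), pd.DataFrame(rows))
    assert fit.resid_var <= 1e-8
    assert fit.params["Intercept"] == pytest.approx(2.0, abs=1e-6)
    assert fit.params["time"] == pytest.approx(0.3, abs=1e-6)


def test_zero_random_effect_variance_detected():
    rng = np.random.default_rng(4)
    rows = [{"subject": f"S{i}", "t": float(t), "y": 1.0 + 0.5 * t + rng.normal(0, 0.3)}
            for i in range(60) for t in range(4)]
    fit = lmm.fit_lmm(ModelSpec("y", "t", (Term(0), Term(1))), pd.DataFrame(rows))
    if fit.re_structure == "intercept+slope":
        assert fit.re_cov[1, 1] <= 0.01 ** 2 * 5     # slope variance near zero
    else:
        assert fit.re_structure == "intercept"


def test_singular_design_names_aliased_terms():
    rng = np.random.default_rng(5)
    d = simulate(rng, n_subj=20)
    d["g2"] = d["g"]
    spec = ModelSpec("y", "t", (Term(0), Term(1), Term(0, ("g",)), Term(0, ("g2",))))
    with pytest.raises(ValueError, match="aliased"):
        lmm.fit_lmm(spec, d)


def test_fit_requires_repeated_measures():
    d = pd.DataFrame({"subject": ["a", "b"], "t": [0.0, 1.0], "y": [0.0, 1.0]})
    with pytest.raises(ValueError):
        lmm.fit_lmm(ModelSpec("y", "t", (Term(0), Term(1))), d)


def test_coefficient_table_ci_width():
    rng = np.random.default_rng(6)
    fit = lmm.fit_lmm(FULL_SPEC, simulate(rng), ml_refit=False)
    tab = fit.coefficient_table()
    width = tab["ci_high"] - tab["ci_low"]
    assert np.allclose(width, 2 * stats.norm.ppf(0.975) * tab["se"])
    assert ((tab["ci_low"] <= tab["estimate"]) & (tab["estimate"] <= tab["ci_high"])).all()


# ---------------------------------------------------------------------------
# AICc


def test_aicc_direct_arithmetic():
    assert lmm.aicc_value(50.0, 2, 100) == pytest.approx(50.0 + 12.0 / 97.0)


def test_aicc_asymptotic_limit():
    assert lmm.aicc_value(100.0, 5, 10**6) - 100.0 < 1e-4


def test_aicc_guard_small_n():
    with pytest.raises(ValueError):
        lmm.aicc_value(10.0, 99, 100)


def test_aicc_exceeds_aic():
    fit = make_fit(list(FULL_TERMS), llf_ml=-100.0, k_params=8, n_obs=200)
    assert lmm.aicc(fit) > fit.aic_ml


# ---------------------------------------------------------------------------
# pruning


def test_prune_null_interaction_removed_at_nominal_rate():
    rng = np.random.default_rng(21)
    removed = 0
    for _ in range(100):
        d = simulate(rng, n_subj=40, n_vis=3, interaction=False)
        fit, _ = lmm.prune_model(FULL_SPEC, d, alpha=0.05)
        removed += int("time:g" not in fit.params.index)
    # binomial envelope around 0.95 at 100 replicates
    assert 0.88 <= removed / 100 <= 1.0


def test_prune_retains_strong_interaction():
    rng = np.random.default_rng(22)
    d = simulate(rng, n_subj=80, beta=(1.0, 0.5, 0.2, -0.6))
    fit, log = lmm.prune_model(FULL_SPEC, d)
    assert "time:g" in fit.params.index
    assert log == []


def test_prune_protected_terms_always_present():
    rng = np.random.default_rng(23)
    d = simulate(rng, n_subj=40, beta=(0.0, 0.0, 0.0, 0.0))
    fit, _ = lmm.prune_model(FULL_SPEC, d)
    for name in ("Intercept", "time", "g"):
        assert name in fit.params.index


def test_prune_respects_hierarchy():
    rng = np.random.default_rng(24)
    d = simulate(rng, n_subj=50, beta=(1.0, 0.3, 0.0, -0.5))
    spec = ModelSpec("y", "t", FULL_TERMS, frozenset({"Intercept", "time"}))
    fit, log = lmm.prune_model(spec, d)
    # while time:g stays, its contained main effect g may never be removed
    if "time:g" in fit.params.index:
        assert "g" in fit.params.index


def test_prune_is_deterministic():
    rng = np.random.default_rng(25)
    d = simulate(rng, n_subj=40, interaction=False)
    f1, l1 = lmm.prune_model(FULL_SPEC, d)
    f2, l2 = lmm.prune_model(FULL_SPEC, d)
    assert l1 == l2
    pd.testing.assert_series_equal(f1.params, f2.params)


# ---------------------------------------------------------------------------
# simple slopes


def test_simple_slope_quadratic_arithmetic():
    fit = make_fit([Term(0), Term(1), Term(2)], llf_ml=0.0, k_params=5,
                   params=[0.0, 0.01, 0.001])
    [s] = lmm.simple_slopes(fit, [10.0], [{}])
    assert s.estimate == pytest.approx(0.03)


def test_simple_slope_constant_without_curvature():
    fit = make_fit([Term(0), Term(1)], llf_ml=0.0, k_params=4, params=[1.0, 0.25])
    slopes = lmm.simple_slopes(fit, [0.0, 5.0, 50.0], [{}])
    assert all(s.estimate == pytest.approx(0.25) for s in slopes)


def test_simple_slope_group_interaction():
    fit = make_fit([Term(0), Term(1), Term(1, ("g",))], llf_ml=0.0, k_params=5,
                   params=[0.0, 0.01, 0.02])
    [s] = lmm.simple_slopes(fit, [3.0], [{"g": 1.0}])
    assert s.estimate == pytest.approx(0.03)


def test_simple_slope_unknown_factor_errors():
    fit = make_fit([Term(0), Term(1)], llf_ml=0.0, k_params=4)
    with pytest.raises(ValueError):
        lmm.simple_slopes(fit, [0.0], [{"nope": 1.0}])


def test_slope_difference_constructed_interaction():
    fit = make_fit([Term(0), Term(1), Term(1, ("g",))], llf_ml=0.0, k_params=5,
                   params=[0.0, 0.056, -0.019])
    d = lmm.slope_difference(fit, 0.0, {"g": 1.0}, {"g": 0.0})
    assert d.estimate == pytest.approx(-0.019)
    assert d.ci_low == pytest.approx(d.estimate - stats.norm.ppf(0.975) * d.se)
    assert d.ci_high == pytest.approx(d.estimate + stats.norm.ppf(0.975) * d.se)


def test_slope_difference_identical_settings_zero():
    fit = make_fit([Term(0), Term(1), Term(1, ("g",))], llf_ml=0.0, k_params=5,
                   params=[0.0, 0.056, -0.019])
    d = lmm.slope_difference(fit, 2.0, {"g": 1.0}, {"g": 1.0})
    assert d.estimate == 0.0
    assert d.ci_low == pytest.approx(-d.ci_high)


def test_simple_slope_matches_finite_difference():
    rng = np.random.default_rng(31)
    d = simulate(rng, n_subj=50)
    spec = ModelSpec("y", "t", tuple(polynomial_terms(2, status="g")))
    fit = lmm.fit_lmm(spec, d, ml_refit=False)
    h = 1e-5
    for setting in ({"g": 0.0}, {"g": 1.0}):
        for t in (0.0, 1.7, 3.0):
            [s] = lmm.simple_slopes(fit, [t], [setting])
            fd = (fit.predict_mean(t + h, setting) - fit.predict_mean(t - h, setting)) / (2 * h)
            assert abs(s.estimate - float(fd[0])) <= 1e-6 * max(1.0, abs(s.estimate))


# ---------------------------------------------------------------------------
# Wald and likelihood-ratio tests


def test_joint_wald_on_zero_block():
    rng = np.random.default_rng(41)
    d = simulate(rng, n_subj=60, interaction=False)
    fit = lmm.fit_lmm(FULL_SPEC, d, ml_refit=False)
    stat, df, p = lmm.joint_wald_test(fit, ["time:g"])
    assert df == 1 and stat >= 0.0 and 0.0 <= p <= 1.0
    with pytest.raises(ValueError):
        lmm.joint_wald_test(fit, ["absent"])


def test_lrt_identical_models_is_trivial():
    rng = np.random.default_rng(42)
    d = simulate(rng, n_subj=30)
    f1 = lmm.fit_lmm(FULL_SPEC, d)
    f2 = lmm.fit_lmm(FULL_SPEC, d)
    assert lmm.likelihood_ratio_test(f1, f2) == (0.0, 0, 1.0)


def test_lrt_chi_square_quantile_identity():
    nested = make_fit([Term(0), Term(1)], llf_ml=0.0, k_params=5)
    full = make_fit([Term(0), Term(1), Term(0, ("g",))], llf_ml=1.92, k_params=6)
    stat, df, p = lmm.likelihood_ratio_test(nested, full)
    assert stat == pytest.approx(3.84)
    assert df == 1
    assert p == pytest.approx(0.05, abs=1e-3)


def test_lrt_rejects_non_nested_and_negative_stat():
    nested = make_fit([Term(0), Term(1), Term(0, ("h",))], llf_ml=0.0, k_params=5)
    full = make_fit([Term(0), Term(1), Term(0, ("g",))], llf_ml=1.0, k_params=6)
    with pytest.raises(ValueError):
        lmm.likelihood_ratio_test(nested, full)
    worse = make_fit([Term(0), Term(1), Term(0, ("g",))], llf_ml=-5.0, k_params=6)
    base = make_fit([Term(0), Term(1)], llf_ml=0.0, k_params=5)
    with pytest.raises(RuntimeError):
        lmm.likelihood_ratio_test(base, worse)


def test_lrt_null_pvalues_uniform():
    rng = np.random.default_rng(43)
    base_spec = ModelSpec("y", "t", (Term(0), Term(1)))
    full_spec = ModelSpec("y", "t", (Term(0), Term(1), Term(0, ("g",))))
    pvals = []
    for _ in range(200):
        d = simulate(rng, n_subj=30, n_vis=3, beta=(1.0, 0.5, 0.0, 0.0))
        nested = lmm.fit_lmm(base_spec, d)
        full = lmm.fit_lmm(full_spec, d)
        pvals.append(lmm.likelihood_ratio_test(nested, full)[2])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# AICc comparison and Tukey contrasts


def _fit_with_aicc(terms, target_aicc, k, n=1000):
    # invert AICc = -2 llf + 2k + 2k(k+1)/(n-k-1) for llf
    llf = -(target_aicc - 2 * k - 2 * k * (k + 1) / (n - k - 1)) / 2.0
    return make_fit(terms, llf_ml=llf, k_params=k, n_obs=n)


def test_compare_aicc_co_best_rule():
    fits = {
        "m1": _fit_with_aicc([Term(0)], 100.0, 4),
        "m3": _fit_with_aicc([Term(0)], 101.5, 4),
        "m4": _fit_with_aicc([Term(0)], 120.0, 4),
    }
    tab = lmm.compare_aicc(fits)
    assert list(tab["model"]) == ["m1", "m3", "m4"]
    assert list(tab["co_best"]) == [True, True, False]
    assert tab["delta_aicc"].iloc[0] == 0.0


def test_compare_aicc_single_fit_trivially_best():
    tab = lmm.compare_aicc({"only": _fit_with_aicc([Term(0)], 90.0, 4)})
    assert len(tab) == 1 and bool(tab["co_best"].iloc[0])


def test_compare_aicc_excluded_label_absent():
    fits = {"m1": _fit_with_aicc([Term(0)], 100.0, 4),
            "m2": _fit_with_aicc([Term(0)], 50.0, 4)}
    tab = lmm.compare_aicc(fits, exclude=("m2",))
    assert "m2" not in set(tab["model"])


def test_compare_aicc_differing_n_errors():
    fits = {"a": _fit_with_aicc([Term(0)], 100.0, 4, n=1000),
            "b": _fit_with_aicc([Term(0)], 100.0, 4, n=900)}
    with pytest.raises(ValueError):
        lmm.compare_aicc(fits)


def test_tukey_pairwise_structure():
    est = {"A": 0.0, "B": 0.1, "C": 1.0}
    ses = {"A": 0.05, "B": 0.05, "C": 0.05}
    tab = lmm.tukey_pairwise(est, ses)
    assert len(tab) == 3
    big = tab[tab["pair"] == "A - C"].iloc[0]
    small = tab[tab["pair"] == "A - B"].iloc[0]
    assert big["p_adj"] < 0.001 < small["p_adj"]
    bonf = lmm.tukey_pairwise(est, ses, method="bonferroni")
    assert (bonf["p_adj"] <= 1.0).all()
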