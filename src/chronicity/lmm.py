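"""Linear mixed-effects engine for trajectory modelling.

Wraps REML/ML fitting (random intercept + correlated time slope per
subject) and implements the surrounding inference machinery used by the
trajectory analyses: sequential backward pruning of interaction terms,
small-sample AICc comparison with a co-best rule, analytic simple slopes
and slope differences with delta-method intervals, joint Wald tests of
interaction blocks, and likelihood-ratio tests of nested fits.

Fixed-effect structures are built from explicit :class:`Term` objects —
products of a power of the time variable with zero or more numeric factor
columns (group indicators, covariates).  This keeps the derivative of the
fitted mean with respect to time available in closed form, so simple slopes
are exact rather than finite-differenced.

Inference is Wald/normal on the fixed-effect covariance (the fitting
backend does not provide Kenward-Roger degrees of freedom; the deviation is
recorded in fit metadata).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "Term",
    "ModelSpec",
    "ModelFit",
    "SimpleSlope",
    "fit_lmm",
    "aicc",
    "aicc_value",
    "prune_model",
    "simple_slopes",
    "slope_difference",
    "joint_wald_test",
    "likelihood_ratio_test",
    "compare_aicc",
    "tukey_pairwise",
    "polynomial_terms",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class Term:
    """One fixed-effect column: time^power x product of factor columns."""

    time_power: int = 0
    factors: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(sorted(self.factors)))

    @property
    def name(self) -> str:
        parts = []
        if self.time_power == 1:
            parts.append("time")
        elif self.time_power > 1:
            parts.append(f"time^{self.time_power}")
        parts.extend(self.factors)
        return ":".join(parts) if parts else "Intercept"

    @property
    def order(self) -> int:
        return self.time_power + len(self.factors)

    def contains(self, other: "Term") -> bool:
        """Hierarchy: this term subsumes ``other`` (strictly higher order)."""
        return (self != other and other.time_power <= self.time_power
                and set(other.factors) <= set(self.factors)
                and self.order > other.order)

    def column(self, data: pd.DataFrame, time: np.ndarray) -> np.ndarray:
        col = np.ones(len(data)) if self.time_power == 0 else time ** self.time_power
        for f in self.factors:
            col = col * data[f].to_numpy(dtype=float)
        return col

    def dcolumn_dtime(self, t: float, setting: dict[str, float]) -> float:
        """d(column)/d(time) at time t with factor columns fixed at ``setting``."""
        if self.time_power == 0:
            return 0.0
        g = self.time_power * t ** (self.time_power - 1)
        for f in self.factors:
            g *= setting.get(f, 0.0)
        return g

    def value_at(self, t: float, setting: dict[str, float]) -> float:
        v = t ** self.time_power if self.time_power else 1.0
        for f in self.factors:
            v *= setting.get(f, 0.0)
        return v


def polynomial_terms(degree: int, status: str | None = None,
                     covariates: tuple[str, ...] = ()) -> list[Term]:
    """Intercept + time..time^degree, each interacted with a status column,
    plus status main effect and additive covariates."""
    terms = [Term(0)]
    if status is not None:
        terms.append(Term(0, (status,)))
    for p in range(1, degree + 1):
        terms.append(Term(p))
        if status is not None:
            terms.append(Term(p, (status,)))
    terms.extend(Term(0, (c,)) for c in covariates)
    return terms


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification over a long-format table.

    ``time`` names the column used both as the fixed-effect time variable
    and as the random-slope variable; ``protected`` lists term names never
    removed by pruning (the intercept, status main effects and linear time
    are always protected in the builders).
    """

    outcome: str
    time: str
    terms: tuple[Term, ...]
    protected: frozenset[str] = frozenset()
    groups: str = "subject"
    label: str = ""

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]


@dataclass
class ModelFit:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_fixed: pd.DataFrame
    re_cov: np.ndarray            # 2x2 random intercept/slope covariance
    resid_var: float
    llf_reml: float
    llf_ml: float
    n_obs: int
    n_groups: int
    k_params: int                 # fixed effects + variance components
    converged: bool
    df_method: str = "wald-normal"
    re_structure: str = "intercept+slope"
    #: cluster-robust (sandwich) fixed-effect covariance with a small-sample
    #: m/(m-1) factor; valid under mean/covariance misspecification
    robust_cov_fixed: pd.DataFrame | None = None

    @property
    def aic_ml(self) -> float:
        return -2.0 * self.llf_ml + 2.0 * self.k_params

    def coefficient_table(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(),
            "z": z.to_numpy(),
            "p": self.pvalues.to_numpy(),
            "ci_low": (self.params - _Z95 * self.bse).to_numpy(),
            "ci_high": (self.params + _Z95 * self.bse).to_numpy(),
        }).reset_index(drop=True)

    def predict_mean(self, t, setting: dict[str, float]) -> np.ndarray:
        """Fixed-effect mean trajectory at times ``t`` under ``setting``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for term in self.spec.terms:
            beta = self.params[term.name]
            out += beta * np.array([term.value_at(ti, setting) for ti in t])
        return out


@dataclass(frozen=True)
class SimpleSlope:
    at_time: float
    setting: tuple[tuple[str, float], ...]
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


def _design_matrix(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    time = data[spec.time].to_numpy(dtype=float)
    X = np.column_stack([t.column(data, time) for t in spec.terms])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the design matrix")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate aliased columns by incremental rank
        aliased = []
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j - len(aliased):
                aliased.append(spec.terms[j - 1].name)
        raise ValueError(f"singular design matrix; aliased terms: {aliased or 'unknown'}")
    return X


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, ml_refit: bool = True) -> ModelFit:
    """Fit the mixed model: REML for coefficient inference, ML refit for IC.

    Random effects are a correlated intercept and time slope per subject.
    Wald statistics and p-values come from the REML fixed-effect covariance.
    With ``ml_refit=False`` the ML pass is skipped (llf_ml is NaN) — cheaper
    when only Wald inference is needed.
    """
    n_sub_multi = data.groupby(spec.groups).size()
    if (n_sub_multi >= 2).sum() == 0:
        raise ValueError("no subject has >= 2 observations; mixed model unidentified")
    y = data[spec.outcome].to_numpy(dtype=float)
    X = _design_matrix(spec, data)
    groups = data[spec.groups].to_numpy()
    exog_re = np.column_stack([np.ones(len(data)), data[spec.time].to_numpy(dtype=float)])
    names = spec.term_names()

    k_fe = X.shape[1]

    def _ok(res) -> bool:
        if res is None or not np.all(np.isfinite(np.asarray(res.fe_params))):
            return False
        d = np.diag(np.asarray(res.cov_params())[:k_fe, :k_fe])
        return bool(np.all(np.isfinite(d)) and np.all(d >= 0))

    def _fit(reml: bool):
        # if the slope variance is estimated on the boundary the information
        # matrix can be indefinite; fall back to a random intercept only
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            for re_cols in (exog_re, exog_re[:, :1]):
                model = MixedLM(y, X, groups=groups, exog_re=re_cols)
                for method, maxiter in (("lbfgs", 200), ("powell", 800), ("cg", 500)):
                    try:
                        res = model.fit(reml=reml, method=method, maxiter=maxiter)
                    except Exception:
                        res = None
                    if _ok(res):
                        return res, re_cols.shape[1]
        raise RuntimeError(
            f"mixed-model optimizer failed (reml={reml}): "
            "non-finite estimates or indefinite fixed-effect covariance "
            "even with a random intercept only")

    res_reml, n_re = _fit(True)
    res_ml = _fit(False)[0] if ml_refit else None

    k_fixed = X.shape[1]
    # + RE covariance (2 var + 1 cov, or 1 var on fallback) + residual var
    k_params = k_fixed + (3 if n_re == 2 else 1) + 1

    re_cov_hat = np.atleast_2d(np.asarray(res_reml.cov_re)) * res_reml.scale
    robust = _cluster_robust_cov(X, y, exog_re[:, :n_re], groups,
                                 np.asarray(res_reml.fe_params), re_cov_hat,
                                 float(res_reml.scale))
    cov = pd.DataFrame(np.asarray(res_reml.cov_params())[:k_fixed, :k_fixed],
                       index=names, columns=names)
    params = pd.Series(np.asarray(res_reml.fe_params), index=names)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
    zvals = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(zvals)), index=names)
    return ModelFit(
        spec=spec,
        params=params,
        bse=bse,
        pvalues=pvals,
        cov_fixed=cov,
        re_cov=re_cov_hat,
        resid_var=float(res_reml.scale),
        llf_reml=float(res_reml.llf),
        llf_ml=float(res_ml.llf) if res_ml is not None else float("nan"),
        n_obs=len(data),
        n_groups=int(pd.Series(groups).nunique()),
        k_params=k_params,
        converged=bool(res_reml.converged and (res_ml is None or res_ml.converged)),
        re_structure="intercept+slope" if n_re == 2 else "intercept",
        robust_cov_fixed=pd.DataFrame(robust, index=names, columns=names),
    )


def _cluster_robust_cov(X: np.ndarray, y: np.ndarray, Z: np.ndarray,
                        groups: np.ndarray, beta: np.ndarray,
                        re_cov: np.ndarray, resid_var: float) -> np.ndarray:
    """Sandwich covariance of the GLS fixed effects, clustered by subject.

    ``A^{-1} B A^{-1}`` with ``A = sum_i X_i' V_i^{-1} X_i`` using the
    fitted marginal covariance ``V_i = Z_i G Z_i' + s^2 I``.  The meat uses
    the CR2 (Bell-McCaffrey) small-sample correction: on the GLS-whitened
    data the per-cluster residuals are inflated by ``(I - H_ii)^{-1/2}``,
    removing the downward leverage bias that makes the plain (CR0/CR1)
    sandwich anti-conservative with moderately many clusters.
    """
    p = X.shape[1]
    r = y - X @ beta
    codes, _ = pd.factorize(groups)
    m = codes.max() + 1
    # whiten per cluster: GLS equals OLS on (W^{1/2} X, W^{1/2} y)
    Xt_list, rt_list = [], []
    A = np.zeros((p, p))
    for g in range(m):
        idx = codes == g
        Zi = Z[idx]
        Vi = Zi @ re_cov @ Zi.T + resid_var * np.eye(int(idx.sum()))
        evals, evecs = np.linalg.eigh(np.linalg.inv(Vi))
        sqrtW = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0))) @ evecs.T
        Xt = sqrtW @ X[idx]
        Xt_list.append(Xt)
        rt_list.append(sqrtW @ r[idx])
        A += Xt.T @ Xt
    Ainv = np.linalg.inv(A)
    B = np.zeros((p, p))
    for Xt, rt in zip(Xt_list, rt_list):
        Hii = Xt @ Ainv @ Xt.T
        evals, evecs = np.linalg.eigh(np.eye(len(rt)) - Hii)
        inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T
        u = Xt.T @ inv_sqrt @ rt
        B += np.outer(u, u)
    return Ainv @ B @ Ainv


def aicc_value(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``AIC + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n_obs ({n}) must exceed n_params + 1 ({k + 1})")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(fit: ModelFit) -> float:
    """AICc of a fit, from its ML log-likelihood; the parameter count k
    includes fixed effects and variance components."""
    return aicc_value(fit.aic_ml, fit.k_params, fit.n_obs)


def prune_model(spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
                ) -> tuple[ModelFit, list[dict]]:
    """Sequential backward elimination of non-significant interaction terms.

    At each step the removable terms are those not protected and not
    contained in any other remaining term (hierarchy is respected: a main
    effect cannot leave while its interaction stays).  Among removable terms
    with p >= alpha the highest-order one is removed, ties broken by larger
    p then lexicographic name; the model is refitted and the loop repeats
    until every remaining removable term is significant.  The log records
    each removal with its p-value, making the path replayable.
    """
    current = spec
    log: list[dict] = []
    while True:
        fit = fit_lmm(current, data)
        terms = list(current.terms)
        removable = [t for t in terms
                     if t.name not in current.protected and t.name != "Intercept"
                     and not any(u.contains(t) for u in terms)]
        candidates = [(t, float(fit.pvalues[t.name])) for t in removable
                      if fit.pvalues[t.name] >= alpha]
        if not candidates:
            return fit, log
        candidates.sort(key=lambda tp: (-tp[0].order, -tp[1], tp[0].name))
        drop, p = candidates[0]
        log.append({"removed": drop.name, "p": p, "order": drop.order})
        current = replace(current, terms=tuple(t for t in terms if t != drop))


def _slope_gradient(fit: ModelFit, t: float, setting: dict[str, float]) -> np.ndarray:
    return np.array([term.dcolumn_dtime(t, setting) for term in fit.spec.terms])


def simple_slopes(fit: ModelFit, at_values, settings: list[dict[str, float]]
                  ) -> list[SimpleSlope]:
    """Analytic d(mean)/d(time) at given times and factor settings.

    The slope is the derivative of the fixed-effect mean with respect to
    the time variable (b_time + 2 b_time^2 t + interaction contributions);
    its standard error is the delta-method form ``sqrt(c' Sigma c)`` with c
    the gradient of the slope in coefficient space.
    """
    out = []
    Sigma = fit.cov_fixed.to_numpy()
    beta = fit.params.to_numpy()
    for setting in settings:
        unknown = set(setting) - {f for term in fit.spec.terms for f in term.factors}
        if unknown:
            raise ValueError(f"setting refers to factors absent from the model: {sorted(unknown)}")
        for t in np.atleast_1d(at_values):
            c = _slope_gradient(fit, float(t), setting)
            est = float(c @ beta)
            se = float(math.sqrt(max(c @ Sigma @ c, 0.0)))
            p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else float("nan")
            out.append(SimpleSlope(at_time=float(t),
                                   setting=tuple(sorted(setting.items())),
                                   estimate=est, se=se,
                                   ci_low=est - _Z95 * se, ci_high=est + _Z95 * se,
                                   p=float(p)))
    return out


def slope_difference(fit: ModelFit, at_value: float, setting_a: dict[str, float],
                     setting_b: dict[str, float]) -> SimpleSlope:
    """Difference of simple slopes (a minus b) with delta-method CI from the
    joint fixed-effect covariance."""
    Sigma = fit.cov_fixed.to_numpy()
    beta = fit.params.to_numpy()
    c = _slope_gradient(fit, at_value, setting_a) - _slope_gradient(fit, at_value, setting_b)
    est = float(c @ beta)
    se = float(math.sqrt(max(c @ Sigma @ c, 0.0)))
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else float("nan")
    return SimpleSlope(at_time=float(at_value),
                       setting=tuple(sorted(setting_a.items())),
                       estimate=est, se=se,
                       ci_low=est - _Z95 * se, ci_high=est + _Z95 * se, p=float(p))


def joint_wald_test(fit: ModelFit, term_names: list[str],
                    robust: bool = False) -> tuple[float, int, float]:
    """Joint chi-square Wald test that a block of coefficients is zero.

    With ``robust=True`` the cluster-robust sandwich covariance is used —
    appropriate when the mean or residual-covariance model may be
    misspecified (notably the own-chronicity model, whose time axis is
    derived from the outcome itself).
    """
    missing = [n for n in term_names if n not in fit.params.index]
    if missing:
        raise ValueError(f"terms not in model: {missing}")
    idx = [list(fit.params.index).index(n) for n in term_names]
    b = fit.params.to_numpy()[idx]
    cov = fit.robust_cov_fixed if robust else fit.cov_fixed
    if cov is None:
        raise ValueError("robust covariance unavailable on this fit")
    V = cov.to_numpy()[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


def likelihood_ratio_test(nested: ModelFit, full: ModelFit) -> tuple[float, int, float]:
    """LRT of nested against full (ML log-likelihoods, chi-square reference)."""
    if nested.n_obs != full.n_obs:
        raise ValueError("fits are on different observation sets")
    if not set(nested.spec.term_names()) <= set(full.spec.term_names()):
        raise ValueError("models are not nested (fixed-effect terms not a subset)")
    stat = 2.0 * (full.llf_ml - nested.llf_ml)
    df = full.k_params - nested.k_params
    if df == 0:
        return 0.0, 0, 1.0      # identical specifications
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'nested'")
    if stat < -1e-6:
        raise RuntimeError(f"negative LRT statistic ({stat:.4g}): an optimizer "
                           "failed to reach its maximum; refit before testing")
    return float(stat), df, float(stats.chi2.sf(max(stat, 0.0), df))


def compare_aicc(fits: dict[str, ModelFit], exclude: tuple[str, ...] = ()
                 ) -> pd.DataFrame:
    """Rank fits by AICc (ascending); co-best = ΔAICc < 2 from the minimum.

    Excluded labels never enter the ranking.  All compared fits must cover
    the same observations.
    """
    rows = []
    kept = {k: v for k, v in fits.items() if k not in exclude}
    if not kept:
        raise ValueError("no fits left to compare after exclusion")
    n_set = {f.n_obs for f in kept.values()}
    if len(n_set) > 1:
        raise ValueError(f"fits cover different numbers of observations: {sorted(n_set)}; "
                         "AICc values are not comparable")
    for label, f in kept.items():
        rows.append({"model": label, "aicc": aicc(f), "llf_ml": f.llf_ml, "k": f.k_params})
    tab = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    tab["co_best"] = tab["delta_aicc"] < 2.0
    return tab


def tukey_pairwise(estimates: dict[str, float], ses: dict[str, float],
                   cov: pd.DataFrame | None = None,
                   method: str = "tukey") -> pd.DataFrame:
    """All pairwise contrasts with studentized-range (Tukey) adjustment.

    Operates on a family of group estimates (e.g. per-group simple slopes)
    with their standard errors and optional joint covariance; p-values use
    the studentized-range distribution with large-sample df, or Bonferroni
    with ``method='bonferroni'``.
    """
    labels = list(estimates)
    k = len(labels)
    rows = []
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            var = ses[a] ** 2 + ses[b] ** 2
            if cov is not None:
                var -= 2 * float(cov.loc[a, b])
            se = math.sqrt(max(var, 0.0))
            diff = estimates[a] - estimates[b]
            if se == 0:
                p = float("nan")
            elif method == "tukey":
                # studentized-range statistic q = |diff| * sqrt(2) / se
                q = abs(diff) * math.sqrt(2.0) / se
                p = float(stats.studentized_range.sf(q, k, 1e6))
            else:
                p = min(1.0, n_pairs * 2 * stats.norm.sf(abs(diff) / se))
            rows.append({"pair": f"{a} - {b}", "estimate": diff, "se": se, "p_adj": p})
    return pd.DataFrame(rows)
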