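"""Orchestration of the trajectory analyses.

Given biomarker chronicity tables (from the SILA stage), positivity calls,
covariates and cognitive scores, this module runs:

* trajectory characterization of WMH on the age scale versus the
  chronicity scale (cubic polynomials with status interactions, pruned);
* the four-time-operationalization model battery for a biomarker outcome
  (age, own-marker chronicity, years since baseline with baseline age, and
  other-marker chronicity), with sequential pruning, AICc ranking that
  excludes the own-chronicity model, joint interaction tests, and
  per-stratum subset sensitivity slopes on a fixed chronicity grid;
* cognitive-trajectory models across the four A/V groups with covariates,
  Tukey-adjusted pairwise slope contrasts, simple slopes at ages 60/70/80,
  and a continuous-chronicity sensitivity model compared by AICc and
  likelihood-ratio tests;
* a two-cohort replication comparison with per-term concordance flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chronicity import lmm
from chronicity.lmm import ModelFit, ModelSpec, Term

__all__ = [
    "SENSITIVITY_GRID",
    "AnalysisBundle",
    "BatteryResult",
    "assign_av_groups",
    "standardize_tests",
    "compose_cognitive_score",
    "build_composites",
    "prepare_battery_data",
    "battery_specs",
    "run_aim1",
    "run_time_battery",
    "run_subset_sensitivity",
    "run_aim3",
    "run_replication",
]

#: chronicity grid (years from threshold) for subset-sensitivity slopes
SENSITIVITY_GRID = (-10.0, -5.0, 0.0, 5.0, 10.0)

#: contributing raw tests per cognitive composite
COMPOSITE_TESTS = {
    "PACC3": ("pacc3_mem", "pacc3_exec", "pacc3_speed"),
    "EF": ("ef",),
    "immediate_memory": ("imm_mem",),
    "delayed_memory": ("del_mem",),
}

GROUP_LEVELS = ("A-V-", "A-V+", "A+V-", "A+V+")


@dataclass
class AnalysisBundle:
    """Everything one cohort's analyses need, in long format.

    ``wmh`` / ``pib`` are per-scan tables carrying at least ``subject,
    age_at_scan, value, time_from_threshold, onset_age``; calls are
    ``subject -> 'positive'|'negative'`` maps; cognition and covariates are
    the generator's (or the study's) tables.
    """

    wmh: pd.DataFrame
    pib: pd.DataFrame
    v_calls: dict[str, str]
    a_calls: dict[str, str]
    covariates: pd.DataFrame | None = None
    cognition: pd.DataFrame | None = None


def assign_av_groups(v_calls: dict[str, str], a_calls: dict[str, str]
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Cross-classify subjects into A-V-, A-V+, A+V-, A+V+ by last-scan status.

    Subjects missing either call are excluded and returned in the log list.
    """
    rows, excluded = [], []
    for sid in sorted(set(v_calls) | set(a_calls)):
        if sid not in v_calls or sid not in a_calls:
            excluded.append(sid)
            continue
        a = "+" if a_calls[sid] == "positive" else "-"
        v = "+" if v_calls[sid] == "positive" else "-"
        rows.append({"subject": sid, "group": f"A{a}V{v}"})
    return pd.DataFrame(rows, columns=["subject", "group"]), excluded


def standardize_tests(cognition: pd.DataFrame, test_cols: tuple[str, ...]
                      ) -> tuple[pd.DataFrame, dict]:
    """Internally standardize raw test scores against the baseline visit.

    The reference mean/SD per test come from each subject's first visit
    (practice_count == 0); they are returned so future data can be scored
    against the same reference.
    """
    base = cognition[cognition["practice_count"] == 0]
    ref = {c: (float(base[c].mean()), float(base[c].std(ddof=1))) for c in test_cols}
    z = cognition.copy()
    for c in test_cols:
        mu, sd = ref[c]
        if sd <= 0:
            raise ValueError(f"test {c} has zero baseline variance")
        z[c] = (cognition[c] - mu) / sd
    return z, ref


def compose_cognitive_score(test_z_scores) -> float:
    """Composite z-score: unweighted mean of the available standardized tests."""
    arr = np.asarray(test_z_scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no contributing test available for this visit")
    return float(arr.mean())


def build_composites(cognition: pd.DataFrame,
                     composites: dict[str, tuple[str, ...]] = COMPOSITE_TESTS
                     ) -> tuple[pd.DataFrame, dict]:
    """Long table of composite z-scores per visit, with the standardization
    reference used."""
    all_tests = tuple(sorted({t for tests in composites.values() for t in tests}))
    z, ref = standardize_tests(cognition, all_tests)
    rows = []
    for _, r in z.iterrows():
        for comp, tests in composites.items():
            vals = [r[t] for t in tests if t in r and np.isfinite(r[t])]
            if not vals:
                continue
            rows.append({"subject": r["subject"], "age_at_visit": r["age_at_visit"],
                         "practice_count": r["practice_count"], "composite": comp,
                         "z": float(np.mean(vals))})
    return pd.DataFrame(rows), ref


# ---------------------------------------------------------------------------
# Aim 1: age scale versus chronicity scale for the WMH trajectory


def run_aim1(wmh_chron: pd.DataFrame, v_calls: dict[str, str],
             log_outcome: bool = True, alpha: float = 0.05) -> dict:
    """Characterize WMH trajectories on the age versus chronicity time scales.

    Fits cubic-polynomial mixed models (pruned from cubic down) with
    V-status interactions on both scales, log-transformed outcome, and
    returns coefficient and simple-slope tables (ages 60 and 75; chronicity
    -20, i.e. below the modelled range, and -5).
    """
    data = wmh_chron.copy()
    data["v_pos"] = data["subject"].map(lambda s: 1.0 if v_calls.get(s) == "positive" else 0.0)
    data["y"] = np.log(data["value"]) if log_outcome else data["value"]
    data["age_c"] = data["age_at_scan"] - 60.0
    data["v_chron"] = data["time_from_threshold"]

    out = {}
    for scale, tcol in (("age", "age_c"), ("chronicity", "v_chron")):
        terms = lmm.polynomial_terms(3, status="v_pos")
        spec = ModelSpec(outcome="y", time=tcol, terms=tuple(terms),
                         protected=frozenset({"Intercept", "v_pos", "time"}),
                         label=f"wmh~{scale}")
        fit, log = lmm.prune_model(spec, data, alpha=alpha)
        at = [0.0, 15.0] if scale == "age" else [-20.0, -5.0]
        slopes = lmm.simple_slopes(fit, at, [{"v_pos": 0.0}, {"v_pos": 1.0}])
        inter_terms = [t.name for t in spec.terms if "v_pos" in t.factors and t.time_power > 0
                       if t.name in fit.params.index]
        joint = lmm.joint_wald_test(fit, inter_terms) if inter_terms else (np.nan, 0, np.nan)
        out[scale] = {"fit": fit, "pruning_log": log,
                      "coefficients": fit.coefficient_table(),
                      "slopes": _slope_table(slopes, offset=60.0 if scale == "age" else 0.0),
                      "interaction_wald": {"stat": joint[0], "df": joint[1], "p": joint[2]}}
    return out


def _slope_table(slopes, offset: float = 0.0) -> pd.DataFrame:
    return pd.DataFrame([{
        "at": s.at_time + offset,
        **dict(s.setting),
        "slope": s.estimate, "se": s.se, "ci_low": s.ci_low, "ci_high": s.ci_high, "p": s.p,
    } for s in slopes])


# ---------------------------------------------------------------------------
# Aim 2: four time operationalizations


def prepare_battery_data(bundle: AnalysisBundle, outcome: str) -> pd.DataFrame:
    """Per-scan modelling table for the battery.

    For the ``wmh`` outcome the grouping status is amyloid positivity and
    the cross-marker chronicity is A chronicity at the WMH scan ages (and
    symmetrically for ``pib``).  Cross-marker chronicity at an arbitrary age
    is age minus that marker's estimated onset age.  The WMH outcome is
    log-transformed; ages are centred at 60 and baseline age at its sample
    mean.
    """
    if outcome not in ("wmh", "pib"):
        raise ValueError("outcome must be 'wmh' or 'pib'")
    own = bundle.wmh if outcome == "wmh" else bundle.pib
    other = bundle.pib if outcome == "wmh" else bundle.wmh
    status_calls = bundle.a_calls if outcome == "wmh" else bundle.v_calls

    data = own.copy()
    data["y"] = np.log(data["value"]) if outcome == "wmh" else data["value"]
    data["own_chron"] = data["time_from_threshold"]
    other_onset = other.groupby("subject")["onset_age"].first()
    data["cross_chron"] = data["age_at_scan"] - data["subject"].map(other_onset)
    data["status"] = data["subject"].map(
        lambda s: 1.0 if status_calls.get(s) == "positive" else 0.0)
    data["age_c"] = data["age_at_scan"] - 60.0
    first_age = data.groupby("subject")["age_at_scan"].transform("min")
    data["time_since_baseline"] = data["age_at_scan"] - first_age
    baseline_age = data.groupby("subject")["age_at_scan"].min()
    data["baseline_age"] = data["subject"].map(baseline_age)
    data["baseline_age_c"] = data["baseline_age"] - baseline_age.mean()
    data = data.dropna(subset=["cross_chron"])
    return data


def battery_specs() -> dict[str, ModelSpec]:
    """The four full time-operationalization specifications.

    Model 1: outcome ~ time(age) * status (quadratic);
    Model 2: outcome ~ baseline age + own-chronicity * status (quadratic);
    Model 3: outcome ~ status * baseline age * time since baseline (three-way);
    Model 4: outcome ~ baseline age + cross-chronicity * status (quadratic).
    Status main effect, linear time, intercept and baseline-age covariates
    are protected from pruning.
    """
    protect = frozenset({"Intercept", "status", "time", "baseline_age_c"})
    q = lambda: lmm.polynomial_terms(2, status="status")
    specs = {
        "model1": ModelSpec("y", "age_c", tuple(q()), protect, label="model1_age"),
        "model2": ModelSpec("y", "own_chron",
                            tuple(q() + [Term(0, ("baseline_age_c",))]),
                            protect, label="model2_own_chronicity"),
        "model3": ModelSpec("y", "time_since_baseline", tuple([
            Term(0), Term(0, ("status",)), Term(0, ("baseline_age_c",)),
            Term(0, ("status", "baseline_age_c")),
            Term(1), Term(1, ("status",)), Term(1, ("baseline_age_c",)),
            Term(1, ("status", "baseline_age_c")),
        ]), protect, label="model3_time_since_baseline"),
        "model4": ModelSpec("y", "cross_chron",
                            tuple(q() + [Term(0, ("baseline_age_c",))]),
                            protect, label="model4_cross_chronicity"),
    }
    return specs


@dataclass
class BatteryResult:
    outcome: str
    fits: dict[str, ModelFit]
    full_fits: dict[str, ModelFit]
    pruning_logs: dict[str, list]
    aicc_table: pd.DataFrame                 # excludes model2 by construction
    interaction_tests: pd.DataFrame          # joint Wald of status x time block (full models)
    slope_tables: dict[str, pd.DataFrame]
    subset_sensitivity: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_time_battery(bundle: AnalysisBundle, outcome: str, alpha: float = 0.05,
                     with_subset_sensitivity: bool = True) -> BatteryResult:
    """Run the four-time-operationalization battery for one outcome.

    Each full model is fitted and sequentially pruned; the AICc ranking
    covers Models 1, 3 and 4 only (the own-chronicity Model 2 fits well by
    construction of the time alignment, so it is excluded from the
    comparison and examined instead through per-stratum subset sensitivity
    on the fixed chronicity grid).  Interaction tests are joint Wald tests
    of the status-by-time block in each full model.
    """
    data = prepare_battery_data(bundle, outcome)
    specs = battery_specs()
    fits, full_fits, logs, slope_tables, inter_rows = {}, {}, {}, {}, []

    for label, spec in specs.items():
        full = lmm.fit_lmm(spec, data)
        fit, plog = lmm.prune_model(spec, data, alpha=alpha)
        full_fits[label], fits[label], logs[label] = full, fit, plog
        block = [t.name for t in spec.terms if "status" in t.factors and t.time_power > 0]
        stat, df, p = lmm.joint_wald_test(full, block, robust=True)
        inter_rows.append({"model": label, "wald_stat": stat, "df": df, "p": p})

        if label == "model3":
            bsd = float(data.groupby("subject")["baseline_age_c"].first().std(ddof=1))
            bmean = float(data.groupby("subject")["baseline_age_c"].first().mean())
            settings = [{"status": s, "baseline_age_c": b}
                        for s in (0.0, 1.0) for b in (bmean - bsd, bmean, bmean + bsd)]
            slopes = lmm.simple_slopes(fit, [0.0, 5.0, 10.0], settings)
        else:
            at = {"model1": [0.0, 10.0, 15.0],      # ages 60, 70, 75
                  "model2": list(SENSITIVITY_GRID),
                  "model4": list(SENSITIVITY_GRID)}[label]
            slopes = lmm.simple_slopes(fit, at, [{"status": 0.0}, {"status": 1.0}])
        slope_tables[label] = _slope_table(slopes, offset=60.0 if label == "model1" else 0.0)

    subset = run_subset_sensitivity(data, alpha=alpha) if with_subset_sensitivity else pd.DataFrame()
    return BatteryResult(
        outcome=outcome, fits=fits, full_fits=full_fits, pruning_logs=logs,
        aicc_table=lmm.compare_aicc(fits, exclude=("model2",)),
        interaction_tests=pd.DataFrame(inter_rows),
        slope_tables=slope_tables,
        subset_sensitivity=subset,
    )


def run_subset_sensitivity(data: pd.DataFrame, time_col: str = "own_chron",
                           status_col: str = "status", alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Own-chronicity slopes fitted separately within each status stratum.

    Quadratic-chronicity mixed models are fitted in the status-positive and
    status-negative subsamples; simple slopes with 95% CIs are evaluated at
    chronicities {-10, -5, 0, 5, 10} and per-grid-point CI overlap between
    the strata is flagged.
    """
    rows = []
    for status_val, lab in ((0.0, "negative"), (1.0, "positive")):
        sub = data[data[status_col] == status_val]
        if sub["subject"].nunique() == 0:
            raise ValueError(f"status stratum '{lab}' is empty")
        if sub["subject"].nunique() < 10:
            import warnings
            warnings.warn(f"status stratum '{lab}' has <10 subjects; slopes will be unstable")
        spec = ModelSpec("y", time_col, tuple(lmm.polynomial_terms(2)),
                         protected=frozenset({"Intercept", "time"}),
                         label=f"subset_{lab}")
        fit = lmm.fit_lmm(spec, sub)
        for s in lmm.simple_slopes(fit, list(SENSITIVITY_GRID), [{}]):
            rows.append({"stratum": lab, "chronicity": s.at_time, "slope": s.estimate,
                         "se": s.se, "ci_low": s.ci_low, "ci_high": s.ci_high})
    tab = pd.DataFrame(rows)
    wide = tab.pivot(index="chronicity", columns="stratum",
                     values=["ci_low", "ci_high"])
    overlap = ~((wide[("ci_low", "positive")] > wide[("ci_high", "negative")])
                | (wide[("ci_low", "negative")] > wide[("ci_high", "positive")]))
    tab["ci_overlap"] = tab["chronicity"].map(overlap)
    return tab


# ---------------------------------------------------------------------------
# Aim 3: cognitive trajectories by A/V group, with chronicity sensitivity


def _cognition_model_data(composite_scores: pd.DataFrame, composite: str,
                          groups: pd.DataFrame, covariates: pd.DataFrame,
                          chronicities: pd.DataFrame | None) -> pd.DataFrame:
    d = composite_scores[composite_scores["composite"] == composite].copy()
    d = d.merge(groups, on="subject").merge(covariates, on="subject")
    d["age_c"] = d["age_at_visit"] - 60.0
    d["z_out"] = d["z"]
    d["reading_z"] = (d["reading"] - d["reading"].mean()) / d["reading"].std(ddof=1)
    d["sex"] = d["sex"].astype(float)
    for lev in GROUP_LEVELS[1:]:
        d[f"g_{lev}"] = (d["group"] == lev).astype(float)
    if chronicities is not None:
        d = d.merge(chronicities, on="subject", how="left")
    return d


def run_aim3(composite_scores: pd.DataFrame, groups: pd.DataFrame,
             covariates: pd.DataFrame, chronicities: pd.DataFrame | None = None,
             composites: tuple[str, ...] = ("PACC3", "EF", "immediate_memory", "delayed_memory"),
             alpha: float = 0.05) -> dict:
    """Cognitive trajectories across A/V groups with covariates.

    Per composite: a mixed model of the composite on age (centred at 60,
    quadratic candidate) interacting with group, adjusted for sex, reading
    score and practice exposures, pruned; Tukey-adjusted pairwise group
    slope contrasts where group-by-age interactions survive; simple slopes
    at ages 60/70/80 per group.  When per-subject last-visit chronicities
    are supplied, a continuous-chronicity sensitivity model (age x A
    chronicity x V chronicity) replaces the group interactions and the two
    are compared by AICc; both are LRT-tested against the shared base model
    (age + covariates only).  Predicted trajectories are evaluated at the
    four (+-10, +-10) chronicity pairs.
    """
    covs = ("sex", "reading_z", "practice_count")
    gcols = tuple(f"g_{lev}" for lev in GROUP_LEVELS[1:])
    results = {}
    for comp in composites:
        d = _cognition_model_data(composite_scores, comp, groups, covariates, chronicities)
        terms = [Term(0)]
        terms += [Term(0, (g,)) for g in gcols]
        terms += [Term(1)] + [Term(1, (g,)) for g in gcols]
        terms += [Term(2)] + [Term(2, (g,)) for g in gcols]
        terms += [Term(0, (c,)) for c in covs]
        protected = frozenset({"Intercept", "time"} | set(gcols)
                              | {Term(0, (c,)).name for c in covs})
        spec = ModelSpec("z_out", "age_c", tuple(terms), protected, label=f"{comp}_groups")
        fit, plog = lmm.prune_model(spec, d, alpha=alpha)

        settings = [{g: 0.0 for g in gcols}]
        for g in gcols:
            s = {h: 0.0 for h in gcols}
            s[g] = 1.0
            settings.append(s)
        slope_rows = []
        for lev, setting in zip(GROUP_LEVELS, settings):
            for s in lmm.simple_slopes(fit, [0.0, 10.0, 20.0], [setting]):
                slope_rows.append({"composite": comp, "group": lev, "age": s.at_time + 60.0,
                                   "slope": s.estimate, "se": s.se,
                                   "ci_low": s.ci_low, "ci_high": s.ci_high, "p": s.p})
        slopes = pd.DataFrame(slope_rows)

        inter_present = [t.name for t in fit.spec.terms
                         if t.time_power > 0 and any(g in t.factors for g in gcols)]
        tukey = {}
        if inter_present:
            for t_age, age in ((0.0, 60), (10.0, 70), (20.0, 80)):
                est, ses = {}, {}
                for lev, setting in zip(GROUP_LEVELS, settings):
                    s = lmm.simple_slopes(fit, [t_age], [setting])[0]
                    est[lev], ses[lev] = s.estimate, s.se
                tukey[age] = lmm.tukey_pairwise(est, ses)

        entry = {"fit": fit, "pruning_log": plog, "coefficients": fit.coefficient_table(),
                 "slopes": slopes, "tukey": tukey}

        if chronicities is not None:
            entry["sensitivity"] = _aim3_sensitivity(d, covs, fit, alpha)
        results[comp] = entry
    return results


def _aim3_sensitivity(d: pd.DataFrame, covs, primary_fit: ModelFit, alpha: float) -> dict:
    ch = ("a_chron_last", "v_chron_last")
    terms = [Term(0), Term(1)]
    terms += [Term(0, (c,)) for c in ch]
    terms += [Term(1, (c,)) for c in ch]
    terms += [Term(0, ch), Term(1, ch)]
    terms += [Term(0, (c,)) for c in covs]
    protected = frozenset({"Intercept", "time"} | {Term(0, (c,)).name for c in ch}
                          | {Term(0, (c,)).name for c in covs})
    spec = ModelSpec("z_out", "age_c", tuple(terms), protected, label="chronicity_sensitivity")
    dd = d.dropna(subset=list(ch))
    fit, plog = lmm.prune_model(spec, dd, alpha=alpha)

    base_spec = ModelSpec("z_out", "age_c",
                          tuple([Term(0), Term(1)] + [Term(0, (c,)) for c in covs]),
                          frozenset({"Intercept", "time"}), label="base")
    base = lmm.fit_lmm(base_spec, dd)
    full_for_lrt = lmm.fit_lmm(spec, dd)
    lrt_sens = lmm.likelihood_ratio_test(base, full_for_lrt)

    comparable = primary_fit.n_obs == fit.n_obs
    aicc_tab = (lmm.compare_aicc({"groups": primary_fit, "chronicity": fit})
                if comparable else pd.DataFrame())

    three_way = Term(1, ch).name
    pred = []
    if three_way in fit.params.index:
        for a in (-10.0, 10.0):
            for v in (-10.0, 10.0):
                setting = {"a_chron_last": a, "v_chron_last": v,
                           **{c: 0.0 for c in covs}}
                ages = np.arange(0.0, 26.0, 5.0)
                for t, zhat in zip(ages, fit.predict_mean(ages, setting)):
                    pred.append({"a_chron": a, "v_chron": v, "age": t + 60.0, "z_hat": zhat})
    return {"fit": fit, "pruning_log": plog,
            "lrt_vs_base": {"stat": lrt_sens[0], "df": lrt_sens[1], "p": lrt_sens[2]},
            "aicc_vs_primary": aicc_tab,
            "predicted_grid": pd.DataFrame(pred)}


# ---------------------------------------------------------------------------
# Aim 4: replication across two cohorts


def run_replication(bundle_a: AnalysisBundle, bundle_b: AnalysisBundle,
                    outcome: str = "wmh", alpha: float = 0.05) -> dict:
    """Run the time battery identically on two cohorts and compare.

    Emits matched coefficient and simple-slope tables and a per-term
    concordance flag: concordant = same sign and overlapping 95% CIs.
    """
    res = {}
    for name, bundle in (("cohort_a", bundle_a), ("cohort_b", bundle_b)):
        res[name] = run_time_battery(bundle, outcome, alpha=alpha,
                                     with_subset_sensitivity=False)
    rows = []
    for label in res["cohort_a"].fits:
        ta = res["cohort_a"].fits[label].coefficient_table().set_index("term")
        tb = res["cohort_b"].fits[label].coefficient_table().set_index("term")
        for term in ta.index.intersection(tb.index):
            a, b = ta.loc[term], tb.loc[term]
            same_sign = np.sign(a["estimate"]) == np.sign(b["estimate"])
            overlap = not (a["ci_low"] > b["ci_high"] or b["ci_low"] > a["ci_high"])
            rows.append({"model": label, "term": term,
                         "est_a": a["estimate"], "est_b": b["estimate"],
                         "same_sign": bool(same_sign), "ci_overlap": bool(overlap),
                         "concordant": bool(same_sign and overlap)})
    return {"results": res, "concordance": pd.DataFrame(rows)}
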