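"""Shared fixtures: seeded cohorts, SILA outputs and a fitted model battery.

Session-scoped because cohort generation and mixed-model fitting dominate
suite runtime; every fixture is a pure function of a hard-coded seed.
"""

import pytest

from chronicity import pipeline
from chronicity.calibration import positivity_calls
from chronicity.cohort import CohortConfig, generate_cohort
from chronicity.sila import fit_sila

WMH_THRESHOLD = 2.06
DVR_THRESHOLD = 1.19


@pytest.fixture(scope="session")
def default_cohort():
    """Default-size cohort (240 subjects, seed 1) with ground truth."""
    cfg = CohortConfig(seed=1)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def sila_default(default_cohort):
    """SILA curves and chronicity tables for the default cohort.

    The WMH curve is trained on the log scale (accumulation is exponential
    in raw mL); PiB stays on the raw DVR scale.
    """
    _, (visits, _, _, _) = default_cohort
    wmh = visits[visits["modality"] == "wmh"]
    pib = visits[visits["modality"] == "pib"]
    curve_w, chron_w = fit_sila(wmh, threshold=WMH_THRESHOLD, log_scale=True)
    curve_p, chron_p = fit_sila(pib, threshold=DVR_THRESHOLD)
    return {"curve_w": curve_w, "chron_w": chron_w,
            "curve_p": curve_p, "chron_p": chron_p}


@pytest.fixture(scope="session")
def analysis_cohort():
    """Smaller cohort (100 subjects, seed 3) for the model-battery fixtures."""
    cfg = CohortConfig(n_subjects=100, seed=3)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def analysis_bundle(analysis_cohort):
    _, (visits, covariates, cognition, _) = analysis_cohort
    wmh = visits[visits["modality"] == "wmh"]
    pib = visits[visits["modality"] == "pib"]
    _, chron_w = fit_sila(wmh, threshold=WMH_THRESHOLD, log_scale=True)
    _, chron_p = fit_sila(pib, threshold=DVR_THRESHOLD)
    return pipeline.AnalysisBundle(
        wmh=chron_w, pib=chron_p,
        v_calls=positivity_calls(chron_w, WMH_THRESHOLD),
        a_calls=positivity_calls(chron_p, DVR_THRESHOLD),
        covariates=covariates, cognition=cognition,
    )


@pytest.fixture(scope="session")
def battery_result(analysis_bundle):
    return pipeline.run_time_battery(analysis_bundle, "wmh")
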