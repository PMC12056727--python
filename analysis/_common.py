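"""Shared setup for the numbered analysis drivers.

Every driver rebuilds its inputs deterministically from the study seed, so
the scripts can run independently and in any order; results land under
``results/`` next to this directory's parent.
"""

from pathlib import Path

from chronicity import pipeline
from chronicity.calibration import DVR_THRESHOLD, WMH_THRESHOLD, positivity_calls
from chronicity.cohort import CohortConfig, generate_cohort
from chronicity.sila import fit_sila

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"

#: study seed for the primary synthetic cohort
SEED = 1
#: seed for the replication cohort (aim 4)
REPLICATION_SEED = 2


def study_config(seed: int = SEED) -> CohortConfig:
    return CohortConfig(seed=seed)


def cohort(seed: int = SEED):
    """(visits, covariates, cognition, truth) for the given seed."""
    return generate_cohort(study_config(seed))


def sila_tables(visits):
    """Curves and chronicity tables for both biomarkers.

    WMH is trained on the log scale (accumulation is exponential in raw
    mL); PiB DVR stays raw.  Thresholds are the published cutoffs.
    """
    wmh = visits[visits["modality"] == "wmh"]
    pib = visits[visits["modality"] == "pib"]
    curve_w, chron_w = fit_sila(wmh, threshold=WMH_THRESHOLD, log_scale=True)
    curve_p, chron_p = fit_sila(pib, threshold=DVR_THRESHOLD)
    return curve_w, chron_w, curve_p, chron_p


def bundle_for(seed: int = SEED) -> pipeline.AnalysisBundle:
    visits, covariates, cognition, _ = cohort(seed)
    _, chron_w, _, chron_p = sila_tables(visits)
    return pipeline.AnalysisBundle(
        wmh=chron_w, pib=chron_p,
        v_calls=positivity_calls(chron_w, WMH_THRESHOLD),
        a_calls=positivity_calls(chron_p, DVR_THRESHOLD),
        covariates=covariates, cognition=cognition,
    )
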