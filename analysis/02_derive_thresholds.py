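"""Derive data-driven positivity thresholds from last-scan values.

Fits the two-component Gaussian mixture to each biomarker's most recent
observations and takes the density intersection as the cutoff — the
convention behind the published 2.06 mL adjusted-WMH and 1.19 DVR values.
Downstream analyses use the published cutoffs; this step reports how close
the data-driven ones land on this cohort.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SEED, cohort

from chronicity.calibration import DVR_THRESHOLD, WMH_THRESHOLD
from chronicity.prep import density_intersection, dvr_to_centiloid, fit_two_component_mixture


def main() -> None:
    visits, _, _, _ = cohort()
    out = RESULTS / "02_thresholds"
    out.mkdir(parents=True, exist_ok=True)

    report = {}
    for modality, published in (("wmh", WMH_THRESHOLD), ("pib", DVR_THRESHOLD)):
        last = (visits[visits["modality"] == modality]
                .sort_values("age_at_scan").groupby("subject").last()["value"])
        mix = fit_two_component_mixture(last)
        thr = density_intersection(mix)
        report[modality] = {
            "threshold": thr, "published": published,
            "weights": mix.weights, "means": mix.means, "sds": mix.sds,
            "equal_variance": mix.equal_variance, "bic": mix.bic,
            "n_iter": mix.n_iter, "converged": mix.converged, "n": int(last.size),
        }
        print(f"{modality}: density-intersection threshold {thr:.3f} "
              f"(published {published}); components "
              f"N({mix.means[0]:.3f}, {mix.sds[0]:.3f}) / N({mix.means[1]:.3f}, {mix.sds[1]:.3f}), "
              f"weights {mix.weights[0]:.2f}/{mix.weights[1]:.2f}")

    print(f"Centiloid at DVR {DVR_THRESHOLD}: {float(dvr_to_centiloid(DVR_THRESHOLD)):.2f}")
    report["centiloid_at_dvr_threshold"] = float(dvr_to_centiloid(DVR_THRESHOLD))
    report["seed"] = SEED
    (out / "thresholds.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {out / 'thresholds.json'}")


if __name__ == "__main__":
    main()
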