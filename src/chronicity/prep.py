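"""Biomarker value preparation and data-driven positivity thresholding.

Deterministic transforms (intracranial-volume adjustment of WMH, the
DVR-to-Centiloid linear map, log transform) plus the two-component Gaussian
mixture used to derive a positivity cutoff at the intersection of the two
component density functions — the convention behind the 2.06 mL adjusted-WMH
and 1.19 DVR cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "CENTILOID_SLOPE",
    "CENTILOID_INTERCEPT",
    "MixtureThreshold",
    "PositivityCall",
    "adjust_for_headsize",
    "dvr_to_centiloid",
    "log_transform",
    "fit_two_component_mixture",
    "density_intersection",
    "classify_positivity",
]

# published linear map from PiB DVR to the Centiloid scale
CENTILOID_SLOPE = 148.33
CENTILOID_INTERCEPT = -154.9621


class DegenerateMixtureError(ValueError):
    """The two-component fit collapsed; use more data or a fixed threshold."""


@dataclass
class MixtureThreshold:
    """Two-component univariate Gaussian mixture and its density-intersection cutoff.

    Components are labelled so ``means[0] < means[1]`` (low = marker-absent,
    high = marker-present).  ``threshold`` is None until set by
    :func:`density_intersection`.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    converged: bool
    n_iter: int
    equal_variance: bool
    bic: float
    threshold: float | None = None
    #: per-iteration log-likelihood trace (EM guarantees non-decreasing)
    llf_trace: tuple[float, ...] = ()


@dataclass(frozen=True)
class PositivityCall:
    subject: str
    biomarker: str          # "V" (WMH) or "A" (PiB)
    status: str             # "positive" | "negative"
    value_at_last: float
    threshold: float


def adjust_for_headsize(raw_wmh: float, ticv: float, reference_ticv: float) -> float:
    """Normalize a WMH volume for head size: ``raw / TICV * mean(TICV)``.

    Expresses lesion volume as a fraction of total intracranial volume,
    rescaled by a reference (sample-mean) TICV so the result stays in mL.
    """
    if not np.all(np.asarray(ticv) > 0):
        raise ValueError("ticv must be positive")
    if not np.all(np.asarray(reference_ticv) > 0):
        raise ValueError("reference_ticv must be positive")
    if np.any(np.asarray(raw_wmh) < 0):
        raise ValueError("raw_wmh must be non-negative")
    return raw_wmh / ticv * reference_ticv


def dvr_to_centiloid(dvr):
    """Linear map from PiB DVR to Centiloids: ``148.33*DVR - 154.9621``."""
    return CENTILOID_SLOPE * np.asarray(dvr, dtype=float) + CENTILOID_INTERCEPT


def log_transform(adjusted_wmh, floor: float = 0.01):
    """Natural log of the adjusted volume, floored to avoid -inf at zero.

    The default floor (0.01 mL) is below segmentation resolution.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return np.log(np.maximum(np.asarray(adjusted_wmh, dtype=float), floor))


def _em_fit(x: np.ndarray, equal_variance: bool, max_iter: int, tol: float):
    """EM for a two-component 1-D Gaussian mixture; deterministic percentile init."""
    n = x.size
    m = np.array([np.percentile(x, 10.0), np.percentile(x, 90.0)])
    pooled = x.std(ddof=1)
    s = np.array([pooled, pooled])
    w = np.array([0.5, 0.5])
    llf_trace = []
    llf_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        log_comp = np.log(w)[:, None] + norm.logpdf(x[None, :], m[:, None], s[:, None])
        log_tot = np.logaddexp(log_comp[0], log_comp[1])
        llf = float(log_tot.sum())
        llf_trace.append(llf)
        resp = np.exp(log_comp - log_tot[None, :])
        # M step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            raise DegenerateMixtureError("a mixture component lost all responsibility; "
                                         "use more data or a fixed threshold")
        w = nk / n
        m = (resp @ x) / nk
        var = (resp * (x[None, :] - m[:, None]) ** 2).sum(axis=1)
        if equal_variance:
            s = np.full(2, math.sqrt(max(var.sum() / n, 0.0)))
        else:
            s = np.sqrt(var / nk)
        data_range = x.max() - x.min()
        if np.any(s < 1e-6 * max(data_range, 1e-300)):
            raise DegenerateMixtureError("a component standard deviation collapsed; "
                                         "use more data or a fixed threshold")
        if llf - llf_prev < tol and it > 1:
            converged = True
            break
        llf_prev = llf
    n_params = 5 if not equal_variance else 4   # weights(1) + means(2) + sds(2 or 1)
    bic = -2.0 * llf_trace[-1] + n_params * math.log(n)
    return w, m, s, llf_trace, converged, it, bic


def fit_two_component_mixture(values, seed: int = 0, max_iter: int = 1000,
                              tol: float = 1e-8) -> MixtureThreshold:
    """Fit a two-class Gaussian mixture to (last-scan) biomarker values.

    Both equal-variance and unequal-variance models are fitted by EM with
    deterministic 10th/90th-percentile initialisation; the winner is chosen
    by BIC.  Components are relabelled so the lower-mean class comes first.
    ``seed`` is accepted for interface stability; the default fit is fully
    deterministic.

    Raises
    ------
    DegenerateMixtureError
        If a component weight collapses below 1% or an SD collapses below
        1e-6 x the data range (e.g. all values identical).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 values to fit a mixture, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x.max() == x.min():
        raise DegenerateMixtureError("all values identical: zero-variance data; "
                                     "use more data or a fixed threshold")

    fits = {}
    errors = {}
    for eq in (True, False):
        try:
            fits[eq] = _em_fit(x, eq, max_iter, tol)
        except DegenerateMixtureError as e:   # one variant may collapse; keep the other
            errors[eq] = e
    if not fits:
        raise next(iter(errors.values()))
    eq = min(fits, key=lambda k: fits[k][-1])
    w, m, s, llf_trace, converged, n_iter, bic = fits[eq]

    if np.any(w < 0.01):
        raise DegenerateMixtureError(f"component weight {w.min():.4f} below 1%; "
                                     "use more data or a fixed threshold")
    order = np.argsort(m)
    return MixtureThreshold(
        weights=(float(w[order[0]]), float(w[order[1]])),
        means=(float(m[order[0]]), float(m[order[1]])),
        sds=(float(s[order[0]]), float(s[order[1]])),
        log_likelihood=float(llf_trace[-1]),
        converged=converged,
        n_iter=n_iter,
        equal_variance=eq,
        bic=float(bic),
        llf_trace=tuple(llf_trace),
    )


def density_intersection(mix: MixtureThreshold) -> float:
    """Cutoff where the two weighted component densities cross, between the means.

    Solves ``w1 phi(x; m1, s1) = w2 phi(x; m2, s2)``.  The log-density
    difference is quadratic in x; the root strictly between the means is the
    classification boundary.  With equal SDs the closed form
    ``(m1+m2)/2 + s^2 ln(w1/w2)/(m2-m1)`` applies.
    """
    (w1, w2), (m1, m2), (s1, s2) = mix.weights, mix.means, mix.sds
    if not m1 < m2:
        raise ValueError("component means must satisfy m1 < m2")
    if s1 == s2:
        root = (m1 + m2) / 2.0 + s1**2 * math.log(w1 / w2) / (m2 - m1)
        if not m1 < root < m2:
            raise ValueError("no density intersection between the component means "
                             "(pathological overlap); consider a manual threshold")
        mix.threshold = float(root)
        return mix.threshold
    # a x^2 + b x + c = 0 from log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - ...
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + math.log(w1 / w2) + math.log(s2 / s1))
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no real density intersection (pathological overlap); "
                         "consider a manual threshold")
    roots = np.array([(-b - math.sqrt(disc)) / (2 * a), (-b + math.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        raise ValueError("no density intersection between the component means "
                         "(pathological overlap); consider a manual threshold")
    mix.threshold = float(inside[0])
    return mix.threshold


def classify_positivity(subject: str, biomarker: str, value_at_last: float,
                        threshold: float) -> PositivityCall:
    """Positivity call at the last scan: positive iff value >= threshold.

    The boundary is inclusive for both markers (adjusted WMH >= 2.06 mL
    means V+, DVR >= 1.19 means A+).
    """
    if not (np.isfinite(value_at_last) and np.isfinite(threshold)):
        raise ValueError("value and threshold must be finite")
    status = "positive" if value_at_last >= threshold else "negative"
    return PositivityCall(subject=subject, biomarker=biomarker, status=status,
                          value_at_last=float(value_at_last), threshold=float(threshold))
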