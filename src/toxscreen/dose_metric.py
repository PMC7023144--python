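"""Dose-metric identification from equi-response doses across a size series.

For a series of particle sizes, the dose of each size producing the same
response (here, a fixed % decrease in viability) is converted to a particle
number concentration N and regressed on the diameter d in log-log space:

    log10(N) = m * log10(d) + q

If the administered amount of a single physical quantity drives the
response, the points fall on a line whose slope identifies that quantity:
m = -2 for surface area (N * d² constant), m = -3 for volume / mass
(N * d³ constant), m = 0 for particle number (N constant).  A slope near
none of these indicates an intermediate metric characterised by the
constant 10^q = N * d^(-m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dosimetry import (
    ParticleSpec,
    mass_dose_for_metric,
    particles_per_ml,
    surface_area_per_ml,
    to_particle_mass,
    volume_per_ml,
)
from .errors import InsufficientDataError, SchemaError

#: canonical log-log slopes for the pure dose metrics
CANONICAL_SLOPES = {"surface": -2.0, "volume": -3.0, "number": 0.0}

DEFAULT_TOLERANCE = 0.75


@dataclass(frozen=True)
class DoseMetricFit:
    """Fitted equi-response line and its dose-metric classification."""

    slope_m: float
    intercept_q: float
    r_squared: float
    n_sizes: int
    classified_metric: str
    intermediate_exponent: float | None = None
    intermediate_constant: float | None = None


class DoseMetricIdentifier(BaseEstimator):
    """Scikit-learn style estimator of the governing dose metric.

    Fits an unweighted OLS line through (log10 d, log10 N) and classifies
    the slope against the canonical values -2 (surface), -3 (volume) and
    0 (particle number).

    Parameters
    ----------
    tolerance : float, default=0.75
        Maximum |slope - canonical| for a canonical call.  The canonical
        slopes are 1 apart at minimum, so tolerances below 0.5 can leave
        gaps; 0.75 accepts moderately off-canonical slopes while rejecting
        slopes equidistant between two canonical values, which classify as
        "intermediate" with the exponent and constant of N * d^(-m).

    Attributes
    ----------
    slope_m_ : float
    intercept_q_ : float
        log10 N at log10 d = 0 (d = 1 in the diameter units used).
    r_squared_ : float
    n_sizes_ : int
    metric_ : str
        One of "surface", "volume", "number", "intermediate".
    """

    def __init__(self, tolerance: float = DEFAULT_TOLERANCE):
        self.tolerance = tolerance

    def fit(self, diameters, numbers):
        """Fit the log-log line from diameters (nm) and particle numbers (/mL)."""
        d = np.asarray(diameters, dtype=float).reshape(-1)
        n = np.asarray(numbers, dtype=float).reshape(-1)
        if d.shape != n.shape:
            raise ValueError("diameters and numbers must have the same length")
        if np.unique(d).size < 3:
            raise InsufficientDataError(
                "dose-metric fit requires at least 3 distinct diameters"
            )
        if np.any(d <= 0) or np.any(n <= 0):
            raise ValueError("diameters and particle numbers must be > 0")
        logn = np.log10(n)
        res = linregress(np.log10(d), logn)
        self.slope_m_ = float(res.slope)
        self.intercept_q_ = float(res.intercept)
        # zero variance in log N (a perfect number-metric series) leaves
        # rvalue undefined although the line fits exactly
        r2 = 1.0 if np.allclose(logn, logn.mean()) else float(res.rvalue**2)
        self.r_squared_ = r2
        self.n_sizes_ = int(np.unique(d).size)
        self.metric_ = classify_slope(self.slope_m_, self.tolerance)
        return self

    def predict(self, diameters):
        """Particle number (/mL) predicted by the fitted line."""
        check_is_fitted(self, "slope_m_")
        logd = np.log10(np.asarray(diameters, dtype=float).reshape(-1))
        return 10.0 ** (self.slope_m_ * logd + self.intercept_q_)

    def result(self) -> DoseMetricFit:
        check_is_fitted(self, "slope_m_")
        intermediate = self.metric_ == "intermediate"
        return DoseMetricFit(
            slope_m=self.slope_m_,
            intercept_q=self.intercept_q_,
            r_squared=self.r_squared_,
            n_sizes=self.n_sizes_,
            classified_metric=self.metric_,
            intermediate_exponent=-self.slope_m_ if intermediate else None,
            intermediate_constant=10.0**self.intercept_q_ if intermediate else None,
        )


def classify_slope(m: float, tolerance: float = DEFAULT_TOLERANCE) -> str:
    """Nearest-canonical classification of a log-log slope.

    Returns the canonical metric strictly nearest to ``m`` when within
    ``tolerance``; ties between two canonical slopes, or no canonical slope
    within tolerance, classify as "intermediate".
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    dists = {name: abs(m - s) for name, s in CANONICAL_SLOPES.items()}
    best = min(dists, key=dists.get)
    best_d = dists[best]
    if best_d > tolerance:
        return "intermediate"
    # equidistance between two canonical slopes (to numerical precision)
    # is ambiguous and classifies as intermediate
    if sum(1 for v in dists.values() if abs(v - best_d) < 1e-9) > 1:
        return "intermediate"
    return best


def fit_loglog(series, tolerance: float = DEFAULT_TOLERANCE) -> DoseMetricFit:
    """Fit the equi-response line from (diameter nm, particles/mL) pairs.

    ``series`` is any iterable of (d, N) pairs or a 2-column array/DataFrame.
    """
    arr = np.asarray(list(series) if not isinstance(series, np.ndarray) else series,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be pairs of (diameter, particle number)")
    ident = DoseMetricIdentifier(tolerance=tolerance).fit(arr[:, 0], arr[:, 1])
    return ident.result()


def classify_metric(fit: DoseMetricFit, tolerance: float = DEFAULT_TOLERANCE) -> str:
    """Re-classify an existing fit under a (possibly different) tolerance."""
    return classify_slope(fit.slope_m, tolerance)


def metric_overlay_table(
    screen: pd.DataFrame,
    specs: dict[str, ParticleSpec],
    metric: str = "surface",
) -> pd.DataFrame:
    """Re-express each particle's dose column in the chosen metric's units.

    Returns the screen table with an added ``metric_dose`` column (cm²/mL
    for surface, cm³/mL for volume, particles/mL for number, µg/mL
    particle-mass for mass) so per-size viability curves can be overlaid on
    a common axis.
    """
    converters = {
        "surface": surface_area_per_ml,
        "volume": volume_per_ml,
        "number": particles_per_ml,
        "mass": to_particle_mass,
    }
    if metric not in converters:
        raise ValueError(
            f"unknown metric {metric!r}; allowed: {sorted(converters)}"
        )
    convert = converters[metric]
    missing = set(screen["particle"].unique()) - set(specs)
    if missing:
        raise SchemaError(f"no particle spec for: {sorted(missing)}")
    out = screen.copy()
    out["metric_dose"] = [
        convert(row.dose_ug_ml, specs[row.particle])
        for row in screen.itertuples()
    ]
    out["metric"] = metric
    return out


__all__ = [
    "CANONICAL_SLOPES",
    "DEFAULT_TOLERANCE",
    "DoseMetricFit",
    "DoseMetricIdentifier",
    "classify_metric",
    "classify_slope",
    "fit_loglog",
    "mass_dose_for_metric",
    "metric_overlay_table",
]
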