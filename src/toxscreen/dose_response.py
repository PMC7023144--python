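"""Fixed-slope Hill cytotoxicity model: LD50 estimation and equi-response doses.

The viability model is the unit-slope Hill curve

    V(C) = 100 / (1 + C / LD50)

with V the percentage of intact cells relative to vehicle control and C the
administered dose.  The single free parameter LD50 is estimated by ordinary
least squares on viability %, optimised over log(LD50) so the parameter
stays positive and the problem is well conditioned across dose scales.

Because the slope is fixed at 1 the curve inverts in closed form: the dose
producing an x % decrease in viability is

    ED_x = LD50 * x / (100 - x)

so ED50 = LD50 and ED20 = LD50 / 4.  This inversion is how equi-response
doses for the dose-metric analysis are obtained.

When the data do not support a finite LD50 (little cytotoxicity at the top
dose, or the optimum runs far beyond the tested range) the fit is censored
and reported as a bound "LD50 > max tested dose".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import CensoredFitError, DegenerateDataError, InsufficientDataError


@dataclass(frozen=True)
class HillFit:
    """Result of a unit-slope Hill fit of viability against dose."""

    ld50: float | None
    censored: bool
    max_dose_tested: float
    rss: float
    n_points: int

    @property
    def bound(self) -> str | None:
        """Human-readable censoring bound, e.g. ``"LD50 > 100"``."""
        if not self.censored:
            return None
        return f"LD50 > {self.max_dose_tested:g}"


@dataclass(frozen=True)
class EquiResponseDose:
    """Dose producing a fixed percentage decrease in viability."""

    response_level_x: float
    dose: float
    source_fit: HillFit


def hill_viability(dose, ld50):
    """Unit-slope Hill viability curve, in % of control."""
    dose = np.asarray(dose, dtype=float)
    return 100.0 / (1.0 + dose / ld50)


class HillCytotoxicityModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the unit-slope Hill viability curve.

    Parameters
    ----------
    censor_top_viability : float, default=75.0
        If the mean viability at the highest tested dose exceeds this
        percentage the fit is censored (too little cytotoxicity observed).
    censor_ld50_factor : float, default=2.0
        If the least-squares LD50 exceeds this multiple of the highest
        tested dose the fit is censored rather than extrapolated.
    viability_tolerance : float, default=5.0
        Viabilities up to ``100 + viability_tolerance`` % are accepted
        (replicate noise can push control-normalised values above 100).

    Attributes
    ----------
    ld50_ : float or None
        Estimated LD50 in the dose units of the input; None when censored.
    censored_ : bool
        True when no finite LD50 is supported by the data.
    max_dose_tested_ : float
    rss_ : float
        Residual sum of squares of the (uncensored) fit.
    n_points_ : int
    """

    def __init__(
        self,
        censor_top_viability: float = 75.0,
        censor_ld50_factor: float = 2.0,
        viability_tolerance: float = 5.0,
    ):
        self.censor_top_viability = censor_top_viability
        self.censor_ld50_factor = censor_ld50_factor
        self.viability_tolerance = viability_tolerance

    def fit(self, X, y):
        """Fit LD50 from doses ``X`` (µg/mL) and viabilities ``y`` (%).

        Vehicle-control rows (dose 0) are dropped: the model is anchored at
        100 % by construction and controls carry no information about LD50.
        """
        dose = np.asarray(X, dtype=float).reshape(-1)
        viab = np.asarray(y, dtype=float).reshape(-1)
        if dose.shape != viab.shape:
            raise ValueError("X and y must have the same length")
        mask = dose > 0
        dose, viab = dose[mask], viab[mask]
        if np.unique(dose).size < 3:
            raise InsufficientDataError(
                "Hill fit requires at least 3 distinct non-zero doses"
            )
        if np.any(viab < 0) or np.any(viab > 100 + self.viability_tolerance):
            raise ValueError(
                "viability must lie in [0, 100 + tolerance] % of control"
            )
        if np.all(viab == 0):
            raise DegenerateDataError(
                "viability is zero at every dose; reduce the dose range"
            )

        self.max_dose_tested_ = float(dose.max())
        self.n_points_ = int(dose.size)

        def rss_at(log_ld50: float) -> float:
            resid = viab - hill_viability(dose, np.exp(log_ld50))
            return float(resid @ resid)

        # Bracket log(LD50) generously around the tested dose range; the
        # censoring rule handles optima beyond the top dose.
        lo = np.log(dose.min()) - np.log(1e4)
        hi = np.log(self.max_dose_tested_) + np.log(1e4)
        res = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        ld50 = float(np.exp(res.x))
        self.rss_ = float(res.fun)

        top_viab = float(viab[dose == self.max_dose_tested_].mean())
        censored = (
            ld50 > self.censor_ld50_factor * self.max_dose_tested_
            or top_viab > self.censor_top_viability
        )
        self.censored_ = bool(censored)
        self.ld50_ = None if censored else ld50
        return self

    def predict(self, X):
        """Predicted viability (%) at doses ``X``."""
        check_is_fitted(self, "censored_")
        if self.censored_:
            raise CensoredFitError("censored fit has no point estimate of LD50")
        return hill_viability(np.asarray(X, dtype=float).reshape(-1), self.ld50_)

    def equi_response_dose(self, x: float) -> float:
        """Dose giving an ``x`` % decrease in viability (closed form)."""
        check_is_fitted(self, "censored_")
        if self.censored_:
            raise CensoredFitError(
                "equi-response dose undefined beyond the tested range "
                f"({self.result().bound})"
            )
        if not 0 < x < 100:
            raise ValueError("response level x must lie strictly in (0, 100)")
        return float(self.ld50_ * x / (100.0 - x))

    def result(self) -> HillFit:
        """Immutable summary of the fitted model."""
        check_is_fitted(self, "censored_")
        return HillFit(
            ld50=self.ld50_,
            censored=self.censored_,
            max_dose_tested=self.max_dose_tested_,
            rss=self.rss_,
            n_points=self.n_points_,
        )


def fit_hill_ld50(doses, viabilities, **params) -> HillFit:
    """Functional wrapper: fit the unit-slope Hill model and return a HillFit."""
    model = HillCytotoxicityModel(**params).fit(doses, viabilities)
    return model.result()


def equi_response_dose(fit: HillFit, x: float) -> EquiResponseDose:
    """Invert a Hill fit at an ``x`` % viability decrease.

    ED_x = LD50 * x / (100 - x); errors on censored fits.
    """
    if fit.censored:
        raise CensoredFitError(
            f"equi-response dose undefined beyond the tested range ({fit.bound})"
        )
    if not 0 < x < 100:
        raise ValueError("response level x must lie strictly in (0, 100)")
    return EquiResponseDose(
        response_level_x=float(x),
        dose=float(fit.ld50 * x / (100.0 - x)),
        source_fit=fit,
    )
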