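"""Single-agent dose-response fitting: 4PL curves, censored IC20, AUC.

The four-parameter logistic (4PL, Hill) curve

    f(d) = lower + (upper - lower) / (1 + (d / EC50)^hill)

describes relative viability as a function of dose ``d`` (uM), with
``upper`` the response at zero dose (~1 after vehicle normalization),
``lower`` the plateau at saturating dose, and ``hill`` > 0 the steepness
for an inhibitory drug.  From the fitted curve we derive:

* IC20 — the dose producing 20% inhibition (viability 0.8), solved
  analytically from the 4PL inverse and *censored* against the tested dose
  range: below_range / above_range when the crossing lies outside it, and
  not_reached when the curve never attains the target level at all.
* AUC — mean fitted viability over a uniform grid in log10 dose across the
  tested range; 1 = no effect, approaching ``lower`` for a maximally potent
  drug.  Being an average rather than an integral it is unit-free and
  comparable across drugs and dose ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DesignError

__all__ = ["DoseResponseFit", "CensoredIC", "ICStatus", "FourParamLogistic",
           "fit_4pl", "ic_level", "auc", "four_pl"]

DEFAULT_DOSE_RANGE = (0.01, 20.0)  # uM, the screened range

#: Upper bound allowed for asymptotes; supra-vehicle responses occur in
#: imaging readouts, so ``upper`` is free up to this cap.
ASYMPTOTE_CAP = 1.5


def four_pl(d: np.ndarray, lower: float, upper: float,
            log10_ec50: float, hill: float) -> np.ndarray:
    """Evaluate the 4PL curve at doses ``d`` (uM)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        logd = np.log10(np.where(d > 0, d, np.nan))
        resp = lower + (upper - lower) / (1.0 + 10.0 ** (hill * (logd - log10_ec50)))
    return np.where(d > 0, resp, upper)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters for one single-agent curve."""

    lower: float
    upper: float
    log10_ec50: float
    hill: float
    rss: float
    converged: bool

    @property
    def is_flat(self) -> bool:
        return not np.isfinite(self.hill)

    def predict(self, doses) -> np.ndarray:
        if self.is_flat:
            return np.full(np.shape(doses), self.upper, dtype=float)
        return four_pl(np.asarray(doses, dtype=float), self.lower, self.upper,
                       self.log10_ec50, self.hill)


class ICStatus(str, Enum):
    VALUE = "value"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"
    NOT_REACHED = "not_reached"


@dataclass(frozen=True)
class CensoredIC:
    """An inhibitory-concentration estimate, censored to the tested range."""

    status: ICStatus
    dose: float | None
    level: float


class FourParamLogistic:
    """Least-squares 4PL dose-response regressor (scikit-learn style).

    Parameters
    ----------
    ec50_grid_hills : sequence of float
        Hill slopes tried during multi-start initialization.
    max_asymptote : float
        Upper bound on the ``upper`` and ``lower`` asymptotes.

    Attributes (after :meth:`fit`)
    ------------------------------
    lower_, upper_, log10_ec50_, hill_ : float
        Fitted curve parameters.
    rss_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
    """

    def __init__(self, ec50_grid_hills: Sequence[float] = (0.5, 1.0, 2.0),
                 max_asymptote: float = ASYMPTOTE_CAP):
        self.ec50_grid_hills = tuple(ec50_grid_hills)
        self.max_asymptote = max_asymptote

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"ec50_grid_hills": self.ec50_grid_hills,
                "max_asymptote": self.max_asymptote}

    def set_params(self, **params) -> "FourParamLogistic":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def fit(self, doses, responses) -> "FourParamLogistic":
        d = np.asarray(doses, dtype=float).ravel()
        y = np.asarray(responses, dtype=float).ravel()
        if d.shape != y.shape:
            raise DesignError("doses and responses must have equal length")
        keep = np.isfinite(d) & np.isfinite(y) & (d > 0)
        d, y = d[keep], y[keep]
        if len(np.unique(d)) < 4:
            raise DesignError("need at least 4 distinct nonzero doses for a 4PL fit")
        if np.ptp(y) == 0.0:
            # Degenerate: a constant response carries no dose information.
            self.lower_ = self.upper_ = float(y[0])
            self.log10_ec50_ = np.nan
            self.hill_ = np.nan
            self.rss_ = 0.0
            self.converged_ = True
            return self

        logd = np.log10(d)
        cap = self.max_asymptote

        ln10 = np.log(10.0)

        def residuals(theta):
            lower, upper, lec50, hill = theta
            pred = lower + (upper - lower) / (1.0 + 10.0 ** (hill * (logd - lec50)))
            return pred - y

        def jacobian(theta):
            lower, upper, lec50, hill = theta
            t = 10.0 ** (hill * (logd - lec50))
            s = 1.0 / (1.0 + t)
            w = (upper - lower) * t * s * s * ln10
            return np.column_stack([1.0 - s, s, w * hill, -w * (logd - lec50)])

        lo_bounds = [0.0, 0.0, logd.min() - 3.0, 1e-3]
        hi_bounds = [cap, cap, logd.max() + 3.0, 10.0]
        upper0 = min(float(np.max(y)), cap)
        lower0 = max(float(np.min(y)), 0.0)
        best = best_conv = None
        for lec50 in np.unique(logd):
            for hill in self.ec50_grid_hills:
                x0 = [lower0, upper0, float(lec50), hill]
                sol = least_squares(residuals, x0, jac=jacobian,
                                    bounds=(lo_bounds, hi_bounds),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                    max_nfev=400)
                rss = float(np.sum(sol.fun ** 2))
                # ties broken toward the shallowest slope
                if best is None or rss < best[0] - 1e-15 or (
                        abs(rss - best[0]) <= 1e-15 and abs(sol.x[3]) < abs(best[1].x[3])):
                    best = (rss, sol)
                if sol.success and (best_conv is None or rss < best_conv[0] - 1e-15 or (
                        abs(rss - best_conv[0]) <= 1e-15
                        and abs(sol.x[3]) < abs(best_conv[1].x[3]))):
                    best_conv = (rss, sol)
            if best is not None and best[0] < 1e-18 * max(len(y), 1):
                break  # already at an essentially perfect fit
        if not best[1].success:
            # polish the best start with a larger iteration budget
            sol = least_squares(residuals, best[1].x, jac=jacobian,
                                bounds=(lo_bounds, hi_bounds),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=5000)
            rss = float(np.sum(sol.fun ** 2))
            if rss <= best[0]:
                best = (rss, sol)
        # A converged solution with an essentially tied RSS beats a marginally
        # better one that ran out of iterations (degenerate flat-noise data).
        if (best_conv is not None and not best[1].success
                and best_conv[0] <= best[0] * (1.0 + 1e-6) + 1e-12):
            best = best_conv
        rss, sol = best
        lower, upper, lec50, hill = (float(v) for v in sol.x)
        if lower > upper:  # inverted solution: re-express as an inhibition fit
            lower, upper, hill = upper, lower, -hill
        self.lower_, self.upper_ = lower, upper
        self.log10_ec50_, self.hill_ = lec50, hill
        self.rss_ = rss
        self.converged_ = bool(sol.success)
        return self

    def predict(self, doses) -> np.ndarray:
        return self.fit_result_().predict(doses)

    def fit_result_(self) -> DoseResponseFit:
        if not hasattr(self, "converged_"):
            raise DesignError("estimator is not fitted")
        return DoseResponseFit(lower=self.lower_, upper=self.upper_,
                               log10_ec50=self.log10_ec50_, hill=self.hill_,
                               rss=self.rss_, converged=self.converged_)


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Fit a 4PL curve by multi-start least squares; see :class:`FourParamLogistic`."""
    return FourParamLogistic().fit(doses, responses).fit_result_()


def ic_level(fit: DoseResponseFit, level: float = 0.2,
             dose_range: tuple[float, float] = DEFAULT_DOSE_RANGE) -> CensoredIC:
    """Dose at which the fitted curve reaches ``1 - level`` viability, censored.

    ``level`` is the inhibition fraction (0.2 for IC20).  The crossing is
    solved analytically from the 4PL inverse; the status reports whether it
    lies inside, below or above the tested range, or is never reached.
    """
    if not fit.converged:
        raise DesignError("cannot derive IC from a non-converged fit")
    if not 0.0 < level < 1.0:
        raise DesignError("inhibition level must be in (0, 1)")
    target = 1.0 - level
    lo, hi = dose_range
    if lo >= hi or lo <= 0:
        raise DesignError(f"degenerate dose range {dose_range}")
    if fit.is_flat or fit.upper == fit.lower:
        return CensoredIC(status=ICStatus.NOT_REACHED, dose=None, level=level)
    lower, upper = fit.lower, fit.upper
    # target must be strictly between the asymptotes to have a solution
    if not (min(lower, upper) < target < max(lower, upper)):
        return CensoredIC(status=ICStatus.NOT_REACHED, dose=None, level=level)
    ratio = (upper - lower) / (target - lower) - 1.0
    if ratio <= 0:
        return CensoredIC(status=ICStatus.NOT_REACHED, dose=None, level=level)
    log10_d = fit.log10_ec50 + np.log10(ratio) / fit.hill
    dose = float(10.0 ** log10_d)
    if dose < lo:
        return CensoredIC(status=ICStatus.BELOW_RANGE, dose=None, level=level)
    if dose > hi:
        return CensoredIC(status=ICStatus.ABOVE_RANGE, dose=None, level=level)
    return CensoredIC(status=ICStatus.VALUE, dose=dose, level=level)


def auc(fit: DoseResponseFit, dose_range: tuple[float, float] = DEFAULT_DOSE_RANGE,
        n_grid: int = 201) -> float:
    """Normalized mean fitted viability over log10 dose across ``dose_range``."""
    if not fit.converged:
        raise DesignError("cannot compute AUC from a non-converged fit")
    lo, hi = dose_range
    if lo >= hi or lo <= 0:
        raise DesignError(f"degenerate dose range {dose_range}")
    x = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    y = fit.predict(10.0 ** x)
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))
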