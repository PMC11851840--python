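"""Per-animal growth modelling.

Two layers: (i) a per-animal robust (Huber) linear regression of body weight
on day — its slope is the animal's average daily gain and its pseudo-R²
gates animals with unreliable weight tracks; (ii) a population
three-parameter logistic growth model fitted to the pooled daily weights,
``BW(day) = bw_max / (1 + exp((xmid - day) / scal))``, where ``bw_max`` is
the asymptotic weight, ``xmid`` the day at half that weight and ``scal``
the curve steepness in days.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import OptimizeWarning, curve_fit

logger = logging.getLogger(__name__)

#: animals with a pseudo-R² below this are excluded from the analysis
DEFAULT_R2_THRESHOLD = 0.8


@dataclass
class RobustGrowthFit:
    pig_id: int
    slope: float  # kg/day, the animal's average daily gain
    intercept: float  # kg
    pseudo_r2: float
    n_days: int
    retained: bool

    def predict(self, day):
        return self.intercept + self.slope * np.asarray(day, dtype=float)


@dataclass
class LogisticFit:
    bw_max: float
    xmid: float
    scal: float
    rss: float
    converged: bool


class WeightOutOfRangeError(ValueError):
    """A target weight lies outside an animal's fitted trajectory."""


def _pseudo_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Squared Pearson correlation between fitted and observed weights;
    degenerate (zero-variance) cases score 1 for a perfect fit, else 0."""
    if np.std(observed) == 0.0 or np.std(fitted) == 0.0:
        return 1.0 if np.allclose(observed, fitted) else 0.0
    r = np.corrcoef(observed, fitted)[0, 1]
    return float(r * r)


def fit_robust_growth(daily: pd.DataFrame, pig_id: int | None = None,
                      r2_threshold: float = DEFAULT_R2_THRESHOLD
                      ) -> RobustGrowthFit:
    """Huber M-estimate of BW ~ day for one animal.

    ``daily`` needs columns ``day`` and ``bw_kg``.  Fewer than 3 distinct
    days yields an invalid (non-retained, NaN-slope) fit.
    """
    if pig_id is None:
        pig_id = int(daily["pig_id"].iloc[0]) if "pig_id" in daily else -1
    day = daily["day"].to_numpy(dtype=float)
    bw = daily["bw_kg"].to_numpy(dtype=float)
    n_days = int(pd.unique(daily["day"]).size)
    if n_days < 3:
        return RobustGrowthFit(pig_id, np.nan, np.nan, np.nan, n_days, False)

    if np.ptp(bw) == 0.0:  # constant weight: slope 0 without iterating
        return RobustGrowthFit(pig_id, 0.0, float(bw[0]), 1.0, n_days, True)

    exog = sm.add_constant(day)
    model = sm.RLM(bw, exog, M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit(scale_est="mad", conv="coefs", tol=1e-8, maxiter=100)
    intercept, slope = res.params
    r2 = _pseudo_r2(bw, res.fittedvalues)
    return RobustGrowthFit(pig_id, float(slope), float(intercept), r2,
                           n_days, bool(r2 >= r2_threshold))


def fit_all_growth(daily: pd.DataFrame,
                   r2_threshold: float = DEFAULT_R2_THRESHOLD
                   ) -> dict[int, RobustGrowthFit]:
    """Robust growth fit per animal from a pooled daily table."""
    return {
        int(pid): fit_robust_growth(group, int(pid), r2_threshold)
        for pid, group in daily.groupby("pig_id", sort=True)
    }


def gate_animals(fits, threshold: float = DEFAULT_R2_THRESHOLD) -> list[int]:
    """Ids whose pseudo-R² >= threshold (boundary inclusive), input order."""
    if isinstance(fits, dict):
        fits = fits.values()
    fits = list(fits)
    kept = [f.pig_id for f in fits
            if np.isfinite(f.pseudo_r2) and f.pseudo_r2 >= threshold]
    if fits and not kept:
        logger.warning("gate_animals: no animal reached pseudo-R2 >= %.3g",
                       threshold)
    return kept


def logistic_bw(bw_max: float, xmid: float, scal: float, day):
    """Three-parameter logistic curve; rejects scal = 0."""
    if scal == 0:
        raise ValueError("scal must be nonzero")
    day = np.asarray(day, dtype=float)
    out = bw_max / (1.0 + np.exp((xmid - day) / scal))
    return float(out) if out.ndim == 0 else out


def fit_logistic(daily: pd.DataFrame, max_nfev: int = 10_000) -> LogisticFit:
    """Nonlinear least squares of the pooled daily weights on the logistic
    curve.  Initialisation: bw_max at 1.05x the maximum observed weight,
    xmid at the day whose weight is nearest half of that, scal at 1/8 of
    the day span.  Non-convergence returns the best iterate, flagged."""
    day = daily["day"].to_numpy(dtype=float)
    bw = daily["bw_kg"].to_numpy(dtype=float)
    if pd.unique(daily["day"]).size < 3:
        raise ValueError("need >= 3 distinct days for a logistic fit")

    bw_max0 = 1.05 * bw.max()
    xmid0 = float(day[np.argmin(np.abs(bw - bw_max0 / 2.0))])
    scal0 = max(np.ptp(day) / 8.0, 1.0)

    def model(d, bw_max, xmid, scal):
        return bw_max / (1.0 + np.exp((xmid - d) / scal))

    converged = True
    try:
        with warnings.catch_warnings():
            # degenerate (e.g. flat) data cannot yield a covariance; the
            # converged flag carries that information instead
            warnings.simplefilter("ignore", OptimizeWarning)
            params, pcov = curve_fit(
                model, day, bw, p0=[bw_max0, xmid0, scal0], method="lm",
                maxfev=max_nfev, ftol=1e-10, xtol=1e-10)
    except RuntimeError:  # ran out of evaluations: report the start point
        converged = False
        params = np.array([bw_max0, xmid0, scal0])
        pcov = np.full((3, 3), np.inf)
    bw_max, xmid, scal = (float(p) for p in params)
    rss = float(np.sum((bw - model(day, *params)) ** 2))
    if not np.all(np.isfinite(pcov)) or scal <= 0 or bw_max <= 0:
        converged = False
    return LogisticFit(bw_max, xmid, scal, rss, converged)


def day_at_weight(fit: RobustGrowthFit, target: float,
                  day_range: tuple[float, float]) -> float:
    """Fractional day at which the robust-fit line crosses ``target`` kg.

    ``day_range`` is the animal's observed (min day, max day); targets whose
    line value falls outside the observed trajectory raise
    :class:`WeightOutOfRangeError`.
    """
    lo, hi = day_range
    bw_lo, bw_hi = fit.predict(lo), fit.predict(hi)
    if fit.slope == 0:
        raise WeightOutOfRangeError(
            f"pig {fit.pig_id}: flat trajectory, weight {target} unreachable")
    day = (target - fit.intercept) / fit.slope
    if not (min(lo, hi) - 1e-9 <= day <= max(lo, hi) + 1e-9):
        raise WeightOutOfRangeError(
            f"pig {fit.pig_id}: weight {target} kg outside fitted span "
            f"[{min(bw_lo, bw_hi):.2f}, {max(bw_lo, bw_hi):.2f}] kg")
    return float(day)
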