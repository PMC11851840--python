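"""Sliding-window analysis of FCR informativeness by measurement range.

Body-weight windows on a 10-kg grid inside 30-120 kg are scored by the
Spearman correlation, across animals, between the window FCR (feed per kg
gain inside the window) and the overall 30-120 kg FCR.  The per-size
average correlation as a function of window size shows an elbow; a
continuous two-segment linear fit locates the breakpoint, and the nearest
grid size is taken as the optimal measurement range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import RobustGrowthFit, WeightOutOfRangeError, day_at_weight

logger = logging.getLogger(__name__)

DEFAULT_SIZES = tuple(range(10, 90, 10))
WEIGHT_LO, WEIGHT_HI = 30.0, 120.0


@dataclass(frozen=True)
class ModuleWindow:
    start: float  # kg
    end: float  # kg

    @property
    def size(self) -> float:
        return self.end - self.start


@dataclass
class ModuleSizeSummary:
    size: float
    mean_spearman: float
    per_window: list[tuple[ModuleWindow, float]]


@dataclass
class BreakpointFit:
    breakpoint: float  # kg
    left_slope: float
    right_slope: float
    intercept: float
    rss: float
    candidates: np.ndarray
    no_elbow: bool


def cfi_at_weight(series: pd.DataFrame, fit: RobustGrowthFit,
                  w: float) -> float:
    """CFI (kg) at the fractional day where the robust-fit weight line
    crosses ``w`` kg, by linear interpolation of the animal's CFI series."""
    series = series.sort_values("day", kind="stable")
    day = series["day"].to_numpy(dtype=float)
    day_w = day_at_weight(fit, w, (day[0], day[-1]))
    return float(np.interp(day_w, day, series["cfi_kg"].to_numpy(float)))


def module_fcr(series: pd.DataFrame, fit: RobustGrowthFit,
               window: ModuleWindow) -> float:
    """Feed per kg gain inside the window: (CFI(end) - CFI(start)) / size."""
    return (cfi_at_weight(series, fit, window.end)
            - cfi_at_weight(series, fit, window.start)) / window.size


def window_grid(size: float, lo: float = WEIGHT_LO,
                hi: float = WEIGHT_HI) -> list[ModuleWindow]:
    """All windows of a given size with starts on the 10-kg grid in [lo, hi]."""
    starts = np.arange(lo, hi - size + 1e-9, 10.0)
    return [ModuleWindow(float(s), float(s + size)) for s in starts]


def sliding_window_summary(
    series: pd.DataFrame,
    growth_fits: dict[int, RobustGrowthFit],
    overall_fcr: dict[int, float],
    sizes=DEFAULT_SIZES,
    lo: float = WEIGHT_LO,
    hi: float = WEIGHT_HI,
    min_animals: int = 3,
) -> list[ModuleSizeSummary]:
    """Spearman correlation of window FCR with overall FCR per window,
    averaged per window size.

    ``overall_fcr`` maps animal -> overall 30-120 kg FCR (the regression
    reference CFI over 90 kg).  Animals not spanning a window are excluded
    from that window's correlation.
    """
    per_pig = {int(p): g for p, g in series.groupby("pig_id", sort=True)}
    ids = [p for p in per_pig if p in growth_fits and p in overall_fcr]
    summaries = []
    for size in sizes:
        per_window: list[tuple[ModuleWindow, float]] = []
        for win in window_grid(size, lo, hi):
            mod, ov = [], []
            skipped = 0
            for pid in ids:
                try:
                    mod.append(module_fcr(per_pig[pid], growth_fits[pid], win))
                    ov.append(overall_fcr[pid])
                except WeightOutOfRangeError:
                    skipped += 1
            if skipped:
                logger.debug("window %s-%s: %d animal(s) outside span",
                             win.start, win.end, skipped)
            if len(mod) < min_animals:
                logger.warning("window %s-%s: only %d animal(s); skipped",
                               win.start, win.end, len(mod))
                continue
            rho = stats.spearmanr(mod, ov).statistic
            per_window.append((win, float(rho)))
        if not per_window:
            continue
        summaries.append(ModuleSizeSummary(
            size=float(size),
            mean_spearman=float(np.mean([r for _, r in per_window])),
            per_window=per_window))
    return summaries


def _two_segment_rss(x: np.ndarray, y: np.ndarray,
                     c: float) -> tuple[float, np.ndarray]:
    """OLS of y on [1, x, max(x - c, 0)] — two lines meeting at c."""
    X = np.column_stack([np.ones_like(x), x, np.clip(x - c, 0.0, None)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def fit_breakpoint(sizes, means, grid_step: float = 0.1) -> BreakpointFit:
    """Continuous two-segment linear fit of mean correlation vs size.

    The breakpoint is found by exhaustive search over a ``grid_step`` grid
    on the open interior of the size range, each candidate scored by the
    RSS of the constrained two-segment OLS; ties break toward the smaller
    breakpoint.  Collinear inputs are flagged ``no_elbow``.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(means, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 (size, mean) points")
    order = np.argsort(x)
    x, y = x[order], y[order]

    candidates = np.round(
        np.arange(x[0] + grid_step, x[-1] - grid_step / 2, grid_step), 10)
    best_c, best_rss, best_beta = None, np.inf, None
    for c in candidates:
        rss, beta = _two_segment_rss(x, y, c)
        if rss < best_rss - 1e-15:
            best_c, best_rss, best_beta = float(c), rss, beta

    single = np.polyfit(x, y, 1)
    rss_single = float(np.sum((y - np.polyval(single, x)) ** 2))
    no_elbow = best_rss >= rss_single - 1e-12
    if no_elbow:
        logger.warning("fit_breakpoint: no elbow; two-segment fit does not "
                       "improve on a single line")
    intercept, b1, b2 = best_beta
    return BreakpointFit(
        breakpoint=best_c, left_slope=float(b1), right_slope=float(b1 + b2),
        intercept=float(intercept), rss=min(best_rss, rss_single),
        candidates=candidates, no_elbow=bool(no_elbow))


def select_optimal_module(bp: BreakpointFit, grid: float = 10.0) -> int:
    """Breakpoint rounded to the nearest window size on the 10-kg grid."""
    return int(np.floor(bp.breakpoint / grid + 0.5) * grid)
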