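"""Cumulative feed intake (CFI) standardization to the 30-120 kg range.

Per animal, CFI accumulated from test entry is regressed on body weight
over a start window (25-50 kg) and an end window (100-140 kg).  Two
correction models standardize CFI to exactly 30 and 120 kg:

* CF model — scales the endpoint-chord slope ``CFI_end / (BW_end - BW_in)``
  by CF, the population-mean ratio of each animal's best-fit slope to its
  chord slope::

      CFI_120 = CFI_end - (BW_end - 120) * [CFI_end / (BW_end - BW_in)] * CF
      CFI_30  = (30 - BW_in) * [CFI_end / (BW_end - BW_in)] * CF

* A model — uses A, the population-mean intercept of the per-animal
  BW -> CFI regression line (CFI = A + b * BW)::

      CFI_120 = CFI_end + (120 - BW_end) * (CFI_end - A) / BW_end
      CFI_30  = (30 - BW_in) * (CFI_end - A) / BW_end

The per-animal regression line also yields CFI_reg, the unbiased
reference value of the 30-120 kg intake: ``slope * (120 - 30)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_START_WINDOW = (25.0, 50.0)
DEFAULT_END_WINDOW = (100.0, 140.0)
#: animals whose BW->CFI line has R² below this are excluded
DEFAULT_CFI_R2_THRESHOLD = 0.9


@dataclass
class CfiLinearFit:
    """Per-animal BW -> CFI line and the endpoint quantities feeding the
    correction formulas."""

    pig_id: int
    slope_best: float  # kg feed per kg BW
    intercept_a: float  # kg (the per-animal A coefficient)
    r2: float
    bw_in: float  # kg, BW on the first test day
    bw_end: float  # kg, BW on the last test day
    cfi_end: float  # kg, CFI on the last test day
    cf: float  # slope_best / endpoint-chord slope
    retained: bool

    def line(self, bw):
        return self.intercept_a + self.slope_best * np.asarray(bw, float)


@dataclass
class CorrectionCoefficients:
    cf_mean: float
    a_mean: float
    n: int
    cf_sd: float
    a_sd: float

    def to_text(self) -> str:
        return (
            "population correction coefficients\n"
            f"n animals: {self.n}\n"
            f"CF: mean {self.cf_mean:.6f}  sd {self.cf_sd:.6f}\n"
            f"A:  mean {self.a_mean:.4f} kg  sd {self.a_sd:.4f} kg\n")


def build_cfi_series(daily: pd.DataFrame) -> pd.DataFrame:
    """Running per-animal sum of daily feed paired with that day's BW.

    ``daily`` needs columns ``pig_id, day, dfi_kg, bw_kg`` sorted by day
    within animal; duplicate (animal, day) pairs are an error.  Returns
    columns ``pig_id, day, cfi_kg, bw_kg``.
    """
    if daily.duplicated(subset=["pig_id", "day"]).any():
        dupes = daily.loc[daily.duplicated(subset=["pig_id", "day"]),
                          "pig_id"].unique()
        raise ValueError(f"duplicate (pig, day) rows for animals {dupes}")
    out = daily.sort_values(["pig_id", "day"], kind="stable").copy()
    out["cfi_kg"] = out.groupby("pig_id", sort=False)["dfi_kg"].cumsum()
    return out[["pig_id", "day", "cfi_kg", "bw_kg"]].reset_index(drop=True)


def fit_cfi_line(series: pd.DataFrame,
                 start_window: tuple[float, float] = DEFAULT_START_WINDOW,
                 end_window: tuple[float, float] = DEFAULT_END_WINDOW,
                 r2_threshold: float = DEFAULT_CFI_R2_THRESHOLD
                 ) -> CfiLinearFit:
    """OLS of CFI on BW over the start- and end-window points of one animal.

    Endpoint quantities (BW_in, BW_end, CFI_end) come from the first and
    last records of the full series; CFI at entry is zero by definition, so
    the endpoint-chord slope is ``CFI_end / (BW_end - BW_in)``.
    """
    series = series.sort_values("day", kind="stable")
    pig_id = int(series["pig_id"].iloc[0]) if "pig_id" in series else -1
    bw = series["bw_kg"].to_numpy(dtype=float)
    cfi = series["cfi_kg"].to_numpy(dtype=float)

    in_start = (bw >= start_window[0]) & (bw <= start_window[1])
    in_end = (bw >= end_window[0]) & (bw <= end_window[1])
    if in_start.sum() < 2 or in_end.sum() < 2:
        raise ValueError(
            f"pig {pig_id}: need >= 2 points in each fitting window "
            f"(got {int(in_start.sum())} in {start_window}, "
            f"{int(in_end.sum())} in {end_window})")
    sel = in_start | in_end
    reg = stats.linregress(bw[sel], cfi[sel])

    bw_in, bw_end = float(bw[0]), float(bw[-1])
    cfi_end = float(cfi[-1])
    if bw_end == bw_in:
        raise ValueError(f"pig {pig_id}: BW_end equals BW_in; "
                         "endpoint slope undefined")
    chord = cfi_end / (bw_end - bw_in)
    cf = float(reg.slope / chord)
    r2 = float(reg.rvalue ** 2)
    return CfiLinearFit(
        pig_id=pig_id, slope_best=float(reg.slope),
        intercept_a=float(reg.intercept), r2=r2, bw_in=bw_in, bw_end=bw_end,
        cfi_end=cfi_end, cf=cf, retained=bool(r2 >= r2_threshold))


def fit_all_cfi_lines(series: pd.DataFrame, **kwargs
                      ) -> dict[int, CfiLinearFit]:
    fits: dict[int, CfiLinearFit] = {}
    for pid, group in series.groupby("pig_id", sort=True):
        try:
            fits[int(pid)] = fit_cfi_line(group, **kwargs)
        except ValueError as exc:
            logger.info("fit_all_cfi_lines: skipping animal %s (%s)",
                        pid, exc)
    return fits


def population_coefficients(fits) -> CorrectionCoefficients:
    """Means and SDs of CF and A over retained animals."""
    if isinstance(fits, dict):
        fits = fits.values()
    retained = [f for f in fits if f.retained]
    if not retained:
        raise ValueError("no retained animals: cannot estimate coefficients")
    cf = np.array([f.cf for f in retained])
    a = np.array([f.intercept_a for f in retained])
    return CorrectionCoefficients(
        cf_mean=float(cf.mean()), a_mean=float(a.mean()), n=len(retained),
        cf_sd=float(cf.std(ddof=1)) if len(retained) > 1 else 0.0,
        a_sd=float(a.std(ddof=1)) if len(retained) > 1 else 0.0)


def correct_cfi_cf(cfi_end: float, bw_in: float, bw_end: float,
                   cf: float) -> tuple[float, float, float]:
    """CF-model standardization; returns (CFI_120, CFI_30, CFI_30-120)."""
    if bw_end <= bw_in:
        raise ValueError("BW_end must exceed BW_in")
    chord = cfi_end / (bw_end - bw_in)
    cfi_120 = cfi_end - (bw_end - 120.0) * chord * cf
    cfi_30 = (30.0 - bw_in) * chord * cf
    return cfi_120, cfi_30, cfi_120 - cfi_30


def correct_cfi_a(cfi_end: float, bw_in: float, bw_end: float,
                  a: float) -> tuple[float, float, float]:
    """A-model standardization; returns (CFI_120, CFI_30, CFI_30-120)."""
    if bw_end <= 0:
        raise ValueError("BW_end must be positive")
    slope = (cfi_end - a) / bw_end
    cfi_120 = cfi_end + (120.0 - bw_end) * slope
    cfi_30 = (30.0 - bw_in) * slope
    return cfi_120, cfi_30, cfi_120 - cfi_30


def cfi_reg_values(fit: CfiLinearFit) -> tuple[float, float, float]:
    """Regression-based reference CFI, anchored at the entry weight so that
    the line value at BW_in counts as zero accumulated feed.

    Returns (CFI_reg 30-120, CFI_reg at 120, CFI_reg at 30).
    """
    reg_120 = fit.slope_best * (120.0 - fit.bw_in)
    reg_30 = fit.slope_best * (30.0 - fit.bw_in)
    return fit.slope_best * 90.0, reg_120, reg_30


def apply_corrections(fits, coefficients: CorrectionCoefficients
                      ) -> pd.DataFrame:
    """Population-mean CF and A applied to every retained animal.

    One row per animal with both corrections, their 30-120 kg differences,
    and the regression-based reference values.
    """
    if isinstance(fits, dict):
        fits = fits.values()
    rows = []
    for f in fits:
        if not f.retained:
            continue
        cf_120, cf_30, cf_range = correct_cfi_cf(
            f.cfi_end, f.bw_in, f.bw_end, coefficients.cf_mean)
        a_120, a_30, a_range = correct_cfi_a(
            f.cfi_end, f.bw_in, f.bw_end, coefficients.a_mean)
        reg_range, reg_120, reg_30 = cfi_reg_values(f)
        rows.append({
            "pig_id": f.pig_id,
            "cfi_120_cf": cf_120, "cfi_30_cf": cf_30,
            "cfi_30_120_cf": cf_range,
            "cfi_120_a": a_120, "cfi_30_a": a_30, "cfi_30_120_a": a_range,
            "cfi_reg_30_120": reg_range, "cfi_reg_120": reg_120,
            "cfi_reg_30": reg_30,
        })
    return pd.DataFrame(rows)


@dataclass
class CorrectionEvaluation:
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    mean_abs_diff: dict[str, float]
    sd_diff: dict[str, float]

    def to_text(self) -> str:
        lines = ["correction evaluation (30-120 kg quantities)",
                 "", "Pearson:", self.pearson.round(4).to_string(),
                 "", "Spearman:", self.spearman.round(4).to_string(), ""]
        for k in self.mean_abs_diff:
            lines.append(f"|{k}|: mean {self.mean_abs_diff[k]:.3f} kg, "
                         f"sd {self.sd_diff[k]:.3f} kg")
        return "\n".join(lines) + "\n"


def evaluate_correction(corrected: pd.DataFrame) -> CorrectionEvaluation:
    """Pairwise correlations and differences among the three 30-120 kg
    quantities (CF-corrected, A-corrected, regression reference)."""
    cols = ["cfi_30_120_cf", "cfi_30_120_a", "cfi_reg_30_120"]
    if len(corrected) < 3:
        raise ValueError("need >= 3 animals to evaluate the correction")
    data = corrected[cols]
    zero_var = [c for c in cols if data[c].nunique() <= 1]
    if zero_var:
        logger.warning("evaluate_correction: zero variance in %s; "
                       "correlations undefined (NaN)", zero_var)
    pearson = data.corr(method="pearson")
    spearman = data.corr(method="spearman")
    for c in zero_var:
        pearson.loc[c, :] = pearson.loc[:, c] = np.nan
        spearman.loc[c, :] = spearman.loc[:, c] = np.nan
    diffs = {
        "cf - reg": data["cfi_30_120_cf"] - data["cfi_reg_30_120"],
        "a - reg": data["cfi_30_120_a"] - data["cfi_reg_30_120"],
        "cf - a": data["cfi_30_120_cf"] - data["cfi_30_120_a"],
    }
    return CorrectionEvaluation(
        pearson=pearson, spearman=spearman,
        mean_abs_diff={k: float(v.abs().mean()) for k, v in diffs.items()},
        sd_diff={k: float(v.std(ddof=1)) for k, v in diffs.items()})
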