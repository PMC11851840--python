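"""Bayesian ridge regression for short-window CFI prediction.

The model predicts an animal's 30-120 kg cumulative feed intake from three
window-level predictors — BW at window entry, BW at window exit, and the
feed consumed inside the window::

    CFI_p = b1 * BW_in + b2 * BW_out + b3 * CFI_window + intercept

Coefficients carry a zero-mean isotropic Gaussian prior with precision
``lambda``; observation noise has precision ``alpha``.  Both precisions are
estimated by evidence (type-II marginal likelihood) maximization with the
MacKay fixed-point update and flat hyperpriors.  Predictors are
standardized internally and coefficients reported on the original scale;
the intercept is unpenalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .cfi import CfiLinearFit, cfi_reg_values
from .growth import RobustGrowthFit, WeightOutOfRangeError
from .windows import ModuleWindow, cfi_at_weight

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ["bw_in", "bw_out", "cfi_window"]


class EvidenceBayesianRidge(RegressorMixin, BaseEstimator):
    """Gaussian linear model with evidence-maximized ridge regularization.

    Parameters
    ----------
    alpha_init, lambda_init:
        Starting values for the noise and weight-prior precisions.  With
        ``optimize_hyperparameters=False`` they are held fixed, in which
        case the coefficients equal the closed-form ridge solution
        ``(X'X + (lambda/alpha) I)^-1 X'y`` on the standardized data.
    max_iter, tol:
        Fixed-point iteration budget and relative-change stopping rule.

    Attributes (after fit): ``coef_``, ``intercept_`` on the original
    scale, ``alpha_``, ``lambda_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, alpha_init: float = 1.0, lambda_init: float = 1.0,
                 optimize_hyperparameters: bool = True, max_iter: int = 300,
                 tol: float = 1e-8):
        self.alpha_init = alpha_init
        self.lambda_init = lambda_init
        self.optimize_hyperparameters = optimize_hyperparameters
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = X.shape
        if n < 5:
            raise ValueError("need >= 5 rows")
        if np.ptp(y) == 0.0:
            raise ValueError("target is constant; nothing to fit")

        self.x_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.zero_variance_mask_ = scale == 0.0
        if self.zero_variance_mask_.any():
            logger.info("fit: %d zero-variance predictor(s); their "
                        "coefficients are fixed at 0",
                        int(self.zero_variance_mask_.sum()))
        scale = np.where(scale == 0.0, 1.0, scale)
        self.x_scale_ = scale
        self.y_mean_ = y.mean()

        Xs = (X - self.x_mean_) / scale
        yc = y - self.y_mean_

        # SVD once; all fixed-point quantities follow from the spectrum.
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        s2 = s ** 2
        uty = U.T @ yc

        alpha = float(self.alpha_init)
        lam = float(self.lambda_init)
        coef_std = np.zeros(p)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            shrink = s / (s2 + lam / alpha)
            coef_new = Vt.T @ (shrink * uty)
            if not self.optimize_hyperparameters:
                coef_std = coef_new
                converged = True
                n_iter = 1
                break
            resid = yc - Xs @ coef_new
            rss = float(resid @ resid)
            gamma = float(np.sum(s2 / (s2 + lam / alpha)))
            wtw = float(coef_new @ coef_new)
            lam_new = gamma / wtw if wtw > 0 else lam
            alpha_new = (n - gamma) / rss if rss > 0 else alpha * 10.0
            delta = np.max(np.abs(coef_new - coef_std)) / max(
                np.max(np.abs(coef_new)), 1e-30)
            coef_std = coef_new
            if (abs(lam_new - lam) <= self.tol * abs(lam)
                    and abs(alpha_new - alpha) <= self.tol * abs(alpha)
                    and delta <= self.tol):
                lam, alpha = lam_new, alpha_new
                converged = True
                break
            lam, alpha = lam_new, alpha_new
        # final coefficient refresh at the converged precisions
        shrink = s / (s2 + lam / alpha)
        coef_std = Vt.T @ (shrink * uty)
        coef_std[self.zero_variance_mask_] = 0.0

        self.alpha_ = alpha
        self.lambda_ = lam
        self.n_iter_ = n_iter
        self.converged_ = converged
        if not converged:
            logger.warning("fit: evidence fixed point not converged after "
                           "%d iterations", self.max_iter)
        self.coef_ = coef_std / scale
        self.intercept_ = float(self.y_mean_ - self.coef_ @ self.x_mean_)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


@dataclass
class CvReport:
    """k-fold cross-validation summary for the CFI predictor."""

    k: int
    seed: int
    per_fold: list[dict]  # each: mse (kg^2), rmse (kg), r2
    mse_mean: float
    mse_sd: float
    rmse_mean: float
    rmse_sd: float
    r2_mean: float
    r2_sd: float
    spearman: float  # pooled out-of-fold predictions vs target
    pearson: float
    oof_predictions: pd.DataFrame = field(repr=False, default=None)

    def to_text(self) -> str:
        return (
            f"{self.k}-fold cross-validation (seed {self.seed})\n"
            f"MSE:  {self.mse_mean:.2f} +/- {self.mse_sd:.2f} kg^2\n"
            f"RMSE: {self.rmse_mean:.2f} +/- {self.rmse_sd:.2f} kg\n"
            f"R2:   {self.r2_mean:.3f} +/- {self.r2_sd:.3f}\n"
            f"out-of-fold Spearman: {self.spearman:.3f}\n"
            f"out-of-fold Pearson:  {self.pearson:.3f}\n")


def build_design(series: pd.DataFrame,
                 growth_fits: dict[int, RobustGrowthFit],
                 cfi_fits: dict[int, CfiLinearFit],
                 window: ModuleWindow) -> pd.DataFrame:
    """One row per animal spanning the window: BW_in/BW_out at the window
    bounds, measured CFI inside the window, and the CFI_reg target."""
    rows = []
    dropped = 0
    for pid, group in series.groupby("pig_id", sort=True):
        pid = int(pid)
        if pid not in growth_fits or pid not in cfi_fits:
            continue
        if not cfi_fits[pid].retained:
            continue
        try:
            c_in = cfi_at_weight(group, growth_fits[pid], window.start)
            c_out = cfi_at_weight(group, growth_fits[pid], window.end)
        except WeightOutOfRangeError:
            dropped += 1
            continue
        target, _, _ = cfi_reg_values(cfi_fits[pid])
        rows.append({
            "pig_id": pid, "bw_in": window.start, "bw_out": window.end,
            "cfi_window": c_out - c_in, "target": target,
        })
    if dropped:
        logger.info("build_design %s-%s kg: dropped %d non-spanning "
                    "animal(s)", window.start, window.end, dropped)
    design = pd.DataFrame(rows)
    if not design.empty:
        constant = [c for c in DESIGN_COLUMNS if design[c].nunique() <= 1]
        if constant:
            logger.info("build_design: zero-variance column(s) %s", constant)
    return design


def fit_brr(design: pd.DataFrame, **params) -> EvidenceBayesianRidge:
    model = EvidenceBayesianRidge(**params)
    return model.fit(design[DESIGN_COLUMNS].to_numpy(),
                     design["target"].to_numpy())


def predict_cfi(model: EvidenceBayesianRidge,
                design: pd.DataFrame) -> np.ndarray:
    return model.predict(design[DESIGN_COLUMNS].to_numpy())


def cross_validate(design: pd.DataFrame, k: int, seed: int,
                   **params) -> CvReport:
    """Animal-level shuffled k-fold CV; pooled out-of-fold predictions give
    the report's rank and linear correlations with the target."""
    n = len(design)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available animals")
    if k < 2:
        raise ValueError("k must be >= 2")
    design = design.sort_values("pig_id", kind="stable").reset_index(drop=True)
    X = design[DESIGN_COLUMNS].to_numpy()
    y = design["target"].to_numpy()

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    oof = np.full(n, np.nan)
    for train_idx, test_idx in kf.split(X):
        model = EvidenceBayesianRidge(**params).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        oof[test_idx] = pred
        mse = float(mean_squared_error(y[test_idx], pred))
        r2 = (float(r2_score(y[test_idx], pred))
              if len(test_idx) >= 2 else np.nan)
        per_fold.append({"mse": mse, "rmse": float(np.sqrt(mse)), "r2": r2})

    mses = np.array([f["mse"] for f in per_fold])
    rmses = np.array([f["rmse"] for f in per_fold])
    r2s = np.array([f["r2"] for f in per_fold], dtype=float)
    oof_df = design[["pig_id"]].copy()
    oof_df["target"] = y
    oof_df["predicted"] = oof
    return CvReport(
        k=k, seed=seed, per_fold=per_fold,
        mse_mean=float(mses.mean()), mse_sd=float(mses.std(ddof=1)),
        rmse_mean=float(rmses.mean()), rmse_sd=float(rmses.std(ddof=1)),
        r2_mean=float(r2s[np.isfinite(r2s)].mean())
        if np.isfinite(r2s).any() else float("nan"),
        r2_sd=float(r2s[np.isfinite(r2s)].std(ddof=1))
        if np.isfinite(r2s).sum() > 1 else 0.0,
        spearman=float(stats.spearmanr(oof, y).statistic),
        pearson=float(stats.pearsonr(oof, y).statistic),
        oof_predictions=oof_df)


def derive_fcr(cfi_30_120, mode: str = "per-kg-gain", gain: float = 90.0,
               days=None):
    """FCR from a 30-120 kg CFI value.

    ``per-kg-gain`` (default): feed per kg of gain, cfi / 90 (kg/kg).
    ``per-day``: feed per day of measurement, cfi / days (kg/day).
    """
    cfi = np.asarray(cfi_30_120, dtype=float)
    if mode == "per-kg-gain":
        if gain <= 0:
            raise ValueError("gain must be positive")
        out = cfi / gain
    elif mode == "per-day":
        days_arr = np.asarray(days, dtype=float)
        if days is None or np.any(days_arr <= 0):
            raise ValueError("days must be positive for per-day mode")
        out = cfi / days_arr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if out.ndim == 0 else out
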