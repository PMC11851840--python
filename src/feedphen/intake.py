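"""Single-visit intake outlier flagging and model-based imputation.

Visits whose feed intake deviates more than three standard deviations from
the population mean are flagged.  A linear model of per-visit intake on body
weight, occupation time and their interaction — with a per-animal random
intercept fitted by REML — is estimated on the unflagged visits and used to
replace flagged intakes with predicted values.  Marginal and conditional R²
follow the Nakagawa variance decomposition: the marginal value is the
fixed-effect share of total variance, the conditional value adds the
animal-level variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """The intake design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "singular intake design; collinear column(s): "
            + ", ".join(self.columns))


@dataclass
class IntakeModelFit:
    """Fitted intake model: FIV ~ BW + OTV + BW:OTV + (1 | animal)."""

    intercept: float  # g
    coef_bw: float  # g per kg
    coef_t: float  # g per s
    coef_bw_t: float  # g per (kg * s)
    random_intercepts: dict[int, float]  # pig_id -> g
    marginal_r2: float
    conditional_r2: float
    residual_sd: float  # g

    def predict(self, events: pd.DataFrame,
                use_random_effects: bool = True) -> np.ndarray:
        bw = events["bw_kg"].to_numpy(dtype=float)
        otv = events["otv_s"].to_numpy(dtype=float)
        pred = (self.intercept + self.coef_bw * bw + self.coef_t * otv
                + self.coef_bw_t * bw * otv)
        if use_random_effects and self.random_intercepts:
            offsets = np.array([
                self.random_intercepts.get(int(p), 0.0)
                for p in events["pig_id"]
            ])
            unknown = sum(int(p) not in self.random_intercepts
                          for p in events["pig_id"].unique())
            if unknown:
                logger.info("intake prediction: %d animal(s) unseen at fit "
                            "time use fixed effects only", unknown)
            pred = pred + offsets
        return pred


def flag_intake_outliers(events: pd.DataFrame) -> np.ndarray:
    """Boolean mask: |FIV - mean| strictly greater than 3 population SDs.

    A single pass with population (ddof 0) statistics over all visits.
    """
    if len(events) < 2:
        raise ValueError("need >= 2 events to flag outliers")
    fiv = events["fiv_g"].to_numpy(dtype=float)
    mean, sd = float(np.mean(fiv)), float(np.std(fiv))
    if sd == 0.0:
        return np.zeros(len(events), dtype=bool)
    return np.abs(fiv - mean) > 3.0 * sd


def _design(events: pd.DataFrame) -> np.ndarray:
    bw = events["bw_kg"].to_numpy(dtype=float)
    otv = events["otv_s"].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(events)), bw, otv, bw * otv])


def _check_rank(X: np.ndarray) -> None:
    names = ["const", "bw", "otv", "bw:otv"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offenders: columns whose removal restores full rank
        base_rank = np.linalg.matrix_rank(X)
        offenders = [
            names[j] for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == base_rank
        ]
        raise SingularDesignError(offenders or names[1:])


def fit_intake_model(events: pd.DataFrame,
                     max_rows: int = 150_000) -> IntakeModelFit:
    """Fit the intake model on unflagged visits.

    Needs >= 10 visits from >= 2 animals.  For very large visit tables a
    deterministic evenly spaced subsample of ``max_rows`` visits is used;
    the model has four fixed parameters and two variance components, so the
    subsample estimates are indistinguishable at this size.
    """
    if len(events) < 10 or events["pig_id"].nunique() < 2:
        raise ValueError("need >= 10 events from >= 2 animals")
    if len(events) > max_rows:
        take = np.linspace(0, len(events) - 1, max_rows).astype(np.int64)
        events = events.iloc[np.unique(take)]

    X = _design(events)
    y = events["fiv_g"].to_numpy(dtype=float)
    _check_rank(X)

    # OLS first: on (near-)noise-free data the mixed model is degenerate.
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0 or ss_res / ss_tot < 1e-12:
        groups = events.groupby("pig_id", sort=True)["fiv_g"]
        return IntakeModelFit(
            intercept=float(beta[0]), coef_bw=float(beta[1]),
            coef_t=float(beta[2]), coef_bw_t=float(beta[3]),
            random_intercepts={int(p): 0.0 for p in groups.groups},
            marginal_r2=1.0, conditional_r2=1.0, residual_sd=0.0)

    groups = events["pig_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True, method="lbfgs", maxiter=200)

    fe = np.asarray(res.fe_params, dtype=float)
    var_fixed = float(np.var(X @ fe))
    var_re = float(np.asarray(res.cov_re)[0, 0])
    var_res = float(res.scale)
    total = var_fixed + var_re + var_res
    random_intercepts = {int(k): float(np.asarray(v)[0])
                         for k, v in res.random_effects.items()}
    return IntakeModelFit(
        intercept=float(fe[0]), coef_bw=float(fe[1]), coef_t=float(fe[2]),
        coef_bw_t=float(fe[3]), random_intercepts=random_intercepts,
        marginal_r2=var_fixed / total,
        conditional_r2=(var_fixed + var_re) / total,
        residual_sd=float(np.sqrt(var_res)))


def impute_flagged(model: IntakeModelFit, events: pd.DataFrame,
                   flagged: np.ndarray) -> pd.DataFrame:
    """Replace flagged intakes by model predictions; other fields untouched.

    Animals unseen at fit time get fixed-effect-only predictions; negative
    predictions are clipped to zero with a logged warning.
    """
    out = events.copy()
    if not np.any(flagged):
        return out
    rows = out.loc[flagged]
    pred = model.predict(rows)
    negative = pred < 0.0
    if negative.any():
        logger.warning("impute_flagged: clipped %d negative prediction(s) "
                       "to 0 g", int(negative.sum()))
        pred = np.clip(pred, 0.0, None)
    out.loc[flagged, "fiv_g"] = pred
    return out


@dataclass
class IntakeImputer:
    """Estimator-style wrapper: ``fit`` learns the flagging statistics and
    the intake model from a visit table, ``transform`` imputes flagged
    visits.  Follows the scikit-learn fit/transform protocol on DataFrames.
    """

    max_rows: int = 150_000

    def get_params(self, deep: bool = True) -> dict:
        return {"max_rows": self.max_rows}

    def set_params(self, **params) -> "IntakeImputer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, events: pd.DataFrame, y=None) -> "IntakeImputer":
        fiv = events["fiv_g"].to_numpy(dtype=float)
        self.mean_ = float(np.mean(fiv))
        self.sd_ = float(np.std(fiv))
        flagged = flag_intake_outliers(events)
        self.model_ = fit_intake_model(events.loc[~flagged],
                                       max_rows=self.max_rows)
        self.n_flagged_ = int(flagged.sum())
        return self

    def flag(self, events: pd.DataFrame) -> np.ndarray:
        if self.sd_ == 0.0:
            return np.zeros(len(events), dtype=bool)
        fiv = events["fiv_g"].to_numpy(dtype=float)
        return np.abs(fiv - self.mean_) > 3.0 * self.sd_

    def transform(self, events: pd.DataFrame) -> pd.DataFrame:
        return impute_flagged(self.model_, events, self.flag(events))

    def fit_transform(self, events: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(events).transform(events)
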