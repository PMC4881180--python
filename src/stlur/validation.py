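"""Internal cross-validation, external validation and agreement metrics.

Internal validation is ten-fold: observations are randomly partitioned, the
model's variables stay fixed while the coefficients are refit on each 90 %
training split, and every observation is predicted exactly once out-of-fold.
Metrics are reported on the log scale (on which the model is fit) and on the
concentration scale (predictions exponentiated, no retransformation bias
correction); RMSE is reported on the concentration scale only.

External validation routes each residence measurement to the rural or urban
model by its region tag, corrects backyard measurements by a multiplicative
factor estimated from model residual strata, and adds a weighted-kappa
comparison of exposure quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import RegressionFit, fit_no_intercept, manual_r2
from .terms import TermSpec, build_design_matrix

__all__ = [
    "ValidationReport",
    "BackyardCorrection",
    "kfold_cv",
    "evaluate",
    "bland_altman",
    "weighted_kappa_quartiles",
    "estimate_backyard_correction",
    "external_validate",
    "validation_table",
]


@dataclass
class ValidationReport:
    """Agreement between measured and predicted NO2 on one scale."""

    scale: str  # "log" | "concentration"
    pearson_r: float
    r2: float
    rmse: float | None  # concentration scale only (ug/m3)
    bland_altman_mean: float
    bland_altman_slope: float
    n: int
    kappa_quartiles: float | None = None
    degenerate: bool = False  # constant predictions / R2 <= 0


@dataclass
class BackyardCorrection:
    """Multiplicative correction for backyard-placed samplers, per region."""

    factor_rural: float | None = None
    factor_urban: float | None = None

    def factor(self, region_kind: str) -> float:
        f = self.factor_rural if region_kind == "rural" else self.factor_urban
        if f is None:
            raise ValueError(f"no backyard factor for region {region_kind!r}")
        if f <= 0:
            raise ValueError("backyard factor must be > 0")
        return f


def kfold_cv(
    terms: list[TermSpec],
    data: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold predictions (log scale) under seeded k-fold refitting.

    The folds are a random partition of observations; the term set is fixed
    and only the coefficients are refit per fold.  ``k = n`` is exact
    leave-one-out.
    """
    y = np.asarray(y, float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n (k={k}, n={n})")
    X, names = build_design_matrix(terms, data)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % k
    preds = np.empty(n)
    for f in range(k):
        test = fold == f
        train = ~test
        if train.sum() <= p:
            raise ValueError(
                f"fold {f} leaves {int(train.sum())} training rows for {p} "
                "design columns; use a smaller k"
            )
        fit = fit_no_intercept(y[train], X[train], names)
        preds[test] = X[test] @ fit.beta
    return preds


def evaluate(
    observed: np.ndarray,
    predicted_log: np.ndarray,
    scale: str = "log",
) -> ValidationReport:
    """Compare measured concentrations with log-scale predictions.

    ``observed`` is always on the concentration scale (ug/m3).  On the log
    scale the comparison is log(observed) vs ``predicted_log``; on the
    concentration scale it is observed vs exp(predicted_log), with RMSE.
    """
    observed = np.asarray(observed, float)
    predicted_log = np.asarray(predicted_log, float)
    if observed.shape != predicted_log.shape or observed.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.any(observed <= 0):
        raise ValueError("non-positive observed concentrations")
    if scale == "log":
        obs, pred = np.log(observed), predicted_log
        rmse = None
    elif scale == "concentration":
        obs, pred = observed, np.exp(predicted_log)
        rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    else:
        raise ValueError(f"scale must be log|concentration, got {scale!r}")
    degenerate = np.std(pred) == 0
    r = 0.0 if degenerate else float(stats.pearsonr(obs, pred)[0])
    r2 = manual_r2(obs, pred)
    ba_mean, ba_slope = bland_altman(obs, pred)
    return ValidationReport(
        scale=scale,
        pearson_r=r,
        r2=r2,
        rmse=rmse,
        bland_altman_mean=ba_mean,
        bland_altman_slope=ba_slope,
        n=observed.size,
        degenerate=degenerate or r2 <= 0,
    )


def bland_altman(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Mean difference (predicted - observed) and the slope of the differences
    regressed on the pair means (with intercept)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    diff = predicted - observed
    mean = (predicted + observed) / 2.0
    if np.std(mean) == 0:
        slope = 0.0
    else:
        slope = float(np.polyfit(mean, diff, 1)[0])
    return float(diff.mean()), slope


def weighted_kappa_quartiles(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Linear-weighted Cohen's kappa of quartile exposure classes.

    Both vectors are cut into 4 classes at the observed vector's quartiles
    (shared binning); weights are 1 - |i - j|/3.
    """
    from sklearn.metrics import cohen_kappa_score

    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size < 8:
        raise ValueError("need at least 8 pairs for quartile classes")
    cuts = np.quantile(observed, [0.25, 0.5, 0.75])
    co = np.digitize(observed, cuts)
    counts = np.bincount(co, minlength=4)
    if (counts == 0).any():
        raise ValueError(
            f"ties leave empty observed quartile bins (counts {counts.tolist()})"
        )
    cp = np.digitize(predicted, cuts)
    if np.array_equal(co, cp):
        return 1.0
    return float(
        cohen_kappa_score(co, cp, labels=[0, 1, 2, 3], weights="linear")
    )


def estimate_backyard_correction(
    log_residuals: np.ndarray,
    backyard: np.ndarray,
    region_kind: np.ndarray | str,
) -> BackyardCorrection:
    """Backyard correction factors from model residual strata.

    With residuals log(measured) - log(predicted), the factor per region is
    exp(mean residual of non-backyard - mean residual of backyard); applying
    it multiplicatively to backyard measured concentrations removes the
    stratum difference in mean log residuals.
    """
    log_residuals = np.asarray(log_residuals, float)
    backyard = np.asarray(backyard, bool)
    if isinstance(region_kind, str):
        region_kind = np.full(log_residuals.shape, region_kind)
    region_kind = np.asarray(region_kind)
    out = BackyardCorrection()
    for kind in np.unique(region_kind):
        sel = region_kind == kind
        by = backyard & sel
        front = ~backyard & sel
        if by.sum() == 0 or front.sum() == 0:
            raise ValueError(
                f"region {kind!r}: need both backyard and non-backyard "
                f"measurements (got {int(by.sum())} / {int(front.sum())})"
            )
        factor = float(np.exp(log_residuals[front].mean() - log_residuals[by].mean()))
        if kind == "rural":
            out.factor_rural = factor
        else:
            out.factor_urban = factor
    return out


def external_validate(
    fits: dict[str, RegressionFit],
    measurements: pd.DataFrame,
    predictors: pd.DataFrame,
    correction: BackyardCorrection | None = None,
) -> dict[str, ValidationReport]:
    """External validation with model choice by location.

    Each measurement row (columns ``no2, region_kind, backyard``) is predicted
    by the fit matching its region tag; backyard measurements are multiplied
    by the region's correction factor before comparison.  Returns reports on
    both scales; the concentration-scale report carries the weighted kappa of
    exposure quartiles.
    """
    if "region_kind" not in measurements:
        raise ValueError("measurements need a region_kind column (rural|urban)")
    unknown = set(measurements.region_kind.unique()) - set(fits)
    if unknown:
        raise ValueError(f"no model for region tag(s) {sorted(unknown)}")
    pred_log = np.empty(len(measurements))
    for kind, fit in fits.items():
        sel = (measurements.region_kind == kind).to_numpy()
        if sel.any():
            pred_log[sel] = fit.predict(predictors.loc[sel])
    obs = measurements.no2.to_numpy(dtype=float).copy()
    if correction is not None:
        by = measurements.backyard.to_numpy(bool)
        for kind in measurements.region_kind.unique():
            sel = by & (measurements.region_kind == kind).to_numpy()
            obs[sel] *= correction.factor(kind)
    out = {
        "log": evaluate(obs, pred_log, "log"),
        "concentration": evaluate(obs, pred_log, "concentration"),
    }
    out["concentration"].kappa_quartiles = weighted_kappa_quartiles(
        obs, np.exp(pred_log)
    )
    return out


def validation_table(reports: dict[str, dict[str, ValidationReport]]) -> pd.DataFrame:
    """Serialize evaluation rows (model / internal CV / external validation)
    into one frame: Pearson r and R^2 on both scales, concentration RMSE."""
    rows = []
    for name, by_scale in reports.items():
        log_r = by_scale["log"]
        conc = by_scale["concentration"]
        rows.append(
            {
                "evaluation": name,
                "pearson_r_log": log_r.pearson_r,
                "pearson_r_conc": conc.pearson_r,
                "r2_log": log_r.r2,
                "r2_conc": conc.r2,
                "rmse_conc": conc.rmse,
                "n": conc.n,
            }
        )
    return pd.DataFrame(rows)
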