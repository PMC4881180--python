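"""No-intercept log-scale multivariable regression.

The exposure model regresses log NO2 on spatial and temporal predictors with
the intercept suppressed: the near-constant background terms (dispersion-model
NO2, time trend) absorb the baseline.  Because standard software does not
report R^2 for a through-origin fit, the coefficient of determination is
computed manually about the observed mean, which keeps it comparable with
intercept-including land-use-regression models.

Confidence intervals use the t distribution with n - p degrees of freedom
(no intercept, p design columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .terms import TermSpec, build_design_matrix

__all__ = [
    "RegressionFit",
    "RankDeficientError",
    "fit_no_intercept",
    "fit_terms",
    "manual_r2",
    "adjusted_r2",
    "vif",
    "iqr_report",
]

_RCOND = 1e-10


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is (numerically) rank deficient."""


@dataclass
class RegressionFit:
    """Result of a no-intercept ordinary-least-squares fit on the log scale."""

    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    resid_sd: float
    r2: float
    adj_r2: float
    nobs: int
    names: list[str]
    terms: list[TermSpec] | None = None

    @property
    def p(self) -> int:
        return len(self.names)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predict log NO2 for new rows (requires the fit to carry its terms)."""
        if self.terms is None:
            raise ValueError("fit does not carry its term list; use the design matrix")
        X, names = build_design_matrix(self.terms, data)
        if names != self.names:
            raise ValueError("design columns do not match the fitted model")
        return X @ self.beta

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            },
            index=pd.Index(self.names, name="term"),
        )


def fit_no_intercept(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> RegressionFit:
    """Ordinary least squares through the origin.

    Solved by singular-value decomposition; raises :class:`RankDeficientError`
    naming the suspect columns when the design is numerically singular.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than design columns ({p})")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < _RCOND:
        null = Vt[-1]
        suspects = [names[j] for j in np.argsort(-np.abs(null))[:3]]
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns involve {suspects}"
        )
    beta = Vt.T @ ((U.T @ y) / s)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    cov = (Vt.T * (1.0 / s**2)) @ Vt * sigma2
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, dof)
    r2 = manual_r2(y, fitted)
    return RegressionFit(
        beta=beta,
        se=se,
        ci_low=beta - tcrit * se,
        ci_high=beta + tcrit * se,
        resid_sd=float(np.sqrt(sigma2)),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p) if n > p + 1 else np.nan,
        nobs=n,
        names=list(names),
    )


def fit_terms(terms: list[TermSpec], data: pd.DataFrame, y: np.ndarray) -> RegressionFit:
    """Build the design matrix for ``terms`` and fit the no-intercept model."""
    X, names = build_design_matrix(terms, data)
    fit = fit_no_intercept(np.asarray(y, float), X, names)
    fit.terms = list(terms)
    return fit


def manual_r2(y: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST with SST about the observed mean.

    Computed manually because regression software omits R^2 when the intercept
    is suppressed.  Can be negative for a model worse than the mean.
    """
    y = np.asarray(y, float)
    fitted = np.asarray(fitted, float)
    if y.shape != fitted.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    sse = float(np.sum((y - fitted) ** 2))
    return 1.0 - sse / sst


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if p < 1 or n <= p + 1:
        raise ValueError(f"adjusted R^2 needs n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def vif(X: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per design column.

    Each column is regressed on the remaining columns plus an intercept;
    VIF_j = 1/(1 - R_j^2).  Perfectly collinear columns report ``inf``.
    Values >= 10 conventionally flag strong collinearity.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[j] = np.inf
            continue
        r2j = 1.0 - float(resid @ resid) / sst
        out[j] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return pd.Series(out, index=names, name="vif")


def iqr_report(
    terms: list[TermSpec],
    data: pd.DataFrame,
    y: np.ndarray,
    land_use_terms: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Per-IQR coefficient report with cumulative-R^2 ordering.

    Percentiles (25/50/75, linear interpolation) are taken on the design
    columns, i.e. on the transformed scale on which each term enters the
    model; the per-IQR estimate is beta * (p75 - p25).  Terms named in
    ``land_use_terms`` (fractions coded 0-1) are reported per 0 -> 100 % of
    used area instead, because their IQR is typically 0.  Terms are ordered by
    greedy forward addition over the final term set, maximising adjusted R^2
    at each step; the cumulative adjusted R^2 after each addition is attached.
    """
    y = np.asarray(y, float)
    X, names = build_design_matrix(terms, data)
    if len(names) != len(terms):
        raise ValueError("iqr_report requires single-column terms (no splines)")
    fit = fit_no_intercept(y, X, names)

    # greedy forward ordering by incremental adjusted R^2
    remaining = list(range(len(terms)))
    order: list[int] = []
    cum_adj: list[float] = []
    while remaining:
        best_j, best_adj = None, -np.inf
        for j in remaining:
            cols = order + [j]
            sub = fit_no_intercept(y, X[:, cols], [names[c] for c in cols])
            a = sub.adj_r2 if np.isfinite(sub.adj_r2) else sub.r2
            if a > best_adj:
                best_j, best_adj = j, a
        order.append(best_j)
        cum_adj.append(best_adj)
        remaining.remove(best_j)

    rows = []
    for rank, j in enumerate(order):
        col = X[:, j]
        p25, p50, p75 = np.percentile(col, [25, 50, 75])
        iqr = p75 - p25
        beta = fit.beta[j]
        if names[j] in land_use_terms:
            scaling, scale = "per_0_to_100", 1.0
        elif iqr == 0:
            scaling, scale = "zero_iqr", 1.0
        else:
            scaling, scale = "iqr", iqr
        rows.append(
            {
                "variable": names[j],
                "p25": p25,
                "p50": p50,
                "p75": p75,
                "estimate_per_iqr": beta * scale,
                "ci_low": fit.ci_low[j] * scale,
                "ci_high": fit.ci_high[j] * scale,
                "cum_adj_r2": cum_adj[rank],
                "scaling": scaling,
                "beta": beta,
            }
        )
    return pd.DataFrame(rows)
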