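"""Generalized least squares for LoD-versus-abundance comparisons.

Linear comparisons use GLS fitted by maximum likelihood, either with iid
errors (equivalent to ordinary least squares) or with first-order
autoregressive (AR(1)) errors for temporal series, where successive time-bin
residuals are allowed correlation rho^|lag| (order-based lags: adjacent bins
are one step apart regardless of their durations).  Goodness of fit is a
likelihood-ratio pseudo-R^2 against the intercept-only null fitted under the
same correlation structure and transformation:

    pseudo-R^2 = 1 - exp(-(2/n) * (loglik_model - loglik_null))

ML (not REML) estimation is used throughout so the model-null log-likelihood
difference is valid.  Standard errors use the n-2 residual-variance
denominator, so with iid errors slope/t/p reproduce the textbook OLS closed
forms exactly; p-values are two-tailed from a t distribution with n-2 df.

Both variables are log-transformed before fitting by default in the pipeline
(to normalize residuals); non-positive values are dropped pairwise with a
warning, since a log of a zero abundance is undefined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fossil_data import ValidationError

__all__ = [
    "RegressionResult",
    "ComparisonSpec",
    "fit_gls",
    "pseudo_r2",
    "run_comparisons",
]

_RHO_BOUND = 0.99


@dataclass
class RegressionResult:
    comparison_id: str
    slope: float
    intercept: float
    t_value: float
    p_value: float
    pseudo_r2: float
    n: int
    correlation: str = "none"  # none | ar1
    rho: float | None = None
    log_transformed: bool = False
    n_dropped: int = 0
    loglik_model: float = math.nan
    loglik_null: float = math.nan


@dataclass(frozen=True)
class ComparisonSpec:
    """One comparison: response ~ predictor within a named proxy table."""

    comparison_id: str
    table: str
    response: str
    predictor: str
    correlation: str = "none"
    log_transform: bool | str = True


def _normalize_log_mode(log_transform: bool | str) -> str:
    """Map the log_transform flag to one of 'none', 'x', 'y', 'both'."""
    if log_transform is True:
        return "both"
    if log_transform is False:
        return "none"
    if log_transform in ("none", "x", "y", "both"):
        return log_transform
    raise ValidationError(f"unknown log_transform {log_transform!r}")


def _ar1_whiten(M: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) whitening transform row-wise (first row scaled, rest differenced)."""
    out = np.empty_like(M, dtype=float)
    out[0] = math.sqrt(1.0 - rho * rho) * M[0]
    out[1:] = M[1:] - rho * M[:-1]
    return out


def _fit_given_rho(X: np.ndarray, y: np.ndarray, rho: float):
    """GLS fit for fixed rho; returns (beta, rss_w, XtX_inv, loglik)."""
    n = len(y)
    Xw = _ar1_whiten(X, rho) if rho else X.astype(float)
    yw = _ar1_whiten(y[:, None], rho)[:, 0] if rho else y.astype(float)
    XtX = Xw.T @ Xw
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss_w = float(resid @ resid)
    # profile ML log-likelihood (sigma^2 concentrated out); the 1/2 log(1-rho^2)
    # term is the Jacobian of the whitening transform
    if rss_w <= 0:
        loglik = math.inf
    else:
        loglik = -0.5 * n * (math.log(2 * math.pi * rss_w / n) + 1.0)
        if rho:
            loglik += 0.5 * math.log(1.0 - rho * rho)
    return beta, rss_w, XtX_inv, loglik


def _ml_fit(X: np.ndarray, y: np.ndarray, correlation: str):
    """ML fit with iid or AR(1) errors; returns (beta, rss_w, XtX_inv, loglik, rho)."""
    if correlation == "none":
        return (*_fit_given_rho(X, y, 0.0), None)
    if correlation != "ar1":
        raise ValidationError(f"unknown correlation structure {correlation!r}")
    res = optimize.minimize_scalar(
        lambda r: -_fit_given_rho(X, y, r)[3],
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    return (*_fit_given_rho(X, y, rho), rho)


def fit_gls(
    x: Sequence[float],
    y: Sequence[float],
    correlation: str = "none",
    log_transform: bool | str = False,
    comparison_id: str = "",
) -> RegressionResult:
    """Fit y = a + b*x by ML with iid or AR(1) errors.

    With ``log_transform=True`` both variables are logged (base 10) after
    pairwise deletion of non-positive values (warned); ``"x"`` or ``"y"``
    log only one side (used when the other is already on a log scale).  For
    AR(1) the input order is the temporal order.  Raises on fewer than 3
    usable points or a constant predictor.
    """
    log_mode = _normalize_log_mode(log_transform)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if log_mode in ("x", "both"):
        keep &= x > 0
    if log_mode in ("y", "both"):
        keep &= y > 0
    n_dropped = int(len(x) - keep.sum())
    if n_dropped and log_mode != "none":
        warnings.warn(
            f"{comparison_id or 'fit_gls'}: dropped {n_dropped} pair(s) with "
            "non-positive or missing values before log transform",
            stacklevel=2,
        )
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValidationError(f"{comparison_id or 'fit_gls'}: need >= 3 usable points, have {n}")
    if log_mode in ("x", "both"):
        x = np.log10(x)
    if log_mode in ("y", "both"):
        y = np.log10(y)
    if np.ptp(x) == 0:
        raise ValidationError(f"{comparison_id or 'fit_gls'}: predictor has zero variance")

    X = np.column_stack([np.ones(n), x])
    beta, rss_w, XtX_inv, ll_model, rho = _ml_fit(X, y, correlation)
    X0 = np.ones((n, 1))
    *_, ll_null, _rho0 = _ml_fit(X0, y, correlation)

    s2 = rss_w / (n - 2)  # n-2 denominator so iid case matches textbook OLS t
    se_slope = math.sqrt(s2 * XtX_inv[1, 1])
    slope = float(beta[1])
    if se_slope == 0.0:
        t_value, p_value = 0.0, 1.0
    else:
        t_value = slope / se_slope
        p_value = 2.0 * stats.t.sf(abs(t_value), df=n - 2)
    return RegressionResult(
        comparison_id=comparison_id,
        slope=slope,
        intercept=float(beta[0]),
        t_value=t_value,
        p_value=float(p_value),
        pseudo_r2=pseudo_r2(ll_model, ll_null, n),
        n=n,
        correlation=correlation,
        rho=rho,
        log_transformed=log_mode != "none",
        n_dropped=n_dropped,
        loglik_model=ll_model,
        loglik_null=ll_null,
    )


def pseudo_r2(
    loglik_model: float, loglik_null: float, n: int, adjusted: bool = False
) -> float:
    """Likelihood-ratio pseudo-R^2: 1 - exp(-(2/n) * (ll_model - ll_null)).

    ``adjusted=True`` divides by the maximum attainable value
    1 - exp((2/n) * loglik_null) (Nagelkerke-style rescaling).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    delta = loglik_model - loglik_null
    if delta < 0:
        warnings.warn(
            "model log-likelihood below the nested null (numerical); "
            "pseudo-R^2 reported as computed",
            stacklevel=2,
        )
    value = 1.0 - math.exp(-(2.0 / n) * delta)
    if adjusted:
        value /= 1.0 - math.exp((2.0 / n) * loglik_null)
    return value


def run_comparisons(
    tables: Mapping[str, pd.DataFrame],
    specs: Iterable[ComparisonSpec],
) -> tuple[list[RegressionResult], dict[str, str]]:
    """Run a batch of comparisons against named proxy tables.

    Each table holds one row per unit (species / bin), already in temporal
    order where AR(1) is requested.  A failing comparison (missing column,
    too few points) is recorded in the returned error map; the others
    proceed.
    """
    results: list[RegressionResult] = []
    errors: dict[str, str] = {}
    for spec in specs:
        try:
            table = tables[spec.table]
            for col in (spec.response, spec.predictor):
                if col not in table.columns:
                    raise ValidationError(f"table {spec.table!r} lacks column {col!r}")
            results.append(
                fit_gls(
                    table[spec.predictor].to_numpy(dtype=float),
                    table[spec.response].to_numpy(dtype=float),
                    correlation=spec.correlation,
                    log_transform=spec.log_transform,
                    comparison_id=spec.comparison_id,
                )
            )
        except (ValidationError, KeyError) as exc:
            errors[spec.comparison_id] = str(exc)
    return results, errors


def results_table(results: Iterable[RegressionResult]) -> pd.DataFrame:
    """Results frame mirroring the published comparison-table layout."""
    rows = [
        {
            "comparison": r.comparison_id,
            "slope": r.slope,
            "t_value": r.t_value,
            "r2": r.pseudo_r2,
            "p_value": r.p_value,
            "n": r.n,
            "correlation": r.correlation,
            "rho": r.rho if r.rho is not None else "",
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["comparison", "slope", "t_value", "r2", "p_value", "n", "correlation", "rho"]
    )
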