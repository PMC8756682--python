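"""OLS, spatial-lag and spatial-error regression with AIC model ranking.

The spatial-lag model (SLM) is  y = delta * W y + X beta + eps ; the
spatial-error model (SEM) keeps the mean linear but lets the disturbance
follow a spatial autoregression, u = lambda * W u + eps.  Both are fitted
by maximum likelihood through the concentrated log-likelihood in the single
spatial parameter: for each candidate value the regression coefficients and
the error variance are profiled out in closed form and the log-Jacobian
log|I - rho*W| is evaluated from the (cached) eigenvalues of W as
sum_i log(1 - rho * omega_i).  The spatial parameter is searched on the
admissible interval (1/omega_min, 1/omega_max), shrunk by 1e-5 at each end,
with a bounded scalar optimizer at tolerance 1e-8.

AIC = 2k - 2 logL with k counting the regression coefficients (incl.
intercept) plus one for the error variance, plus one more for delta/lambda
in the spatial models; the same convention across models keeps rankings
meaningful.  OLS reports the classical adjusted R-squared; for the ML
spatial fits a true adjusted R-squared does not exist, so the squared
Pearson correlation of fitted vs observed is reported, labelled pseudo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .errors import (CollinearityError, ConvergenceError, DegenerateInputError,
                     FormatError)
from .geo_io import AttributeTable
from .weights import WeightMatrix

__all__ = ["DesignMatrix", "Coefficient", "RegressionResult", "fit_ols",
           "fit_spatial_lag", "fit_spatial_error", "compare_models",
           "slm_concentrated_loglik", "sem_concentrated_loglik"]

_BOUND_SHRINK = 1e-5
_XTOL = 1e-8
_MODEL_SIMPLICITY = {"ols": 0, "slm": 1, "sem": 2}


@dataclass
class Coefficient:
    estimate: float
    se: float
    p_value: float


@dataclass
class RegressionResult:
    model_kind: str                    # "ols" | "slm" | "sem"
    outcome_name: str
    coefficients: dict[str, Coefficient]
    spatial_parameter: Optional[tuple[str, Coefficient]]  # ("delta"/"lambda", ...)
    sigma2: float
    log_likelihood: float
    aic: float
    r2_kind: str                       # "adjusted_r2" | "pseudo_r2"
    r2: float
    n: int
    k: int
    residuals: np.ndarray
    fitted: np.ndarray


@dataclass
class DesignMatrix:
    """Outcome vector and predictor matrix with a leading intercept column."""

    outcome_name: str
    predictor_names: list[str]         # excludes the intercept
    y: np.ndarray
    X: np.ndarray                      # n x (p+1), first column ones

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, ncol = self.X.shape
        if ncol != len(self.predictor_names) + 1:
            raise FormatError("X must have an intercept plus one column "
                              "per predictor")
        if self.y.shape != (n,):
            raise FormatError("y length does not match X")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X))):
            raise DegenerateInputError("design contains non-finite values")
        if n <= ncol + 2:
            raise DegenerateInputError(
                f"n = {n} too small for {ncol} columns (need n > columns + 2)"
            )
        rank = np.linalg.matrix_rank(self.X)
        if rank < ncol:
            raise CollinearityError(
                "design matrix is rank deficient; dependent columns: "
                f"{self._dependent_columns()}",
                columns=self._dependent_columns(),
            )

    def _dependent_columns(self) -> list[str]:
        names = ["intercept"] + self.predictor_names
        dependent = []
        for j in range(1, self.X.shape[1]):
            others = np.delete(self.X, j, axis=1)
            col = self.X[:, j]
            resid = col - others @ np.linalg.lstsq(others, col, rcond=None)[0]
            if np.linalg.norm(resid) <= 1e-8 * max(1.0, np.linalg.norm(col)):
                dependent.append(names[j])
        return dependent

    @classmethod
    def from_table(cls, table: AttributeTable, outcome: str,
                   predictors: list[str]) -> "DesignMatrix":
        y = table.variable(outcome)
        cols = [np.ones(len(y))] + [table.variable(p) for p in predictors]
        return cls(outcome_name=outcome, predictor_names=list(predictors),
                   y=y, X=np.column_stack(cols))

    @property
    def column_names(self) -> list[str]:
        return ["intercept"] + self.predictor_names


def _gaussian_loglik(n: int, rss: float) -> float:
    sigma2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)


def _coef_table(names, estimates, ses, dist) -> dict[str, Coefficient]:
    out = {}
    for name, b, s in zip(names, estimates, ses):
        z = b / s if s > 0 else np.inf * np.sign(b)
        out[name] = Coefficient(float(b), float(s), float(2 * dist(abs(z))))
    return out


def _check_residual_variance(sigma2: float, y: np.ndarray, model: str) -> None:
    # a (numerically) perfect fit makes the Gaussian ML likelihood unbounded
    # and every variance-based quantity meaningless
    if sigma2 <= 1e-12 * max(1.0, float(np.var(y))):
        raise DegenerateInputError(
            f"{model}: residual variance is numerically zero — the outcome "
            "is an exact linear combination of the predictors"
        )


def fit_ols(design: DesignMatrix) -> RegressionResult:
    """Ordinary least squares with classical standard errors."""
    X, y = design.X, design.y
    n, ncol = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - ncol
    cov = rss / df * np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.diag(cov))
    tdist = scipy.stats.t(df)
    coefs = _coef_table(design.column_names, beta, ses, tdist.sf)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    loglik = _gaussian_loglik(n, rss)
    k = ncol + 1  # + 1 for the error variance
    return RegressionResult(
        model_kind="ols", outcome_name=design.outcome_name, coefficients=coefs,
        spatial_parameter=None, sigma2=rss / n, log_likelihood=loglik,
        aic=2 * k - 2 * loglik, r2_kind="adjusted_r2", r2=adj_r2, n=n, k=k,
        residuals=resid, fitted=fitted,
    )


# ---------------------------------------------------------------------------
# spatial maximum likelihood
# ---------------------------------------------------------------------------


def _search_interval(weights: WeightMatrix) -> tuple[float, float, np.ndarray]:
    evals = weights.eigenvalues()
    lo, hi = weights.spatial_parameter_interval()
    if not np.isfinite(lo):
        lo = -1.0 / max(abs(float(evals[-1])), 1e-12)  # conservative fallback
    return lo + _BOUND_SHRINK, hi - _BOUND_SHRINK, evals


def _check_spatial_inputs(weights: WeightMatrix, design: DesignMatrix) -> None:
    if weights.style != "row_standardized":
        raise FormatError("spatial models require row-standardized weights")
    if weights.n != len(design.y):
        raise FormatError("weights and design have different n")


def _maximize_concentrated(neg_ll, lo: float, hi: float, label: str) -> float:
    res = scipy.optimize.minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": _XTOL},
    )
    rho = float(res.x)
    if not res.success:
        raise ConvergenceError(f"{label} scalar optimization failed: {res}")
    if min(rho - lo, hi - rho) < 1e-6:
        # optimum pinned to the admissible boundary: not an interior MLE
        raise ConvergenceError(
            f"{label} optimizer hit the admissible-interval boundary "
            f"at {rho:.6f} (interval [{lo:.6f}, {hi:.6f}])"
        )
    return rho


def _numeric_hessian(fun, theta: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    m = len(theta)
    hess = np.empty((m, m))
    for a in range(m):
        for b in range(a, m):
            ea = np.zeros(m); ea[a] = steps[a]
            eb = np.zeros(m); eb[b] = steps[b]
            if a == b:
                val = (fun(theta + ea) - 2 * fun(theta) + fun(theta - ea)) \
                    / steps[a] ** 2
            else:
                val = (fun(theta + ea + eb) - fun(theta + ea - eb)
                       - fun(theta - ea + eb) + fun(theta - ea - eb)) \
                    / (4 * steps[a] * steps[b])
            hess[a, b] = hess[b, a] = val
    return hess


def _ml_standard_errors(full_loglik, rho_hat, beta_hat, sigma2_hat):
    theta = np.concatenate([[rho_hat], beta_hat, [sigma2_hat]])
    steps = 1e-5 * (1.0 + np.abs(theta))
    # keep the variance coordinate positive at every probe point
    steps[-1] = min(steps[-1], sigma2_hat / 4.0)

    def neg(th):
        return -full_loglik(th[0], th[1:-1], th[-1])

    hess = _numeric_hessian(neg, theta, steps)
    try:
        cov = np.linalg.inv(hess)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(len(theta), np.nan)
    return ses[0], ses[1:-1]


def fit_spatial_lag(weights: WeightMatrix, design: DesignMatrix
                    ) -> RegressionResult:
    """ML fit of the spatial-lag model y = delta*Wy + X beta + eps."""
    _check_spatial_inputs(weights, design)
    X, y = design.X, design.y
    n, ncol = X.shape
    lo, hi, evals = _search_interval(weights)
    Wy = weights.matrix @ y

    b0, *_ = np.linalg.lstsq(X, y, rcond=None)
    bL, *_ = np.linalg.lstsq(X, Wy, rcond=None)
    e0 = y - X @ b0
    eL = Wy - X @ bL

    def concentrated(delta: float) -> float:
        e = e0 - delta * eL
        sigma2 = (e @ e) / n
        logdet = float(np.sum(np.log(1.0 - delta * evals)))
        return -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet

    delta = _maximize_concentrated(lambda d: -concentrated(d), lo, hi, "SLM")
    beta = b0 - delta * bL
    innov = e0 - delta * eL
    sigma2 = float(innov @ innov) / n
    _check_residual_variance(sigma2, y, "SLM")
    loglik = concentrated(delta)

    def full_loglik(d, b, s2):
        e = y - d * Wy - X @ b
        logdet = float(np.sum(np.log(1.0 - d * evals)))
        return (-0.5 * n * np.log(2 * np.pi * s2) + logdet
                - (e @ e) / (2 * s2))

    se_delta, se_beta = _ml_standard_errors(full_loglik, delta, beta, sigma2)
    norm_sf = scipy.stats.norm.sf
    coefs = _coef_table(design.column_names, beta, se_beta, norm_sf)
    sp_z = delta / se_delta if se_delta > 0 else np.inf
    spatial = ("delta", Coefficient(delta, float(se_delta),
                                    float(2 * norm_sf(abs(sp_z)))))
    fitted = delta * Wy + X @ beta
    r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    k = ncol + 2
    return RegressionResult(
        model_kind="slm", outcome_name=design.outcome_name, coefficients=coefs,
        spatial_parameter=spatial, sigma2=sigma2, log_likelihood=loglik,
        aic=2 * k - 2 * loglik, r2_kind="pseudo_r2", r2=r2, n=n, k=k,
        residuals=innov, fitted=fitted,
    )


def fit_spatial_error(weights: WeightMatrix, design: DesignMatrix
                      ) -> RegressionResult:
    """ML fit of the spatial-error model y = X beta + u, u = lambda*Wu + eps."""
    _check_spatial_inputs(weights, design)
    X, y = design.X, design.y
    n, ncol = X.shape
    lo, hi, evals = _search_interval(weights)
    Wy = weights.matrix @ y
    WX = weights.matrix @ X

    def profile(lam: float):
        ys = y - lam * Wy
        Xs = X - lam * WX
        b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ b
        return b, float(e @ e) / n

    def concentrated(lam: float) -> float:
        _, sigma2 = profile(lam)
        logdet = float(np.sum(np.log(1.0 - lam * evals)))
        return -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet

    lam = _maximize_concentrated(lambda L: -concentrated(L), lo, hi, "SEM")
    beta, sigma2 = profile(lam)
    _check_residual_variance(sigma2, y, "SEM")
    loglik = concentrated(lam)

    def full_loglik(L, b, s2):
        u = y - X @ b
        e = u - L * (weights.matrix @ u)
        logdet = float(np.sum(np.log(1.0 - L * evals)))
        return (-0.5 * n * np.log(2 * np.pi * s2) + logdet
                - (e @ e) / (2 * s2))

    se_lam, se_beta = _ml_standard_errors(full_loglik, lam, beta, sigma2)
    norm_sf = scipy.stats.norm.sf
    coefs = _coef_table(design.column_names, beta, se_beta, norm_sf)
    sp_z = lam / se_lam if se_lam > 0 else np.inf
    spatial = ("lambda", Coefficient(lam, float(se_lam),
                                     float(2 * norm_sf(abs(sp_z)))))
    fitted = X @ beta
    resid = y - fitted
    r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    k = ncol + 2
    return RegressionResult(
        model_kind="sem", outcome_name=design.outcome_name, coefficients=coefs,
        spatial_parameter=spatial, sigma2=sigma2, log_likelihood=loglik,
        aic=2 * k - 2 * loglik, r2_kind="pseudo_r2", r2=r2, n=n, k=k,
        residuals=resid, fitted=fitted,
    )


def slm_concentrated_loglik(weights: WeightMatrix, design: DesignMatrix,
                            delta: float) -> float:
    """Concentrated SLM log-likelihood at a given delta (beta, sigma2
    profiled out).  At delta = 0 this equals the OLS Gaussian
    log-likelihood."""
    _check_spatial_inputs(weights, design)
    X, y = design.X, design.y
    n = len(y)
    evals = weights.eigenvalues()
    Wy = weights.matrix @ y
    ys = y - delta * Wy
    b, *_ = np.linalg.lstsq(X, ys, rcond=None)
    e = ys - X @ b
    sigma2 = (e @ e) / n
    logdet = float(np.sum(np.log(1.0 - delta * evals)))
    return -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet


def sem_concentrated_loglik(weights: WeightMatrix, design: DesignMatrix,
                            lam: float) -> float:
    """Concentrated SEM log-likelihood at a given lambda (beta, sigma2
    profiled out)."""
    _check_spatial_inputs(weights, design)
    X, y = design.X, design.y
    n = len(y)
    evals = weights.eigenvalues()
    ys = y - lam * (weights.matrix @ y)
    Xs = X - lam * (weights.matrix @ X)
    b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    e = ys - Xs @ b
    sigma2 = (e @ e) / n
    logdet = float(np.sum(np.log(1.0 - lam * evals)))
    return -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet


def compare_models(results: list[RegressionResult]) -> pd.DataFrame:
    """Rank fitted models by ascending AIC (ties: higher R2, then simpler).

    The models must have been fitted on the same data (same n, same
    outcome).  Returns one row per model, best first.
    """
    if len(results) < 2:
        raise FormatError("compare_models needs at least 2 results")
    n0, outcome0 = results[0].n, results[0].outcome_name
    for res in results[1:]:
        if res.n != n0:
            raise FormatError(f"mismatched n: {res.n} vs {n0}")
        if res.outcome_name != outcome0:
            raise FormatError(
                f"mismatched outcome: {res.outcome_name!r} vs {outcome0!r}"
            )
    rows = []
    for res in results:
        sp_name, sp_val = ("", np.nan)
        if res.spatial_parameter is not None:
            sp_name = res.spatial_parameter[0]
            sp_val = res.spatial_parameter[1].estimate
        rows.append({
            "model": res.model_kind,
            "aic": res.aic,
            "log_likelihood": res.log_likelihood,
            "r2_kind": res.r2_kind,
            "r2": res.r2,
            "spatial_parameter": sp_name,
            "spatial_value": sp_val,
            "k": res.k,
            "n": res.n,
        })
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(results)),
        key=lambda i: (rows[i]["aic"], -rows[i]["r2"],
                       _MODEL_SIMPLICITY.get(rows[i]["model"], 99)),
    )
    return table.iloc[order].reset_index(drop=True)
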