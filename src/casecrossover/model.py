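"""Fixed-effects conditional quasi-Poisson regression.

Daily death counts within each year x month x day-of-week stratum are
modelled as Poisson conditional on the stratum total, which is equivalent to
an unconditional Poisson regression with one free intercept per stratum.
Rather than materializing hundreds of stratum indicator columns, the
stratum intercepts are profiled out analytically: given the non-stratum
coefficients beta, the intercept MLE makes each stratum's fitted total equal
its observed total, and Newton steps on the concentrated likelihood use the
within-stratum (mu-weighted) centered design.  The resulting point estimates
and beta-block covariance are numerically identical to the dummy-variable
formulation.

Overdispersion is handled quasi-likelihood style: the model covariance is
scaled by the Pearson dispersion phi = X^2 / (n - rank), leaving point
estimates untouched and widening Wald intervals by sqrt(phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .strata import StratumAssignment

__all__ = [
    "FitResult",
    "RREstimate",
    "ConvergenceError",
    "CollinearityError",
    "fit",
    "dispersion_estimate",
    "rr_from_fit",
]

Z_975 = 1.959964  # two-sided 95% normal quantile


class ConvergenceError(RuntimeError):
    """Newton iterations did not converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class CollinearityError(ValueError):
    """Design is rank-deficient after within-stratum centering."""

    def __init__(self, message: str, columns: list[int]):
        super().__init__(message)
        self.columns = columns


@dataclass(frozen=True)
class FitResult:
    """Conditional quasi-Poisson fit.

    ``beta``/``cov`` cover the non-stratum columns only (stratum intercepts
    are absorbed); ``cov`` is already scaled by the Pearson dispersion.
    ``column_meta`` maps each exposure column position to its lag index.
    """

    beta: np.ndarray
    cov: np.ndarray
    dispersion: float
    n_obs: int
    n_strata: int
    converged: bool
    iterations: int
    deviance: float
    column_meta: dict[int, int] = field(default_factory=dict)
    column_names: tuple[str, ...] = ()
    absorbed_columns: tuple[int, ...] = ()
    stratum_effects: dict[int, float] | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def column_for_lag(self, lag: int) -> int:
        for col, l in self.column_meta.items():
            if l == lag:
                return col
        raise KeyError(f"no exposure column for lag {lag}")


@dataclass(frozen=True)
class RREstimate:
    """Relative risk per exposure increment, with 95% Wald CI on the log scale."""

    lag: int
    rr: float
    lo: float
    hi: float
    increment: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.rr <= self.hi):
            raise ValueError("CI bounds must bracket the point estimate")


def _stratum_codes(strata) -> np.ndarray:
    if isinstance(strata, StratumAssignment):
        return strata.codes
    return np.asarray(strata, dtype=np.int64)


def _absorbed(X: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Columns constant within every stratum (absorbed by the intercepts)."""
    n_strata = codes.max() + 1
    hi = np.full((n_strata, X.shape[1]), -np.inf)
    lo = np.full((n_strata, X.shape[1]), np.inf)
    np.maximum.at(hi, codes, X)
    np.minimum.at(lo, codes, X)
    span = np.nanmax(np.abs(X), axis=0) + 1.0
    return ((hi - lo) < 1e-12 * span).all(axis=0)


def _profiled_mu(eta_x, codes, y_tot, n_strata):
    """Fitted means with stratum intercepts at their conditional MLE.

    Shift-invariant in eta, computed with a per-stratum max subtraction so
    large linear predictors cannot overflow.
    """
    shift = np.full(n_strata, -np.inf)
    np.maximum.at(shift, codes, eta_x)
    ex = np.exp(eta_x - shift[codes])
    denom = np.bincount(codes, weights=ex, minlength=n_strata)
    return ex * (y_tot / denom)[codes]


def fit(
    deaths,
    X,
    strata,
    *,
    column_meta: dict[int, int] | None = None,
    column_names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    drop_absorbed: bool = False,
    report_stratum_effects: bool = False,
) -> FitResult:
    """Fit the conditional quasi-Poisson model.

    Parameters
    ----------
    deaths:
        Daily counts (rows already restricted to complete cases).
    X:
        Design block: exposure columns followed by confounder columns.
        No intercept — it is absorbed by the stratum effects.
    strata:
        :class:`~casecrossover.strata.StratumAssignment` or integer codes,
        aligned with ``deaths``.
    drop_absorbed:
        If True, columns constant within every stratum (hence inestimable)
        are dropped and recorded instead of raising.

    Notes
    -----
    Strata whose total count is zero contribute nothing to the conditional
    likelihood and are excluded from ``n_obs``/``n_strata`` bookkeeping.
    """
    y = np.asarray(deaths, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("deaths and design have different lengths")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("NaN/inf in fit inputs: drop incomplete rows first")
    codes_full = _stratum_codes(strata)
    if len(codes_full) != len(y):
        raise ValueError("stratum labels and deaths have different lengths")

    # drop non-informative zero-total strata
    totals = np.bincount(codes_full, weights=y)
    keep = totals[codes_full] > 0
    y, X, codes = y[keep], X[keep], codes_full[keep]
    if y.size == 0:
        raise ValueError("no informative strata (all stratum totals are zero)")
    codes = np.unique(codes, return_inverse=True)[1]
    n_strata = int(codes.max()) + 1
    n_obs = len(y)

    # columns absorbed by the stratum intercepts are inestimable
    absorbed_mask = _absorbed(X, codes)
    absorbed = tuple(int(j) for j in np.flatnonzero(absorbed_mask))
    if absorbed and not drop_absorbed:
        names = _names(absorbed, column_names)
        raise CollinearityError(
            f"columns constant within every stratum (absorbed): {names}", list(absorbed)
        )
    keep_cols = np.flatnonzero(~absorbed_mask)
    Xk = X[:, keep_cols]
    p = Xk.shape[1]
    if p == 0:
        raise ValueError("no estimable columns remain")

    # standardize for conditioning; transform estimates back at the end
    scale = Xk.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (Xk - Xk.mean(axis=0)) / scale

    y_tot = np.bincount(codes, weights=y, minlength=n_strata)
    w_pos = y > 0

    def deviance(mu):
        return 2.0 * float(np.sum(y[w_pos] * np.log(y[w_pos] / mu[w_pos])))

    beta = np.zeros(p)
    eta = Xs @ beta
    mu = _profiled_mu(eta, codes, y_tot, n_strata)
    dev = deviance(mu)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Newton step on the concentrated likelihood
        w_sum = np.bincount(codes, weights=mu, minlength=n_strata)
        Xc = Xs - (_stratum_mean(Xs, mu, codes, w_sum))[codes]
        H = (Xc * mu[:, None]).T @ Xc
        score = Xs.T @ (y - mu)
        try:
            step = scipy.linalg.solve(H, score, assume_a="pos")
        except scipy.linalg.LinAlgError:
            bad = _collinear_columns(Xc * np.sqrt(mu)[:, None])
            names = _names([keep_cols[j] for j in bad], column_names)
            raise CollinearityError(
                f"rank-deficient design after within-stratum centering: {names}",
                [int(keep_cols[j]) for j in bad],
            ) from None

        # step-halving safeguard
        new_beta = beta + step
        for _ in range(30):
            eta = Xs @ new_beta
            mu_new = _profiled_mu(eta, codes, y_tot, n_strata)
            dev_new = deviance(mu_new)
            if np.isfinite(dev_new) and dev_new <= dev + 1e-12 * (abs(dev) + 1.0):
                break
            step *= 0.5
            new_beta = beta + step
        beta, mu = new_beta, mu_new
        trace.append(dev_new)
        if abs(dev - dev_new) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new

    if not converged:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(last deviance change {abs(trace[-2] - trace[-1]):.3e})",
            trace,
        )

    # information and dispersion at the optimum
    w_sum = np.bincount(codes, weights=mu, minlength=n_strata)
    Xc = Xs - (_stratum_mean(Xs, mu, codes, w_sum))[codes]
    H = (Xc * mu[:, None]).T @ Xc
    rank = p + n_strata
    phi = dispersion_estimate(y, mu, rank)
    cov_s = phi * scipy.linalg.inv(H)

    # undo standardization
    beta_out = np.zeros(X.shape[1])
    beta_out[keep_cols] = beta / scale
    cov_out = np.zeros((X.shape[1], X.shape[1]))
    d = 1.0 / scale
    cov_out[np.ix_(keep_cols, keep_cols)] = cov_s * np.outer(d, d)

    stratum_effects = None
    if report_stratum_effects:
        eta_x = X[:, keep_cols] @ (beta / scale)
        shift = np.full(n_strata, -np.inf)
        np.maximum.at(shift, codes, eta_x)
        denom = np.bincount(codes, weights=np.exp(eta_x - shift[codes]), minlength=n_strata)
        stratum_effects = {
            int(s): float(np.log(y_tot[s] / denom[s]) - shift[s]) for s in range(n_strata)
        }

    return FitResult(
        beta=beta_out,
        cov=cov_out,
        dispersion=phi,
        n_obs=n_obs,
        n_strata=n_strata,
        converged=converged,
        iterations=it,
        deviance=dev,
        column_meta=dict(column_meta or {}),
        column_names=tuple(column_names or ()),
        absorbed_columns=absorbed,
        stratum_effects=stratum_effects,
    )


def _stratum_mean(Xs, mu, codes, w_sum):
    num = np.zeros((len(w_sum), Xs.shape[1]))
    np.add.at(num, codes, Xs * mu[:, None])
    return num / w_sum[:, None]


def _collinear_columns(A: np.ndarray) -> list[int]:
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    cut = diag[0] * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    return sorted(int(piv[j]) for j in range(len(diag)) if diag[j] <= cut)


def _names(cols, column_names) -> str:
    if column_names:
        return ", ".join(str(column_names[j]) for j in cols)
    return ", ".join(str(j) for j in cols)


def dispersion_estimate(deaths, fitted_means, rank: int) -> float:
    """Pearson dispersion: sum((y - mu)^2 / mu) / (n - rank)."""
    y = np.asarray(deaths, dtype=float)
    mu = np.asarray(fitted_means, dtype=float)
    if (mu <= 0).any():
        raise ValueError("fitted means must be positive")
    if len(y) <= rank:
        raise ValueError(f"no residual degrees of freedom: n={len(y)}, rank={rank}")
    pearson = float(np.sum((y - mu) ** 2 / mu))
    return pearson / (len(y) - rank)


def rr_from_fit(fit_result: FitResult, lag: int, increment: float = 10.0) -> RREstimate:
    """Relative risk per ``increment`` exposure units at the given lag.

    RR = exp(beta_l * increment); the 95% CI is Wald on the log scale with
    the dispersion-scaled standard error.
    """
    col = fit_result.column_for_lag(lag)
    b = fit_result.beta[col]
    se = np.sqrt(fit_result.cov[col, col])
    return RREstimate(
        lag=lag,
        rr=float(np.exp(b * increment)),
        lo=float(np.exp((b - Z_975 * se) * increment)),
        hi=float(np.exp((b + Z_975 * se) * increment)),
        increment=float(increment),
        n_obs=fit_result.n_obs,
    )
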