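"""Weibull and generalized-gamma models for the methylation noise background.

The three-parameter Weibull CDF

    F(x) = 1 - exp(-((x - mu)/lambda)**alpha),  x > mu

and its generalized-gamma extension (extra shape ``psi``; Weibull is the
``psi = 1`` member) are fitted by nonlinear least squares of the model CDF
against the empirical CDF of observed information/divergence values.  Model
comparison uses least-squares AIC/BIC and Stein's adjusted R-squared as a
cross-validation proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "WeibullParams",
    "GGParams",
    "FitResult",
    "weibull_cdf",
    "gg_cdf",
    "weibull_rvs",
    "fit_cdf",
    "stein_r2",
    "select_model",
    "aic_least_squares",
    "bic_least_squares",
]

MIN_FIT_POINTS = 20
DEFAULT_VALUE_FLOOR = 1e-8  # bits; near-zero values distort sub-2kb fits
DEFAULT_LAMBDA_PLAUSIBLE = (1e-6, 1e6)


@dataclass(frozen=True)
class WeibullParams:
    """Shape ``alpha``, scale ``lambda_scale`` and location ``mu`` (>= 0)."""

    alpha: float
    lambda_scale: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("Weibull shape alpha must be positive")
        if self.lambda_scale <= 0:
            raise ValueError("scale must be positive")
        if self.mu < 0:
            raise ValueError("location mu must be non-negative")

    @property
    def k(self) -> int:
        return 3

    def as_tuple(self) -> tuple[float, ...]:
        return (self.alpha, self.lambda_scale, self.mu)


@dataclass(frozen=True)
class GGParams:
    """Generalized-gamma parameters: shapes ``alpha`` (sign selects the CDF
    branch) and ``psi``, scale ``lambda_scale``, location ``mu``."""

    alpha: float
    lambda_scale: float
    mu: float = 0.0
    psi: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha == 0:
            raise ValueError("GG shape alpha must be nonzero")
        if self.lambda_scale <= 0:
            raise ValueError("scale must be positive")
        if self.mu < 0:
            raise ValueError("location mu must be non-negative")
        if self.psi <= 0:
            raise ValueError("shape psi must be positive")

    @property
    def k(self) -> int:
        return 4

    def as_tuple(self) -> tuple[float, ...]:
        return (self.alpha, self.lambda_scale, self.mu, self.psi)


def weibull_cdf(x, params: WeibullParams) -> np.ndarray | float:
    """Three-parameter Weibull CDF; 0 for x <= mu."""
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    z = np.clip((arr - params.mu) / params.lambda_scale, 0.0, None)
    out = -np.expm1(-(z ** params.alpha))
    return float(out[0]) if scalar else out


def gg_cdf(x, params: GGParams) -> np.ndarray | float:
    """Generalized-gamma CDF via the regularized lower incomplete gamma.

    For ``alpha > 0``: ``P(psi, ((x - mu)/lambda)**alpha)``; for
    ``alpha < 0`` the complementary branch ``1 - P(...)`` (the transform is
    decreasing, so the complement restores a proper CDF).  Reduces exactly to
    the Weibull CDF at ``psi = 1``.
    """
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    rel = (arr - params.mu) / params.lambda_scale
    out = np.zeros_like(arr)
    pos = rel > 0
    if params.alpha > 0:
        out[pos] = special.gammainc(params.psi, rel[pos] ** params.alpha)
    else:
        out[pos] = 1.0 - special.gammainc(params.psi, rel[pos] ** params.alpha)
        out[~pos] = 0.0
    return float(out[0]) if scalar else out


def weibull_rvs(
    params: WeibullParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw Weibull variates with location; inverse-transform sampling."""
    u = rng.random(size)
    return params.mu + params.lambda_scale * (-np.log1p(-u)) ** (1.0 / params.alpha)


@dataclass
class FitResult:
    """Outcome of a least-squares CDF fit with goodness-of-fit metrics."""

    model: str
    params: WeibullParams | GGParams
    n_points: int
    rss: float
    r2: float
    r2_adj_stein: float
    aic: float
    bic: float
    converged: bool
    kind: str | None = None  # divergence column the fit was made on
    region_length: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def lambda_scale(self) -> float:
        return self.params.lambda_scale

    def cdf(self, x):
        if self.model == "weibull":
            return weibull_cdf(x, self.params)
        return gg_cdf(x, self.params)


def stein_r2(r2: float, n: int, k: int) -> float:
    """Stein's adjusted R-squared, an average cross-validation estimate.

    ``1 - [(n-1)/(n-k-1)] [(n-2)/(n-k-2)] [(n+1)/n] (1 - r2)`` for ``n``
    observations and ``k`` free parameters.
    """
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (got n={n}, k={k})")
    factor = ((n - 1) / (n - k - 1)) * ((n - 2) / (n - k - 2)) * ((n + 1) / n)
    return 1.0 - factor * (1.0 - r2)


def aic_least_squares(n: int, rss: float, k: int) -> float:
    """AIC for a least-squares fit: ``n ln(RSS/n) + 2 (k + 1)``."""
    return n * math.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def bic_least_squares(n: int, rss: float, k: int) -> float:
    return n * math.log(max(rss, 1e-300) / n) + (k + 1) * math.log(n)


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Hazen plotting positions avoid the 0 and 1 endpoints that distort tails.
    x = np.sort(values)
    n = x.size
    return x, (np.arange(1, n + 1) - 0.5) / n


def _initial_params(x: np.ndarray, model: str) -> np.ndarray:
    mu0 = 0.9 * float(x.min())
    lam0 = max(float(np.median(x)) - mu0, 1e-6)
    if model == "weibull":
        return np.array([1.0, lam0, mu0])
    return np.array([1.0, lam0, mu0, 1.0])


def fit_cdf(
    values,
    model: str = "weibull",
    init: WeibullParams | GGParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    min_value: float = DEFAULT_VALUE_FLOOR,
    kind: str | None = None,
    region_length: float | None = None,
) -> FitResult:
    """Fit the model CDF to the empirical CDF of ``values`` by least squares.

    Non-finite values (e.g. infinite KL sentinels) and values below
    ``min_value`` are excluded before fitting.  Requires at least
    ``MIN_FIT_POINTS`` remaining values.  Non-convergence is reported in the
    result's ``converged`` flag, never as a silent success.

    Parameters are box-constrained: ``alpha > 0``, ``lambda > 0`` and
    ``0 <= mu < min(values)``.  Custom boxes may be supplied per parameter
    name via ``bounds``.
    """
    if model not in ("weibull", "gg"):
        raise ValueError(f"unknown model {model!r}")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    arr = arr[arr >= min_value]
    k = 3 if model == "weibull" else 4
    if arr.size < max(MIN_FIT_POINTS, k + 2):
        raise ValueError(
            f"need at least {max(MIN_FIT_POINTS, k + 2)} finite values above "
            f"the floor, got {arr.size}"
        )
    x, f_emp = _ecdf(arr)
    n = x.size
    tss = float(np.sum((f_emp - f_emp.mean()) ** 2))

    def make_result(theta, converged, flags=()):
        if model == "weibull":
            params = WeibullParams(*theta)
            resid = weibull_cdf(x, params) - f_emp
        else:
            params = GGParams(*theta)
            resid = gg_cdf(x, params) - f_emp
        rss = float(np.sum(resid**2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        return FitResult(
            model=model,
            params=params,
            n_points=n,
            rss=rss,
            r2=r2,
            r2_adj_stein=stein_r2(r2, n, k),
            aic=aic_least_squares(n, rss, k),
            bic=bic_least_squares(n, rss, k),
            converged=converged,
            kind=kind,
            region_length=region_length,
            flags=list(flags),
        )

    theta0 = _initial_params(x, model)
    if init is not None:
        theta0 = np.asarray(init.as_tuple(), dtype=float)

    xmin = float(x.min())
    mu_hi = max(xmin * (1 - 1e-9), 0.0) if xmin > 0 else 0.0
    lo = [1e-3, 1e-12, 0.0]
    hi = [1e3, 1e12, mu_hi if mu_hi > 0 else 1e-300]
    names = ["alpha", "lambda_scale", "mu"]
    if model == "gg":
        lo.append(1e-3)
        hi.append(1e3)
        names.append("psi")
    if bounds:
        for name, (a, b) in bounds.items():
            idx = names.index(name)
            lo[idx], hi[idx] = a, b
    theta0 = np.clip(theta0, lo, hi)

    if np.ptp(x) == 0:  # degenerate: all values equal, CDF is a step
        return make_result(theta0, converged=False, flags=["degenerate_input"])

    def residuals(theta):
        if model == "weibull":
            p = WeibullParams(*theta)
            return weibull_cdf(x, p) - f_emp
        p = GGParams(*theta)
        return gg_cdf(x, p) - f_emp

    try:
        sol = optimize.least_squares(
            residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-12,
            ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        converged = bool(sol.success) and np.all(np.isfinite(sol.x))
        theta = sol.x if converged else theta0
    except Exception:
        converged, theta = False, theta0
    return make_result(theta, converged=converged)


def select_model(
    fits: Sequence[FitResult],
    lambda_plausible: tuple[float, float] = DEFAULT_LAMBDA_PLAUSIBLE,
) -> list[FitResult]:
    """Rank converged fits by AIC and flag physically implausible scales.

    A fitted scale outside ``lambda_plausible`` (default [1e-6, 1e6] bits) is
    flagged ``implausible_lambda`` — the analogue of rejecting near-zero
    scale estimates that are meaningless as per-molecule energies.  Flagged
    fits sort after unflagged ones.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select among")
    lo, hi = lambda_plausible
    ranked = []
    for f in converged:
        if not (lo <= f.lambda_scale <= hi):
            if "implausible_lambda" not in f.flags:
                f = replace_flags(f, f.flags + ["implausible_lambda"])
        ranked.append(f)
    ranked.sort(key=lambda f: ("implausible_lambda" in f.flags, f.aic))
    return ranked


def replace_flags(fit: FitResult, flags: list[str]) -> FitResult:
    return FitResult(
        model=fit.model, params=fit.params, n_points=fit.n_points, rss=fit.rss,
        r2=fit.r2, r2_adj_stein=fit.r2_adj_stein, aic=fit.aic, bic=fit.bic,
        converged=fit.converged, kind=fit.kind,
        region_length=fit.region_length, flags=list(flags),
    )


def fit_to_row(fit: FitResult) -> dict:
    """Flatten a FitResult to a table row (for the fit-dist CLI output)."""
    row = {
        "model": fit.model,
        "kind": fit.kind,
        "region_length": fit.region_length,
        "alpha": fit.params.alpha,
        "lambda": fit.params.lambda_scale,
        "mu": fit.params.mu,
        "psi": getattr(fit.params, "psi", 1.0),
        "n_points": fit.n_points,
        "rss": fit.rss,
        "r2": fit.r2,
        "r2_adj_stein": fit.r2_adj_stein,
        "aic": fit.aic,
        "bic": fit.bic,
        "converged": fit.converged,
        "flags": ",".join(fit.flags),
    }
    return row
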