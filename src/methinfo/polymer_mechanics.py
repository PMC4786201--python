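"""Persistence-length estimation from the length trend of fitted scales.

The fitted scale parameter lambda(l) of the noise distribution grows with
region length l.  Two regression regimes are implemented:

* linear, for regions much longer than the persistence length:
  ``lambda(l) = a' + b' l`` with ``Lp = (1 - a' ln2) / (b' ln2)``;
* exponential, for short fragments behaving as a linear entropic spring:
  ``lambda(l) = a exp(d l)`` with ``Lp = 3 / (2 d)``.

Both require lengths in nanometres (0.34 nm per base pair / per cytosine
digit); running them on a bp-unit trend raises unless conversion is
requested, since a persistence length is only meaningful in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

from .dist_models import FitResult

__all__ = [
    "NM_PER_BP",
    "LambdaTrend",
    "PersistenceEstimate",
    "lambda_trend",
    "persistence_linear",
    "persistence_exponential",
]

NM_PER_BP = 0.34

LN2 = math.log(2.0)


@dataclass(frozen=True)
class LambdaTrend:
    """Mean fitted scale per region length, with dispersion bookkeeping."""

    lengths: np.ndarray          # distinct region lengths, ascending
    lam_mean: np.ndarray         # mean lambda-hat per length
    lam_sd: np.ndarray           # NaN where a single sample contributed
    n_samples: np.ndarray
    length_unit: str = "bp"      # {"bp", "nm"}

    def __post_init__(self) -> None:
        if self.length_unit not in ("bp", "nm"):
            raise ValueError(f"unknown length unit {self.length_unit!r}")
        if len(set(np.round(self.lengths, 12))) != len(self.lengths):
            raise ValueError("region lengths must be distinct")
        if (np.asarray(self.lengths) <= 0).any():
            raise ValueError("region lengths must be positive")
        if (np.asarray(self.lam_mean) <= 0).any():
            raise ValueError("mean scales must be positive")

    def __len__(self) -> int:
        return len(self.lengths)

    def to_nm(self) -> "LambdaTrend":
        if self.length_unit == "nm":
            return self
        return replace(
            self, lengths=np.asarray(self.lengths, dtype=float) * NM_PER_BP,
            length_unit="nm",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "l": self.lengths,
                "lambda_mean": self.lam_mean,
                "lambda_sd": self.lam_sd,
                "n_samples": self.n_samples,
                "length_unit": self.length_unit,
            }
        )


def lambda_trend(
    fits: Iterable[FitResult] | pd.DataFrame,
    length_unit: str = "bp",
    require_converged: bool = True,
) -> LambdaTrend:
    """Aggregate per-(sample, length) scale estimates into a length trend.

    Accepts either FitResult objects carrying ``region_length`` or a frame
    with columns ``l`` and ``lambda``.  Non-converged or implausibility-
    flagged fits are excluded (the paper's physical-plausibility screen).
    At least two distinct lengths are required.
    """
    if isinstance(fits, pd.DataFrame):
        df = fits.rename(columns={"lambda": "lam"})[["l", "lam"]].copy()
    else:
        rows = []
        for f in fits:
            if f.region_length is None:
                raise ValueError("FitResult lacks region_length")
            if require_converged and (
                not f.converged or "implausible_lambda" in f.flags
            ):
                continue
            rows.append({"l": f.region_length, "lam": f.lambda_scale})
        df = pd.DataFrame(rows)
    if df.empty or df["l"].nunique() < 2:
        raise ValueError("need fits at >= 2 distinct region lengths")
    g = df.groupby("l")["lam"]
    lengths = np.array(sorted(df["l"].unique()), dtype=float)
    mean = g.mean().reindex(lengths).to_numpy()
    sd = g.std(ddof=1).reindex(lengths).to_numpy()  # NaN for singletons
    n = g.size().reindex(lengths).to_numpy()
    return LambdaTrend(lengths, mean, sd, n, length_unit=length_unit)


@dataclass(frozen=True)
class PersistenceEstimate:
    """A persistence-length estimate with its regression coefficients."""

    model: str                   # {"linear", "exponential"}
    coeffs: tuple[float, float]  # (a', b') or (a, d)
    lp_nm: float
    fit_r2: float
    valid: bool
    message: str = ""


def _require_nm(trend: LambdaTrend, convert: bool) -> LambdaTrend:
    if trend.length_unit == "nm":
        return trend
    if convert:
        return trend.to_nm()
    raise ValueError(
        "trend lengths are in bp; persistence length is only meaningful in "
        "nm — pass convert_bp=True or convert with LambdaTrend.to_nm()"
    )


def persistence_linear(
    trend: LambdaTrend, convert_bp: bool = False
) -> PersistenceEstimate:
    """Estimate Lp from the long-fragment linear trend lambda(l) = a' + b' l.

    ``Lp = (1 - a' ln2) / (b' ln2)``.  A non-positive slope or a non-positive
    resulting length is flagged invalid rather than raised.
    """
    trend = _require_nm(trend, convert_bp)
    if len(trend) < 3:
        raise ValueError("need >= 3 trend points for the linear model")
    x = np.asarray(trend.lengths, dtype=float)
    y = np.asarray(trend.lam_mean, dtype=float)
    b_prime, a_prime = np.polyfit(x, y, 1)
    yhat = a_prime + b_prime * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if b_prime <= 0:
        return PersistenceEstimate(
            "linear", (float(a_prime), float(b_prime)), float("nan"), r2,
            valid=False, message="non-positive slope: no positive persistence length",
        )
    lp = (1.0 - a_prime * LN2) / (b_prime * LN2)
    valid = lp > 1e-9  # a numerically-zero length is as meaningless as a negative one
    return PersistenceEstimate(
        "linear", (float(a_prime), float(b_prime)), float(lp), r2, valid=valid,
        message="" if valid else "non-positive persistence length",
    )


def persistence_exponential(
    trend: LambdaTrend, convert_bp: bool = False
) -> PersistenceEstimate:
    """Estimate Lp from the short-fragment entropic-spring trend.

    Fits ``lambda(l) = a exp(d l)`` by nonlinear least squares (log-linear
    regression provides the start), then ``Lp = 3 / (2 d)``.
    """
    trend = _require_nm(trend, convert_bp)
    if len(trend) < 3:
        raise ValueError("need >= 3 trend points for the exponential model")
    x = np.asarray(trend.lengths, dtype=float)
    y = np.asarray(trend.lam_mean, dtype=float)
    d0, loga0 = np.polyfit(x, np.log(y), 1)

    def residuals(theta):
        a, d = theta
        return a * np.exp(d * x) - y

    sol = optimize.least_squares(
        residuals, [math.exp(loga0), d0], xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=5000,
    )
    a_hat, d_hat = sol.x
    yhat = a_hat * np.exp(d_hat * x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if d_hat <= 0:
        return PersistenceEstimate(
            "exponential", (float(a_hat), float(d_hat)), float("nan"), r2,
            valid=False, message="non-positive rate: no positive persistence length",
        )
    lp = 3.0 / (2.0 * d_hat)
    return PersistenceEstimate(
        "exponential", (float(a_hat), float(d_hat)), float(lp), r2, valid=True,
    )
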