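"""GM(1,1) grey prediction model with posterior-error accuracy testing.

The GM(1,1) model forecasts a short positive time series X^(0)(1..n) by
modelling its accumulated series X^(1)(k) = sum_{i<=k} X^(0)(i) with the
grey differential equation dX^(1)/dt + a X^(1) = u.  The development
coefficient ``a`` and grey action quantity ``u`` are estimated by ordinary
least squares on the difference form

    X^(0)(k) = -a z^(1)(k) + u,   k = 2..n,

where z^(1)(k) = (X^(1)(k) + X^(1)(k-1)) / 2 are trapezoid background
values.  The time-response equation

    Xhat^(1)(k+1) = (X^(0)(1) - u/a) e^{-a k} + u/a,   k = 0, 1, ...

is restored to the original scale by first differencing, with
xhat^(0)(1) = X^(0)(1) by convention (so the first residual is exactly 0).
``a < 0`` corresponds to exponential growth.

Model adequacy is judged by the posterior error ratio C (residual
dispersion relative to the dispersion of the data) and the small-error
probability P (the fraction of residuals within 0.6745 standard deviations
of the mean residual); P > 0.95 and C < 0.35 grade the model level 1,
reliable for extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ContractError, DegenerateModelError, InsufficientDataError
from .panel import NationalSeries

#: Conventions for the posterior error ratio C.  "variance" divides the
#: population variances S2²/S1² (the form the packaged national-series
#: diagnostics follow); "std" divides the population standard deviations.
C_CONVENTIONS = ("variance", "std")


@dataclass(frozen=True)
class GreyModel:
    """A fitted GM(1,1) model."""

    a: float
    u: float
    x0_first: float
    n: int
    years: tuple[int, ...]
    fitted: tuple[float, ...]
    residuals: tuple[float, ...]

    @property
    def response_coefficient(self) -> float:
        """Coefficient of e^{-ak} in the time response: X^(0)(1) - u/a."""
        return self.x0_first - self.u / self.a

    @property
    def asymptote(self) -> float:
        """The u/a constant term of the time response."""
        return self.u / self.a

    def response_string(self) -> str:
        """Human-readable time-response equation."""
        return (
            f"Xhat1(k+1) = {self.response_coefficient:.4f}"
            f"*exp({-self.a:.6g}*k) + {self.asymptote:.4f}"
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Posterior-error diagnostics of a fitted grey model."""

    C: float
    P: float
    level: int
    S1: float
    S2: float
    mean_residual: float
    convention: str

    @property
    def reliable(self) -> bool:
        return self.level == 1


def _restored_series(a: float, u: float, x0_first: float, length: int) -> np.ndarray:
    """Restored values xhat^(0)(1..length); first value is x0_first exactly."""
    k = np.arange(length, dtype=float)  # first observation year <-> k = 0
    x1_hat = (x0_first - u / a) * np.exp(-a * k) + u / a
    out = np.empty(length)
    out[0] = x0_first
    out[1:] = np.diff(x1_hat)
    return out


def fit_gm11(series: NationalSeries) -> GreyModel:
    """Fit GM(1,1) to a national series by least squares.

    Requires n >= 4 strictly positive, non-constant values.
    """
    x0 = np.asarray(series.values, dtype=float)
    n = x0.size
    if n < 4:
        raise InsufficientDataError(f"GM(1,1) needs at least 4 points, got {n}")
    if (x0 <= 0).any():
        raise DegenerateModelError("GM(1,1) requires strictly positive values")
    if np.ptp(x0) == 0:
        raise DegenerateModelError("constant series: grey model degenerate")

    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    design = np.column_stack([-z, np.ones(n - 1)])
    (a, u), *_ = np.linalg.lstsq(design, x0[1:], rcond=None)
    if abs(a) < 1e-12:
        raise DegenerateModelError("development coefficient a is ~0")

    fitted = _restored_series(a, u, x0[0], n)
    return GreyModel(
        a=float(a),
        u=float(u),
        x0_first=float(x0[0]),
        n=n,
        years=tuple(series.years),
        fitted=tuple(fitted),
        residuals=tuple(x0 - fitted),
    )


def forecast(model: GreyModel, horizon: int) -> dict[int, float]:
    """Restored predictions for the ``horizon`` years after the sample."""
    if horizon < 1:
        raise ContractError("forecast horizon must be >= 1")
    full = _restored_series(model.a, model.u, model.x0_first, model.n + horizon)
    last_year = model.years[-1]
    return {
        last_year + h: float(full[model.n + h - 1]) for h in range(1, horizon + 1)
    }


def accuracy_test(model: GreyModel, convention: str = "variance") -> AccuracyReport:
    """Posterior error ratio C, small-error probability P, accuracy level.

    Residuals for all n in-sample years enter (the first is 0 by
    construction); dispersions use the population (divide-by-n) formula.
    Levels follow the conventional ladder: level 1 if P > 0.95 and C < 0.35,
    level 2 if P > 0.80 and C < 0.50, level 3 if P > 0.70 and C < 0.65,
    level 4 otherwise.
    """
    if convention not in C_CONVENTIONS:
        raise ContractError(f"convention must be one of {C_CONVENTIONS}")
    x0 = np.array([f + r for f, r in zip(model.fitted, model.residuals)])
    eps = np.asarray(model.residuals)
    s1 = float(np.std(x0))
    s2 = float(np.std(eps))
    if s1 == 0:
        raise DegenerateModelError("original series has zero dispersion")
    c = (s2 / s1) ** 2 if convention == "variance" else s2 / s1
    p = float(np.mean(np.abs(eps - eps.mean()) < 0.6745 * s1))
    if p > 0.95 and c < 0.35:
        level = 1
    elif p > 0.80 and c < 0.50:
        level = 2
    elif p > 0.70 and c < 0.65:
        level = 3
    else:
        level = 4
    return AccuracyReport(
        C=c,
        P=p,
        level=level,
        S1=s1,
        S2=s2,
        mean_residual=float(eps.mean()),
        convention=convention,
    )


def relative_errors(model: GreyModel) -> dict[int, float]:
    """Per-year percentage errors 100*|fitted - actual|/actual (first year 0)."""
    out = {}
    for year, fit, res in zip(model.years, model.fitted, model.residuals):
        actual = fit + res
        out[year] = 100.0 * abs(res) / actual
    return out


def forecast_table(model: GreyModel, horizon_year: int) -> pd.DataFrame:
    """Fitted values with relative errors plus forecasts up to horizon_year."""
    if horizon_year <= model.years[-1]:
        raise ContractError("horizon year must be after the last observed year")
    rel = relative_errors(model)
    rows = [
        {"year": y, "value": f, "relative_error_pct": rel[y], "kind": "fitted"}
        for y, f in zip(model.years, model.fitted)
    ]
    for y, v in forecast(model, horizon_year - model.years[-1]).items():
        rows.append(
            {"year": y, "value": v, "relative_error_pct": float("nan"),
             "kind": "forecast"}
        )
    return pd.DataFrame(rows)
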