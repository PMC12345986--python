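"""Logistic growth modelling of longitudinal pig body weights.

The model is the three-parameter logistic curve

    y(t) = A / (1 + B * exp(-K * t))

with ``A`` the mature (asymptotic) body weight in kg, ``B`` a dimensionless
shape/offset parameter and ``K`` the intrinsic growth rate per day.  Age ``t``
is measured in days, weight ``y`` in kg.

Closed-form landmarks used throughout husbandry practice:

* inflection age  t* = ln(B)/K — the age of maximum daily gain;
* inflection weight y(t*) = A/2;
* maximum daily gain (MDG) = A*K/4 kg/day, reported in g/day;
* fastest post-inflection deceleration of the growth rate at
  t = [ln(B) + ln(2 + sqrt(3))]/K, where the curve's second time-derivative
  is most negative; the weight there is A*(3 + sqrt(3))/6.  This age is the
  "optimal slaughter age" proxy: beyond it, daily gain collapses fastest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitConvergenceError, InsufficientDataError, InvalidParameterError

__all__ = [
    "LogisticParams",
    "LogisticFit",
    "GrowthLandmarks",
    "predict_weight",
    "growth_rate",
    "growth_acceleration",
    "fit_logistic",
    "landmarks",
    "adg_table",
]

#: ln(2 + sqrt(3)): offset (in units of 1/K) from the inflection age to the
#: age of fastest growth-rate decline (post-inflection root of y''' = 0).
_LN_2_PLUS_SQRT3 = math.log(2.0 + math.sqrt(3.0))


@dataclass(frozen=True)
class LogisticParams:
    """Parameters (A, B, K) of the logistic growth curve.

    Attributes
    ----------
    A : float
        Asymptotic body weight, kg. Must be positive.
    B : float
        Dimensionless shape parameter. Must be positive.
    K : float
        Growth-rate parameter, per day. Must be positive.
    """

    A: float
    B: float
    K: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "K"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"logistic parameter {name} must be finite and > 0, got {value!r}"
                )


@dataclass(frozen=True)
class LogisticFit:
    """Result of a least-squares logistic fit.

    ``pcc`` is the Pearson correlation between observed and fitted weights
    over all points used in the fit (the fit-quality statistic printed in
    growth-model tables); ``residual_sd`` is in kg.
    """

    params: LogisticParams
    pcc: float
    n_animals: int
    n_points: int
    residual_sd: float


@dataclass(frozen=True)
class GrowthLandmarks:
    """Closed-form landmark quantities of a fitted logistic curve.

    Ages in days, weights in kg, ``max_daily_gain`` in g/day.
    """

    inflection_age: float
    inflection_weight: float
    max_daily_gain: float
    max_decel_age: float
    max_decel_weight: float


def predict_weight(params: LogisticParams, age):
    """Body weight (kg) at ``age`` days under the logistic model.

    ``age`` may be a scalar or array; ages must be >= 0.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise InvalidParameterError("age must be >= 0")
    out = params.A / (1.0 + params.B * np.exp(-params.K * age))
    return float(out) if out.ndim == 0 else out


def growth_rate(params: LogisticParams, age):
    """Instantaneous growth rate dy/dt in kg/day.

    Analytic first derivative: A*K*B*exp(-K*t) / (1 + B*exp(-K*t))^2.
    Maximal at the inflection age ln(B)/K where it equals A*K/4.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise InvalidParameterError("age must be >= 0")
    e = params.B * np.exp(-params.K * age)
    out = params.A * params.K * e / (1.0 + e) ** 2
    return float(out) if out.ndim == 0 else out


def growth_acceleration(params: LogisticParams, age):
    """Second time-derivative of weight, kg/day^2.

    Analytic form A*K^2*u*(u - 1)/(1 + u)^3 with u = B*exp(-K*t); most
    negative at the maximum-deceleration age.
    """
    age = np.asarray(age, dtype=float)
    u = params.B * np.exp(-params.K * age)
    out = params.A * params.K**2 * u * (u - 1.0) / (1.0 + u) ** 3
    return float(out) if out.ndim == 0 else out


def landmarks(params: LogisticParams) -> GrowthLandmarks:
    """Derive all landmark quantities from logistic parameters.

    Returns inflection age/weight, maximum daily gain (g/day), and the
    post-inflection maximum-deceleration age/weight.
    """
    t_inf = math.log(params.B) / params.K
    t_dec = (math.log(params.B) + _LN_2_PLUS_SQRT3) / params.K
    return GrowthLandmarks(
        inflection_age=t_inf,
        inflection_weight=params.A / 2.0,
        max_daily_gain=1000.0 * params.A * params.K / 4.0,
        max_decel_age=t_dec,
        max_decel_weight=params.A * (3.0 + math.sqrt(3.0)) / 6.0,
    )


def _as_age_weight_arrays(records) -> tuple[np.ndarray, np.ndarray, int]:
    """Extract (age, weight, n_animals) from a DataFrame or record iterable."""
    if isinstance(records, pd.DataFrame):
        df = records
        ages = df["age_days"].to_numpy(dtype=float)
        weights = df["weight_kg"].to_numpy(dtype=float)
        n_animals = df["animal_id"].nunique() if "animal_id" in df.columns else 1
        return ages, weights, int(n_animals)
    recs = list(records)
    ages = np.array([getattr(r, "age_days", None) or r[0] for r in recs], dtype=float)
    weights = np.array(
        [getattr(r, "weight_kg", None) or r[1] for r in recs], dtype=float
    )
    ids = {getattr(r, "animal_id", i) for i, r in enumerate(recs)}
    return ages, weights, len(ids)


def _initial_values(ages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Self-starting initial estimate (log-scale) for the logistic fit.

    A0 = 1.05 * max(weight); B0, K0 from the linear regression of
    log(A0/y - 1) on age (intercept = ln B0, slope = -K0).
    """
    a0 = 1.05 * float(np.max(weights))
    z = np.log(np.clip(a0 / weights - 1.0, 1e-12, None))
    slope, intercept = np.polyfit(ages, z, 1)
    k0 = max(-slope, 1e-6)
    b0 = max(math.exp(intercept), 1e-6)
    return np.log([a0, b0, k0])


def fit_logistic(records) -> LogisticFit:
    """Fit the logistic curve to pooled (age, weight) observations.

    ``records`` is a DataFrame with columns ``animal_id, age_days, weight_kg``
    (breed column ignored) or an iterable of objects/tuples carrying age and
    weight.  All animals are pooled into one population curve.  Positivity of
    (A, B, K) is enforced by optimizing over log-parameters.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 distinct (age, weight) points.
    FitConvergenceError
        The damped least-squares solver did not converge; diagnostics carry
        the iteration count and final cost.
    """
    ages, weights, n_animals = _as_age_weight_arrays(records)
    if np.any(ages <= 0) or np.any(weights <= 0):
        raise InvalidParameterError("ages and weights must be positive")
    n_distinct = len({(a, w) for a, w in zip(ages, weights)})
    if n_distinct < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct (age, weight) points, got {n_distinct}"
        )

    def residuals(log_theta: np.ndarray) -> np.ndarray:
        a, b, k = np.exp(log_theta)
        return weights - a / (1.0 + b * np.exp(-k * ages))

    x0 = _initial_values(ages, weights)
    sol = optimize.least_squares(
        residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=500 * 3,
    )
    if not sol.success:
        raise FitConvergenceError(
            f"logistic fit did not converge: {sol.message}",
            diagnostics={"nfev": sol.nfev, "cost": sol.cost, "status": sol.status},
        )
    a, b, k = np.exp(sol.x)
    params = LogisticParams(A=float(a), B=float(b), K=float(k))
    fitted = predict_weight(params, ages)
    if np.ptp(fitted) == 0 or np.ptp(weights) == 0:
        pcc = float("nan")
    else:
        pcc = float(stats.pearsonr(weights, fitted)[0])
    dof = max(len(weights) - 3, 1)
    residual_sd = float(np.sqrt(np.sum((weights - fitted) ** 2) / dof))
    return LogisticFit(
        params=params,
        pcc=pcc,
        n_animals=n_animals,
        n_points=len(weights),
        residual_sd=residual_sd,
    )


def adg_table(
    params: LogisticParams,
    group_mean_ages: Sequence[float] | Iterable[float],
    convention: str = "cumulative",
    start_age: float = 50.0,
) -> np.ndarray:
    """Average daily gain (g/day) at each group's mean age.

    Two conventions:

    * ``"cumulative"`` (default): gain accumulated since ``start_age`` days
      divided by elapsed days — (y(t) - y(start)) / (t - start).  At
      t == start_age the limit (instantaneous rate) is used.
    * ``"instantaneous"``: the model growth rate dy/dt at t.
    """
    ages = np.asarray(list(group_mean_ages), dtype=float)
    if np.any(ages <= 0):
        raise InvalidParameterError("group mean ages must be > 0")
    if convention == "instantaneous":
        return 1000.0 * np.atleast_1d(growth_rate(params, ages))
    if convention != "cumulative":
        raise ValueError(f"unknown ADG convention {convention!r}")
    y = np.atleast_1d(predict_weight(params, ages))
    y0 = predict_weight(params, start_age)
    out = np.empty_like(y)
    at_start = np.isclose(ages, start_age)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1000.0 * (y - y0) / (ages - start_age)
    if np.any(at_start):
        out[at_start] = 1000.0 * np.atleast_1d(growth_rate(params, ages))[at_start]
    return out
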