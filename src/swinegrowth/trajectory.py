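"""Trait-versus-body-weight trajectories and plateau detection.

After the growth inflection point, traits such as loin muscle area (LMA)
and intramuscular fat (IMF) typically rise quickly and then level off.  Two
candidate mean-response families are fitted by least squares:

* ``quadratic``:   y = c2*bw^2 + c1*bw + c0
* ``asymptotic``:  y = a - b*exp(-c*bw), c > 0 (monomolecular / von
  Bertalanffy-type saturation)

``model_form='auto'`` picks the family with the lower AIC.  A *plateau* is
declared at the smallest body weight in the observed range where the fitted
local slope |dy/dbw| falls below ``threshold_fraction`` times the maximum
fitted slope in range; for the asymptotic family this has the closed form
bw_start + ln(1/threshold)/c whenever it lies inside the range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitConvergenceError, InsufficientDataError

__all__ = ["TraitCurveFit", "PlateauResult", "fit_trait_curve", "plateau_weight",
           "predict_trait", "trait_slope"]

_FORMS = ("quadratic", "asymptotic")


@dataclass(frozen=True)
class TraitCurveFit:
    """A fitted trait-vs-body-weight curve.

    ``coefficients`` are (c2, c1, c0) for the quadratic form and (a, b, c)
    for the asymptotic form.  ``bw_range`` is the observed (min, max) body
    weight in kg; slopes and plateaus are only evaluated inside it.
    """

    trait: str
    breed: str
    model_form: str
    coefficients: tuple[float, ...]
    aic: float
    bw_range: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class PlateauResult:
    """Outcome of the slope-threshold plateau rule.

    ``plateau_weight`` is None when the fitted slope never drops below
    ``threshold_fraction`` x the in-range maximum slope (e.g. a straight
    line); slopes are in trait units per kg.
    """

    plateau_weight: float | None
    slope_at_plateau: float | None
    max_slope: float
    threshold_fraction: float


def _aic(sse: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC up to an additive constant shared by models.
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + 2 * k


def predict_trait(fit: TraitCurveFit, bw):
    """Evaluate the fitted mean response at body weight ``bw`` (kg)."""
    bw = np.asarray(bw, dtype=float)
    if fit.model_form == "quadratic":
        c2, c1, c0 = fit.coefficients
        out = c2 * bw**2 + c1 * bw + c0
    else:
        a, b, c = fit.coefficients
        out = a - b * np.exp(-c * bw)
    return float(out) if out.ndim == 0 else out


def trait_slope(fit: TraitCurveFit, bw):
    """Analytic derivative of the fitted response, trait units per kg."""
    bw = np.asarray(bw, dtype=float)
    if fit.model_form == "quadratic":
        c2, c1, _ = fit.coefficients
        out = 2.0 * c2 * bw + c1
    else:
        a, b, c = fit.coefficients
        out = b * c * np.exp(-c * bw)
    return float(out) if out.ndim == 0 else out


def _fit_quadratic(bw, y) -> tuple[tuple[float, ...], float]:
    coeffs = np.polyfit(bw, y, 2)
    sse = float(np.sum((np.polyval(coeffs, bw) - y) ** 2))
    return tuple(float(c) for c in coeffs), sse


def _fit_asymptotic(bw, y) -> tuple[tuple[float, ...], float]:
    def model(x, a, b, c):
        return a - b * np.exp(-c * x)

    a0 = float(np.max(y)) + 0.05 * max(float(np.ptp(y)), 1e-6)
    # linearize log(a0 - y) = log b - c*bw for starting values
    with np.errstate(invalid="ignore"):
        z = np.log(np.clip(a0 - y, 1e-9, None))
    slope, intercept = np.polyfit(bw, z, 1)
    c0 = min(max(-slope, 1e-4), 10.0)
    b0 = math.exp(min(intercept, 500.0))
    try:
        popt, _ = optimize.curve_fit(
            model, bw, y, p0=[a0, b0, c0],
            bounds=([-np.inf, 1e-12, 1e-8], [np.inf, np.inf, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise FitConvergenceError(f"asymptotic trait fit failed: {exc}") from exc
    sse = float(np.sum((model(bw, *popt) - y) ** 2))
    return tuple(float(p) for p in popt), sse


def fit_trait_curve(
    bw, trait_values, model_form: str = "auto", trait: str = "", breed: str = ""
) -> TraitCurveFit:
    """Least-squares fit of a trait trajectory against body weight.

    ``model_form`` is ``'quadratic'``, ``'asymptotic'`` or ``'auto'`` (pick
    the lower AIC).  Requires at least 6 points and strictly positive body
    weights.
    """
    bw = np.asarray(bw, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    if bw.shape != y.shape:
        raise ValueError("bw and trait value arrays must have the same length")
    mask = np.isfinite(bw) & np.isfinite(y)
    bw, y = bw[mask], y[mask]
    if len(bw) < 6:
        raise InsufficientDataError(f"need >= 6 points, got {len(bw)}")
    if np.any(bw <= 0):
        raise ValueError("body weights must be positive")

    candidates: dict[str, tuple[tuple[float, ...], float]] = {}
    forms = _FORMS if model_form == "auto" else (model_form,)
    if model_form != "auto" and model_form not in _FORMS:
        raise ValueError(f"unknown model_form {model_form!r}")
    for form in forms:
        fitter = _fit_quadratic if form == "quadratic" else _fit_asymptotic
        try:
            candidates[form] = fitter(bw, y)
        except FitConvergenceError:
            if model_form != "auto":
                raise
    if not candidates:
        raise FitConvergenceError("no trajectory family converged")

    n = len(bw)
    aics = {f: _aic(sse, n, 3) for f, (_, sse) in candidates.items()}
    best = min(aics, key=aics.get)
    coeffs, _sse = candidates[best]
    return TraitCurveFit(
        trait=trait,
        breed=breed,
        model_form=best,
        coefficients=coeffs,
        aic=float(aics[best]),
        bw_range=(float(np.min(bw)), float(np.max(bw))),
        n_points=n,
    )


def plateau_weight(
    fit: TraitCurveFit,
    threshold_fraction: float = 0.1,
    scan_step: float = 0.1,
) -> PlateauResult:
    """Find where the fitted trajectory plateaus, if it does.

    The plateau is the smallest body weight in ``fit.bw_range`` at which the
    absolute fitted slope drops below ``threshold_fraction`` times the
    maximum absolute slope in range.  The asymptotic family admits the
    closed form lo + ln(1/threshold)/c (its slope is maximal at the range
    start); other forms are scanned at ``scan_step`` kg resolution.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    lo, hi = fit.bw_range
    grid = np.arange(lo, hi + scan_step / 2, scan_step)
    slopes = np.abs(np.atleast_1d(trait_slope(fit, grid)))
    max_slope = float(np.max(slopes))
    if max_slope == 0.0:
        return PlateauResult(None, None, 0.0, threshold_fraction)

    if fit.model_form == "asymptotic":
        c = fit.coefficients[2]
        bw_star = lo + math.log(1.0 / threshold_fraction) / c
        if bw_star <= hi:
            return PlateauResult(
                plateau_weight=float(bw_star),
                slope_at_plateau=float(trait_slope(fit, bw_star)),
                max_slope=max_slope,
                threshold_fraction=threshold_fraction,
            )
        return PlateauResult(None, None, max_slope, threshold_fraction)

    below = slopes < threshold_fraction * max_slope
    if not below.any():
        return PlateauResult(None, None, max_slope, threshold_fraction)
    idx = int(np.argmax(below))
    return PlateauResult(
        plateau_weight=float(grid[idx]),
        slope_at_plateau=float(trait_slope(fit, grid[idx])),
        max_slope=max_slope,
        threshold_fraction=threshold_fraction,
    )
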