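"""Piecewise log-linear life-course model of methylation trajectories.

Within a stratum, standardized mean methylation follows

    ScaledM = gamma0 + gamma1 * g(R),        R = relative age,

where the transform g linearizes the trajectory across life:

    g(R) = ln(R / c)      for R <  c        (fast early change)
    g(R) = R / c - 1      for R >= c        (linear adult change)

with the knot c = 0.1 by default.  g and its derivative are both continuous
at the knot (g(c) = 0, g'(c) = 1/c).  The age-derivative of the fitted
curve, gamma1 * g'(R0) / L, is the model-based rate of change at relative
age R0; evaluated above the knot it gives the "old" rate gamma1 / (c L),
below the knot the "young" rate gamma1 / (R0 L), whence the young and old
rates are proportional with constant c / R_young.

The alternative transform g2(R) = ln(R / c) everywhere is provided for
model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import StratumView, pearson
from .errors import DegenerateStratumError

__all__ = [
    "LifeCourseFit",
    "loglinear_transform",
    "fit_lifecourse",
    "derivative_arocm",
    "young_old_relation",
]

DEFAULT_KNOT = 0.1


def loglinear_transform(R, which: str = "g", knot: float = DEFAULT_KNOT):
    """Evaluate the life-course transform and its derivative.

    Returns ``(T, dT_dR)``.  ``which`` is ``"g"`` (piecewise: logarithmic
    below the knot, linear above) or ``"g2"`` (logarithmic everywhere).
    The natural log is used; R must be positive wherever a log branch
    applies.
    """
    if which not in ("g", "g2"):
        raise ValueError("transform must be 'g' or 'g2'")
    if not (0.0 < knot < 1.0):
        raise ValueError("knot must lie in (0, 1)")
    R = np.asarray(R, dtype=float)
    scalar = R.ndim == 0
    R = np.atleast_1d(R)
    if np.any(R < 0) or np.any(R > 1):
        raise ValueError("relative ages must lie in [0, 1]")

    if which == "g2":
        if np.any(R == 0):
            raise ValueError("g2 is undefined at R = 0")
        T = np.log(R / knot)
        dT = 1.0 / R
    else:
        below = R < knot
        if np.any(R[below] == 0):
            raise ValueError("g is undefined at R = 0")
        T = np.empty_like(R)
        dT = np.empty_like(R)
        T[below] = np.log(R[below] / knot)
        dT[below] = 1.0 / R[below]
        T[~below] = R[~below] / knot - 1.0
        dT[~below] = 1.0 / knot
    if scalar:
        return float(T[0]), float(dT[0])
    return T, dT


@dataclass
class LifeCourseFit:
    """Least-squares fit of ScaledM on the transformed relative age."""

    stratum_id: str
    transform: str
    knot: float
    gamma0: float
    gamma1: float
    pearson_r: float
    n: int
    L: float


def fit_lifecourse(view: StratumView, transform: str = "g",
                   knot: float = DEFAULT_KNOT) -> LifeCourseFit:
    """Fit gamma0 + gamma1 * g(R) to a stratum's scaled methylation."""
    if view.n < 3:
        raise DegenerateStratumError("too_few_samples", view.stratum_id)
    R = np.asarray(view.rel_ages, dtype=float)
    if not (np.any(R < knot) and np.any(R >= knot)):
        warnings.warn(
            f"stratum {view.stratum_id!r}: relative ages do not span the "
            f"knot at {knot}; the two branches are not both constrained"
        )
    T, _ = loglinear_transform(R, transform, knot)
    if T.std() == 0:
        raise DegenerateStratumError("constant_transformed_ages", view.stratum_id)
    y = np.asarray(view.scaled, dtype=float)
    X = np.column_stack([np.ones_like(T), T])
    (g0, g1), *_ = np.linalg.lstsq(X, y, rcond=None)
    return LifeCourseFit(
        stratum_id=view.stratum_id,
        transform=transform,
        knot=knot,
        gamma0=float(g0),
        gamma1=float(g1),
        pearson_r=pearson(y, T),
        n=view.n,
        L=view.L,
    )


def derivative_arocm(fit: LifeCourseFit, L: float, R0: float) -> float:
    """Model-based rate of change (per year) at relative age R0.

    This is the age-derivative of the fitted life-course curve:
    gamma1 * g'(R0) / L.
    """
    if L <= 0:
        raise ValueError("lifespan must be positive")
    if not (0.0 < R0 <= 1.0):
        raise ValueError("R0 must lie in (0, 1]")
    _, d = loglinear_transform(R0, fit.transform, fit.knot)
    return fit.gamma1 * d / L


def young_old_relation(R_young: float, knot: float = DEFAULT_KNOT) -> float:
    """Proportionality constant between young and old rates: knot / R_young.

    With the default knot 0.1 this is 1 / (10 * R_young); it tends to 1 as
    the young reference age approaches the knot, where the two rates meet.
    """
    if not (0.0 < R_young < knot):
        raise ValueError(f"R_young must lie in (0, {knot})")
    return knot / R_young
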