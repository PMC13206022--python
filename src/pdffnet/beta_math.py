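"""Beta-family machinery parameterized by mode and variance.

Liver proton-density fat fraction (PDFF) is a proportion in (0, 1), so a
beta distribution Beta(alpha, beta) is a natural predictive law for it.
Throughout this package a ground-truth PDFF value is identified with the
*mode* of such a distribution, which for alpha, beta > 1 sits strictly
inside the unit interval at

    mode = (alpha - 1) / (alpha + beta - 2).

The mode alone does not pin down (alpha, beta): every point on the
"mode line"

    alpha = 1 + m * (s - 2),   beta = 1 + (1 - m) * (s - 2),   s > 2,

where s = alpha + beta is the total concentration, has the same mode m.
Supplying a target variance removes the remaining degree of freedom, and
because the variance is strictly decreasing in s along the mode line the
inversion reduces to a monotone one-dimensional root find.

This module provides that inversion, its feasibility limit, and
equal-tailed intervals of the resulting distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

__all__ = [
    "BetaParams",
    "ModeVarianceSpec",
    "CredibleInterval",
    "beta_mode",
    "beta_variance",
    "max_feasible_variance",
    "solve_beta_from_mode_variance",
    "beta_credible_interval",
    "MODE_CLAMP",
]

#: Modes are clamped to [MODE_CLAMP, 1 - MODE_CLAMP] before inversion so a
#: reported fat fraction of exactly 0 (or 1) cannot degenerate the mode line.
MODE_CLAMP = 1e-4

#: Supremum of the feasible variance under alpha, beta > 1; attained in the
#: limit s -> 2+ where the distribution tends to the uniform Beta(1, 1).
VARIANCE_SUPREMUM = 1.0 / 12.0


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of one predictive beta distribution.

    Both shapes must exceed 1 so the density is unimodal with an interior
    mode; this is what lets a PDFF value be read off as the distribution's
    peak.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError(f"shape parameters must be finite, got ({self.alpha}, {self.beta})")
        if self.alpha <= 1.0 or self.beta <= 1.0:
            raise ValueError(
                f"unimodal interior-mode beta requires alpha, beta > 1, got ({self.alpha}, {self.beta})"
            )

    @property
    def concentration(self) -> float:
        return self.alpha + self.beta


@dataclass(frozen=True)
class ModeVarianceSpec:
    """A (mode, variance) pair specifying a beta distribution implicitly."""

    mode: float
    variance: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mode < 1.0:
            raise ValueError(f"mode must lie in (0, 1), got {self.mode}")
        if not 0.0 < self.variance < VARIANCE_SUPREMUM:
            raise ValueError(
                f"variance must lie in (0, 1/12) for an interior-mode beta, got {self.variance}"
            )


@dataclass(frozen=True)
class CredibleInterval:
    """Equal-tailed interval [lower, upper] at the given coverage level."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError(f"need 0 <= lower < upper <= 1, got [{self.lower}, {self.upper}]")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def beta_mode(params: BetaParams) -> float:
    """Interior mode (alpha - 1) / (alpha + beta - 2) of a Beta(alpha, beta)."""
    return (params.alpha - 1.0) / (params.alpha + params.beta - 2.0)


def beta_variance(params: BetaParams) -> float:
    """Variance alpha*beta / ((alpha+beta)^2 (alpha+beta+1))."""
    s = params.alpha + params.beta
    return params.alpha * params.beta / (s * s * (s + 1.0))


def _shapes_on_mode_line(mode: float, concentration: float) -> tuple[float, float]:
    """Shapes with the given mode at total concentration s = alpha + beta."""
    return 1.0 + mode * (concentration - 2.0), 1.0 + (1.0 - mode) * (concentration - 2.0)


def _variance_on_mode_line(mode: float, concentration: float) -> float:
    a, b = _shapes_on_mode_line(mode, concentration)
    s = concentration
    return a * b / (s * s * (s + 1.0))


def max_feasible_variance(mode: float, concentration_floor: float) -> float:
    """Largest attainable variance for a given mode at concentrations >= floor.

    Along the mode line the variance decreases strictly with the total
    concentration s, so the maximum over s >= concentration_floor is the
    value at the floor itself. As the floor approaches 2 from above this
    tends to 1/12 (the uniform distribution) for every mode.
    """
    if not 0.0 < mode < 1.0:
        raise ValueError(f"mode must lie in (0, 1), got {mode}")
    if concentration_floor <= 2.0:
        raise ValueError(f"concentration floor must exceed 2, got {concentration_floor}")
    return _variance_on_mode_line(mode, concentration_floor)


FeasibilityPolicy = Literal["error", "clamp"]

#: When clamping an infeasible variance, target this multiple of the maximum
#: feasible variance so the root find stays strictly inside its bracket.
_CLAMP_FRACTION = 0.99
_DEFAULT_FLOOR = 2.0 + 1e-6
_BRACKET_CAP = 1e7


def solve_beta_from_mode_variance(
    spec: ModeVarianceSpec,
    tolerance: float = 1e-10,
    *,
    on_infeasible: FeasibilityPolicy = "error",
) -> BetaParams:
    """Invert (mode, variance) into a BetaParams pair.

    The mode is matched exactly by construction (shapes are taken on the
    mode line); the concentration s > 2 is found by Brent root-finding so
    the variance matches to within ``tolerance``. A requested variance at
    or above ``max_feasible_variance(mode, floor)`` is either rejected
    (``on_infeasible="error"``) or replaced by 99% of that maximum
    (``on_infeasible="clamp"``, used inside the calibration loop where a
    mid-training crash is worse than a slightly narrower label).
    """
    if tolerance <= 0.0:
        raise ValueError("tolerance must be positive")
    mode = min(max(spec.mode, MODE_CLAMP), 1.0 - MODE_CLAMP)
    target = spec.variance

    vmax = max_feasible_variance(mode, _DEFAULT_FLOOR)
    if target >= vmax:
        if on_infeasible == "clamp":
            target = _CLAMP_FRACTION * vmax
        else:
            raise ValueError(
                f"variance {target} infeasible for mode {mode}: maximum under "
                f"alpha, beta > 1 is {vmax:.6g}"
            )

    # Variance -> 0 as s -> infinity, so doubling the upper end of the
    # bracket is guaranteed to cross any feasible target.
    lo, hi = _DEFAULT_FLOOR, 10.0
    while _variance_on_mode_line(mode, hi) > target:
        hi *= 2.0
        if hi > _BRACKET_CAP:
            raise ArithmeticError(
                f"no concentration below {_BRACKET_CAP:g} reaches variance {target} at mode {mode}"
            )

    s_root = brentq(
        lambda s: _variance_on_mode_line(mode, s) - target,
        lo,
        hi,
        xtol=1e-14,
        rtol=8.881784197001252e-16,
        maxiter=200,
    )
    a, b = _shapes_on_mode_line(mode, s_root)
    params = BetaParams(alpha=a, beta=b)
    err = abs(beta_variance(params) - target)
    if err > tolerance:
        raise ArithmeticError(
            f"variance inversion converged to error {err:.3g} > tolerance {tolerance:.3g}"
        )
    return params


def beta_credible_interval(params: BetaParams, level: float = 0.95) -> CredibleInterval:
    """Equal-tailed interval: quantiles at (1-level)/2 and 1-(1-level)/2."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    tail = 0.5 * (1.0 - level)
    lower = float(beta_dist.ppf(tail, params.alpha, params.beta))
    upper = float(beta_dist.ppf(1.0 - tail, params.alpha, params.beta))
    return CredibleInterval(lower=lower, upper=upper, level=level)
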