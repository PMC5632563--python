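"""Minimal per-cluster-per-period sample size under a power constraint.

Power as a function of the (continuous) cell size m is evaluated with the
error-spending boundaries re-solved at every candidate, since the information
fractions I_t / I_T depend on m through sigma2 = sigma_e2 / m.  The search
finds the continuous root of power(m) = 1 - beta by bracketed bisection
(power is increasing in m), rounds up to the next integer, and verifies the
constraint still holds after re-solving at that integer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationError, InfeasibleDesignError, NumericalError
from .information import InformationProfile, information_closed_form, information_profile
from .layout_model import SWLayout, VarianceComponents
from .oc import stopping_distribution
from .spending import Boundaries, SpendingSpec, solve_boundaries

__all__ = ["DesignSpec", "SolvedDesign", "fixed_sample_m", "find_m", "solve_design", "attained_power"]


@dataclass(frozen=True)
class DesignSpec:
    """All knobs of a sequential SW-CRT design.

    ``m`` is either a positive integer or the string "search", in which case
    :func:`find_m` determines the minimal cell size meeting the power
    constraint at the clinically relevant difference ``delta``.
    """

    layout: SWLayout
    analyses: tuple[int, ...]
    m: int | str
    vc: VarianceComponents
    spending: SpendingSpec
    delta: float

    def __post_init__(self) -> None:
        analyses = tuple(int(t) for t in self.analyses)
        object.__setattr__(self, "analyses", analyses)
        if analyses[-1] != self.layout.T:
            raise ConfigurationError("the final analysis must be at period T")
        if not self.layout.X[:, : analyses[0]].any():
            raise ConfigurationError(
                "no cluster is treated by the first analysis; tau would be inestimable"
            )
        if self.delta <= 0:
            raise ConfigurationError("delta must be positive")
        if self.m != "search" and (not isinstance(self.m, (int, np.integer)) or self.m < 1):
            raise ConfigurationError('m must be a positive integer or "search"')


class SolvedDesign(NamedTuple):
    m: int
    boundaries: Boundaries
    profile: InformationProfile


def attained_power(spec: DesignSpec, m: float) -> float:
    """P(Reject H0 | tau = delta) with boundaries re-solved at cell size m."""
    profile = information_profile(spec.layout, spec.analyses, m, spec.vc)
    bounds = solve_boundaries(spec.spending, profile, spec.delta)
    dist = stopping_distribution(_WithM(spec, m), bounds, profile, spec.delta)
    return dist.reject_prob


class _WithM:
    """Lightweight design view exposing .m and .layout for the OC engine."""

    def __init__(self, spec: DesignSpec, m) -> None:
        self.layout = spec.layout
        self.m = int(np.ceil(m))
        self.spending = spec.spending


def fixed_sample_m(
    layout: SWLayout,
    vc: VarianceComponents,
    alpha: float,
    beta: float,
    delta: float,
    m_max: int = 10**6,
) -> int:
    """Smallest integer m so the single final analysis has one-sided power 1-beta.

    Solves Phi(delta*sqrt(I_T(m)) - z_{1-alpha}) >= 1 - beta on the continuous
    scale, then rounds up.
    """
    need = norm.ppf(1 - alpha) + norm.ppf(1 - beta)

    def gap(m: float) -> float:
        return delta * np.sqrt(information_closed_form(layout, layout.T, m, vc)) - need

    return int(np.ceil(_continuous_root(gap, m_max)))


def _continuous_root(gap, m_max: float) -> float:
    """Root of an increasing function of m in (0, m_max]."""
    lo = 1e-6
    while gap(lo) > 0 and lo > 1e-12:
        lo /= 10.0
    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 2 * m_max:
            raise InfeasibleDesignError(f"power not attainable with m <= {m_max}")
    return brentq(gap, lo, hi, xtol=1e-4)


def find_m(spec: DesignSpec, m_max: int = 10**6) -> SolvedDesign:
    """Minimal integer cell size m with P(Reject H0 | delta) >= 1 - beta.

    Boundaries are re-solved at every candidate m.  After rounding the
    continuous root up, the power constraint is re-verified at the integer
    (and m incremented if rounding-induced boundary changes broke it).
    """
    target = 1.0 - spec.spending.beta

    def gap(m: float) -> float:
        # Boundary crossing (f_t > e_t) happens when m is far above the root:
        # the type-II spend is then exhausted too easily under delta.  Treat
        # it as exceeding the power target so bracketing can proceed.
        try:
            return attained_power(spec, m) - target
        except InfeasibleDesignError:
            return 1.0

    m_cont = _continuous_root(gap, m_max)
    m_int = int(np.ceil(m_cont - 1e-9))
    while m_int <= m_max:
        if attained_power(spec, m_int) >= target - 1e-12:
            break
        m_int += 1
    else:
        raise InfeasibleDesignError(f"power not attainable with m <= {m_max}")
    profile = information_profile(spec.layout, spec.analyses, m_int, spec.vc)
    bounds = solve_boundaries(spec.spending, profile, spec.delta)
    return SolvedDesign(m=m_int, boundaries=bounds, profile=profile)


def solve_design(spec: DesignSpec, m_max: int = 10**6) -> tuple[DesignSpec, SolvedDesign]:
    """Resolve m (searching if requested) and solve the boundaries.

    Returns the spec with m fixed to its integer value together with the
    solved boundaries and information profile.
    """
    if spec.m == "search":
        solved = find_m(spec, m_max)
        return replace(spec, m=solved.m), solved
    profile = information_profile(spec.layout, spec.analyses, spec.m, spec.vc)
    bounds = solve_boundaries(spec.spending, profile, spec.delta)
    return spec, SolvedDesign(m=int(spec.m), boundaries=bounds, profile=profile)
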