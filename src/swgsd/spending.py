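"""Error-spending stopping boundaries for sequential SW-CRT designs.

Type-I and type-II error are allocated across the analysis schedule by the
power-family spending functions

    e(z) = alpha * z**gamma_e        (efficacy / type-I)
    f(z) = beta  * z**gamma_f        (futility / type-II)

of the information fraction z = I_t / I_T.  Boundaries are solved analysis by
analysis: the efficacy boundary e_t makes the probability of a first upper
crossing at t under tau = 0 equal the incremental type-I spend, and the
futility boundary f_t makes the first lower crossing at t under tau = delta
equal the incremental type-II spend, given all earlier boundaries.  At the
final analysis the efficacy boundary is set from the type-I spending equation
(prioritising exact type-I error) and the futility boundary is forced equal
to it so a decision is always made.

Early stopping in one direction only is obtained by fixing the other
boundary at +/- infinity at every interim analysis; the full error in the
suppressed direction is then spent at the final analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._recursion import N_NODES, PathState
from .errors import ConfigurationError, InfeasibleDesignError, NumericalError
from .information import InformationProfile

__all__ = ["SpendingSpec", "Boundaries", "spend", "solve_boundaries", "boundaries_to_csv"]

_BRACKET = (-15.0, 15.0)  # root bracket on the Z scale
_SPEND_FLOOR = 1e-12  # incremental spend below this => no stopping at that analysis

MODES = ("efficacy", "futility", "both", "none")


@dataclass(frozen=True)
class SpendingSpec:
    """One-sided error rates and spending exponents.

    mode selects the permitted reasons for early stopping: "efficacy",
    "futility", "both", or "none" (no early stopping; with a single-analysis
    schedule this is the classical fixed design).  gamma_e / gamma_f may be
    omitted when the corresponding direction never stops early.
    """

    alpha: float
    beta: float
    mode: str = "both"
    gamma_e: float | None = None
    gamma_f: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.beta < 1:
            raise ConfigurationError("beta must lie in (0, 1)")
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        if self.stops_efficacy and (self.gamma_e is None or self.gamma_e <= 0):
            raise ConfigurationError("gamma_e must be positive when efficacy stopping is allowed")
        if self.stops_futility and (self.gamma_f is None or self.gamma_f <= 0):
            raise ConfigurationError("gamma_f must be positive when futility stopping is allowed")

    @property
    def stops_efficacy(self) -> bool:
        return self.mode in ("efficacy", "both")

    @property
    def stops_futility(self) -> bool:
        return self.mode in ("futility", "both")


@dataclass(frozen=True)
class Boundaries:
    """Solved futility (f) and efficacy (e) boundary vectors with f[-1] == e[-1].

    ``spent_typeI[k]`` / ``spent_typeII[k]`` are the error probabilities
    actually committed at analysis k, recomputed from the solved boundaries.
    """

    analyses: tuple[int, ...]
    f: np.ndarray
    e: np.ndarray
    spent_typeI: np.ndarray
    spent_typeII: np.ndarray

    def replace_bounds(self, f: np.ndarray, e: np.ndarray) -> "Boundaries":
        return Boundaries(self.analyses, np.asarray(f, float), np.asarray(e, float),
                          self.spent_typeI, self.spent_typeII)


def spend(z: float, total: float, gamma: float) -> float:
    """Cumulative error spend total * z**gamma at information fraction z in [0, 1]."""
    if not 0 <= z <= 1:
        raise ValueError(f"information fraction z={z} outside [0, 1]")
    return total * z**gamma


def _increments(fractions: np.ndarray, total: float, gamma: float) -> np.ndarray:
    cum = np.array([spend(z, total, gamma) for z in fractions])
    return np.diff(np.concatenate([[0.0], cum]))


def _solve_bound(state: PathState, target: float, upper: bool) -> float:
    """Root on the Z scale so the next-analysis first crossing equals target."""
    if target <= _SPEND_FLOOR:
        return np.inf if upper else -np.inf
    prob = state.crossing_upper if upper else state.crossing_lower
    lo, hi = _BRACKET
    g_lo, g_hi = prob(lo) - target, prob(hi) - target
    if g_lo * g_hi > 0:
        if (upper and g_lo < 0) or (not upper and g_hi < 0):
            raise InfeasibleDesignError(
                "requested error spend exceeds the available continuation probability"
            )
        raise NumericalError("boundary root not bracketed in [-15, 15]")
    return float(brentq(lambda b: prob(b) - target, lo, hi, xtol=1e-10))


def solve_boundaries(
    spec: SpendingSpec,
    profile: InformationProfile,
    delta: float,
    n_nodes: int = N_NODES,
) -> Boundaries:
    """Solve the error-spending boundaries for a given information profile.

    ``delta`` is the clinically relevant effect under which type-II error is
    spent.  The attained type-II error is whatever results from forcing
    f_T = e_T; the sample-size search in :mod:`swgsd.search` restores the
    power constraint.
    """
    if delta <= 0:
        raise ConfigurationError("delta must be positive")
    K = len(profile.analyses)
    fractions = profile.fractions
    if spec.stops_efficacy:
        inc_e = _increments(fractions, spec.alpha, spec.gamma_e)
        inc_e[-1] = spec.alpha - np.sum(inc_e[:-1])
    else:
        inc_e = np.concatenate([np.zeros(K - 1), [spec.alpha]])
    if spec.stops_futility:
        inc_f = _increments(fractions, spec.beta, spec.gamma_f)
    else:
        inc_f = np.zeros(K)

    state_null = PathState(0.0, profile.info, n_nodes)
    state_alt = PathState(delta, profile.info, n_nodes)
    f = np.full(K, -np.inf)
    e = np.full(K, np.inf)
    spent1 = np.zeros(K)
    spent2 = np.zeros(K)
    for k in range(K):
        if k < K - 1:
            if spec.stops_efficacy:
                e[k] = _solve_bound(state_null, inc_e[k], upper=True)
            if spec.stops_futility:
                f[k] = _solve_bound(state_alt, inc_f[k], upper=False)
            if f[k] > e[k]:
                raise InfeasibleDesignError(
                    f"futility boundary exceeds efficacy boundary at analysis "
                    f"t={profile.analyses[k]} (f={f[k]:.4f} > e={e[k]:.4f})"
                )
        else:
            e[k] = _solve_bound(state_null, inc_e[k], upper=True)
            f[k] = e[k]
        spent1[k] = state_null.crossing_upper(e[k])
        spent2[k] = state_alt.crossing_lower(f[k])
        if k < K - 1:
            state_null.advance(f[k], e[k])
            state_alt.advance(f[k], e[k])
    return Boundaries(analyses=profile.analyses, f=f, e=e, spent_typeI=spent1, spent_typeII=spent2)


def boundaries_to_csv(bounds: Boundaries, path) -> None:
    """Write boundaries as CSV with infinities rendered as "inf"/"-inf"."""
    buf = io.StringIO()
    buf.write("analysis_period,f,e,typeI_spent,typeII_spent\n")
    for k, t in enumerate(bounds.analyses):
        fv = f"{bounds.f[k]:.10g}" if np.isfinite(bounds.f[k]) else ("-inf" if bounds.f[k] < 0 else "inf")
        ev = f"{bounds.e[k]:.10g}" if np.isfinite(bounds.e[k]) else ("-inf" if bounds.e[k] < 0 else "inf")
        buf.write(f"{t},{fv},{ev},{bounds.spent_typeI[k]:.10g},{bounds.spent_typeII[k]:.10g}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
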