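"""Operating characteristics of a sequential stepped-wedge design.

For a solved design the joint law of (stopping analysis omega_R, decision
psi_R) at any true effect tau follows from multivariate-normal
boundary-crossing probabilities; the same deterministic recursion used to
solve the boundaries evaluates them here, so boundaries and operating
characteristics are mutually consistent.  Derived quantities: rejection
probability, the full distribution of the total number of measurements
M = m*C*omega_R, its expectation, and tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._recursion import N_NODES, first_crossing_probs
from .errors import ConfigurationError
from .information import InformationProfile
from .spending import Boundaries

__all__ = [
    "StoppingDistribution",
    "stopping_distribution",
    "expected_sample_size",
    "prob_exceeds",
    "oc_curve",
    "oc_table",
]


@dataclass(frozen=True)
class StoppingDistribution:
    """P(omega_R = omega, psi_R = psi | tau) and derived sample-size quantities.

    ``probs[k, psi]`` is the probability of stopping at the k-th analysis with
    decision psi (0 = accept H0, 1 = reject H0).  ``M_pmf`` maps each
    achievable total measurement count m*C*omega to its probability.
    """

    tau: float
    analyses: tuple[int, ...]
    probs: np.ndarray
    m: int
    C: int
    reject_prob: float = field(init=False)
    expected_M: float = field(init=False)
    min_M: int = field(init=False)
    max_M: int = field(init=False)
    M_pmf: dict = field(init=False)

    def __post_init__(self) -> None:
        sizes = np.array([self.m * self.C * t for t in self.analyses])
        stop = self.probs.sum(axis=1)
        object.__setattr__(self, "reject_prob", float(self.probs[:, 1].sum()))
        object.__setattr__(self, "expected_M", float(sizes @ stop))
        object.__setattr__(self, "min_M", int(sizes[0]))
        object.__setattr__(self, "max_M", int(sizes[-1]))
        object.__setattr__(self, "M_pmf", {int(s): float(p) for s, p in zip(sizes, stop)})


def stopping_distribution(
    design,
    boundaries: Boundaries,
    profile: InformationProfile,
    tau: float,
    n_nodes: int = N_NODES,
) -> StoppingDistribution:
    """Joint stopping-time/decision distribution at true effect tau.

    ``design`` only needs ``m`` and a ``layout`` with ``C`` (duck-typed); the
    stopping rules are: stop and accept iff Z_t <= f_t, stop and reject iff
    Z_t > e_t, with f_T = e_T forcing a final decision.
    """
    if tuple(boundaries.analyses) != tuple(profile.analyses):
        raise ConfigurationError("boundaries and information profile use different schedules")
    p_lower, p_upper = first_crossing_probs(profile.info, boundaries.f, boundaries.e, tau, n_nodes)
    probs = np.column_stack([p_lower, p_upper])
    return StoppingDistribution(
        tau=float(tau),
        analyses=tuple(profile.analyses),
        probs=probs,
        m=int(design.m),
        C=int(design.layout.C),
    )


def expected_sample_size(dist: StoppingDistribution, m: int | None = None, C: int | None = None) -> float:
    """E(M | tau) = sum over analyses of m*C*omega * P(stop at omega)."""
    if (m is not None and m != dist.m) or (C is not None and C != dist.C):
        sizes = np.array([m * C * t for t in dist.analyses])
        return float(sizes @ dist.probs.sum(axis=1))
    return dist.expected_M


def prob_exceeds(dist: StoppingDistribution, threshold: int) -> float:
    """P(M > threshold) from the sample-size distribution."""
    return float(sum(p for size, p in dist.M_pmf.items() if size > threshold))


def oc_curve(design, boundaries, profile, tau_grid, n_nodes: int = N_NODES) -> pd.DataFrame:
    """Rejection probability and expected sample size over a grid of true effects."""
    rows = []
    for tau in np.asarray(tau_grid, dtype=float):
        dist = stopping_distribution(design, boundaries, profile, tau, n_nodes)
        rows.append({"tau": tau, "reject_prob": dist.reject_prob, "expected_M": dist.expected_M})
    return pd.DataFrame(rows)


def oc_table(label: str, design, boundaries, profile, delta: float) -> dict:
    """One summary row in the layout of the worked-example tables."""
    d0 = stopping_distribution(design, boundaries, profile, 0.0)
    d1 = stopping_distribution(design, boundaries, profile, delta)
    spec = design.spending
    return {
        "design": label,
        "analyses": "{" + ",".join(str(t) for t in profile.analyses) + "}",
        "stopping": {"both": "E&F", "efficacy": "E", "futility": "F", "none": "NA"}[spec.mode],
        "gamma_e": spec.gamma_e if spec.stops_efficacy else None,
        "gamma_f": spec.gamma_f if spec.stops_futility else None,
        "m": design.m,
        "EM_null": round(d0.expected_M, 2),
        "reject_null": round(d0.reject_prob, 4),
        "EM_alt": round(d1.expected_M, 2),
        "reject_alt": round(d1.reject_prob, 4),
        "min_M": d0.min_M,
        "max_M": d0.max_M,
    }
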