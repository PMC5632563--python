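"""Stepped-wedge treatment layouts and the Hussey-Hughes linear mixed model.

A balanced complete-block stepped-wedge cluster randomised trial (SW-CRT)
observes ``C`` clusters over ``T`` time periods.  Every cluster starts in the
control condition, crosses to the intervention at a randomised period, and
finishes on the intervention; an equal (or as equal as possible) number of
clusters switches at each of periods ``2..T``.

The model used throughout for cross-sectional data is the Hussey-Hughes
linear mixed model

    y_ijk = mu + pi_j + tau * X_ij + c_i + eps_ijk

with a random cluster intercept ``c_i ~ N(0, sigma_c2)`` and residual
``eps_ijk ~ N(0, sigma_e2)``; ``pi_1 = 0`` for identifiability and ``tau`` is
the treatment effect of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InestimableEffectError, InvalidDesignError, InvalidScheduleError

__all__ = [
    "SWLayout",
    "VarianceComponents",
    "MixedModelSpec",
    "build_sw_layout",
    "build_hh_model",
    "layout_to_csv",
    "layout_from_csv",
]


@dataclass(frozen=True)
class SWLayout:
    """A C x T binary treatment-indicator matrix and its switch schedule.

    ``X[i, j] = 1`` iff cluster ``i`` receives the intervention in period
    ``j + 1`` (storage is 0-based; period labels are 1-based).  ``switches[s]``
    is the number of clusters that cross over at period ``s + 2``.
    """

    C: int
    T: int
    X: np.ndarray
    switches: tuple[int, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=int)
        if X.shape != (self.C, self.T):
            raise InvalidDesignError(f"X must be {self.C}x{self.T}, got {X.shape}")
        if not np.isin(X, (0, 1)).all():
            raise InvalidDesignError("X must be binary")
        if np.any(np.diff(X, axis=1) < 0):
            raise InvalidDesignError("clusters may never revert to control")
        if X[:, 0].any():
            raise InvalidDesignError("every cluster must begin in the control condition")
        if not X[:, -1].all():
            raise InvalidDesignError("every cluster must finish on the intervention")
        if sum(self.switches) != self.C:
            raise InvalidScheduleError("switch schedule must sum to C")
        object.__setattr__(self, "X", X)


@dataclass(frozen=True)
class VarianceComponents:
    """Between-cluster variance sigma_c2 >= 0 and residual variance sigma_e2 > 0."""

    sigma_c2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not self.sigma_e2 > 0:
            raise InvalidDesignError("sigma_e2 must be positive")
        if self.sigma_c2 < 0:
            raise InvalidDesignError("sigma_c2 must be non-negative")

    def scaled(self, factor: float) -> "VarianceComponents":
        return VarianceComponents(self.sigma_c2 * factor, self.sigma_e2 * factor)


@dataclass
class MixedModelSpec:
    """Design and covariance matrices of a linear mixed model y = D beta + Z u + eps.

    ``p`` is the (0-based) index of the treatment effect tau within beta.
    ``Sigma = Zmat G Zmat' + R`` is block-diagonal by cluster for the
    Hussey-Hughes structure; ``block_sizes`` records the block partition so
    downstream code can invert Sigma block-wise.
    """

    D: np.ndarray
    Zmat: np.ndarray
    G: np.ndarray
    R: np.ndarray
    Sigma: np.ndarray
    p: int
    block_sizes: tuple[int, ...] = field(default_factory=tuple)


def build_sw_layout(C: int, T: int, schedule=None) -> SWLayout:
    """Construct a balanced complete-block stepped-wedge layout.

    Parameters
    ----------
    C, T
        Cluster and period counts (C >= 1, T >= 2).
    schedule
        Optional length-(T-1) vector giving the number of clusters switching
        at each of periods 2..T.  The default distributes C as evenly as
        possible, assigning any remainder to the earliest steps.

    Rows of the returned ``X`` are sorted by switch time, earliest first.
    """
    if T < 2:
        raise InvalidDesignError("T must be at least 2")
    if C < 1:
        raise InvalidDesignError("C must be at least 1")
    steps = T - 1
    if schedule is None:
        base, rem = divmod(C, steps)
        schedule = tuple(base + (1 if s < rem else 0) for s in range(steps))
    else:
        schedule = tuple(int(s) for s in schedule)
        if len(schedule) != steps:
            raise InvalidScheduleError(f"schedule must have length T-1={steps}")
        if any(s < 0 for s in schedule):
            raise InvalidScheduleError("schedule entries must be non-negative")
        if sum(schedule) != C:
            raise InvalidScheduleError(f"schedule sums to {sum(schedule)}, expected C={C}")
    X = np.zeros((C, T), dtype=int)
    row = 0
    for step, n_switch in enumerate(schedule):
        X[row : row + n_switch, step + 1 :] = 1
        row += n_switch
    return SWLayout(C=C, T=T, X=X, switches=schedule)


def build_hh_model(layout: SWLayout, m: int, vc: VarianceComponents, t: int) -> MixedModelSpec:
    """Assemble D, Z, G, R and Sigma for the Hussey-Hughes model up to period t.

    The response vector stacks clusters, within cluster periods 1..t, within
    each cluster-period its m individuals.  Fixed effects are ordered
    (mu, pi_2, ..., pi_t, tau); random effects are the C cluster intercepts.
    """
    if not 1 <= t <= layout.T:
        raise InvalidDesignError(f"analysis period t={t} outside 1..{layout.T}")
    if m < 1:
        raise InvalidDesignError("m must be at least 1")
    if not layout.X[:, :t].any():
        raise InestimableEffectError(
            f"no cluster has received the intervention by period {t}; tau is inestimable"
        )
    C = layout.C
    n = m * C * t
    p_fix = 1 + (t - 1) + 1  # mu, pi_2..pi_t, tau
    D = np.zeros((n, p_fix))
    Zmat = np.zeros((n, C))
    row = 0
    for i in range(C):
        for j in range(t):
            for _ in range(m):
                D[row, 0] = 1.0
                if j >= 1:
                    D[row, j] = 1.0  # pi_{j+1} occupies column j
                D[row, p_fix - 1] = layout.X[i, j]
                Zmat[row, i] = 1.0
                row += 1
    G = vc.sigma_c2 * np.eye(C)
    R = vc.sigma_e2 * np.eye(n)
    Sigma = Zmat @ G @ Zmat.T + R
    return MixedModelSpec(
        D=D,
        Zmat=Zmat,
        G=G,
        R=R,
        Sigma=Sigma,
        p=p_fix - 1,
        block_sizes=(m * t,) * C,
    )


def layout_to_csv(layout: SWLayout, path) -> None:
    """Write the treatment-indicator matrix as headerless 0/1 CSV (C rows x T cols)."""
    np.savetxt(path, layout.X, fmt="%d", delimiter=",")


def layout_from_csv(path) -> SWLayout:
    """Read a headerless 0/1 CSV treatment-indicator matrix.

    The switch schedule is recovered from the column sums; rows need not be
    sorted by switch time and are kept in file order.
    """
    X = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=int))
    C, T = X.shape
    col_new = np.diff(np.concatenate([[0], X.sum(axis=0)]))
    switches = tuple(int(v) for v in col_new[1:]) if T >= 2 else ()
    return SWLayout(C=C, T=T, X=X, switches=switches)
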