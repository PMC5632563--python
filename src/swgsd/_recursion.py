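"""First-crossing probabilities for sequential Z statistics.

Under the canonical joint distribution, the score statistics
S_k = Z_k * sqrt(I_k) have independent Gaussian increments,
S_k - S_{k-1} ~ N(tau * (I_k - I_{k-1}), I_k - I_{k-1}).  Stopping-region
probabilities are therefore computed by the classical group-sequential
recursion: propagate the sub-density of paths still inside the continuation
region (f_k, e_k] analysis by analysis, integrating with deterministic
Gauss-Legendre quadrature on the score scale.

Grids are truncated at +/- 8 marginal standard deviations around the drifted
mean, which discards O(1e-15) probability mass; crossing probabilities use
exact normal tail functions so boundary values far outside the grid remain
well-defined.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

N_NODES = 192  # Gauss-Legendre nodes per stage
_TRUNC = 8.0  # grid half-width in marginal standard deviations


class PathState:
    """Continuation sub-density of the score process after the analyses absorbed so far.

    Advance analysis by analysis with :meth:`advance`; query the first-crossing
    probabilities of candidate boundaries at the *next* analysis with
    :meth:`crossing_lower` / :meth:`crossing_upper` (these do not mutate state,
    so they are cheap inside a boundary root-finder).
    """

    def __init__(self, tau: float, info, n_nodes: int = N_NODES):
        self.tau = float(tau)
        self.info = np.asarray(info, dtype=float)
        self.n_nodes = int(n_nodes)
        self.k = 0  # number of analyses already absorbed
        self._nodes: np.ndarray | None = None  # score-scale quadrature nodes
        self._wdens: np.ndarray | None = None  # quadrature weight * sub-density
        self._gl_x, self._gl_w = np.polynomial.legendre.leggauss(self.n_nodes)

    # -- geometry -------------------------------------------------------------
    def _increment(self):
        """(mean, sd) of the score increment into the next analysis."""
        k = self.k
        dI = self.info[k] - (self.info[k - 1] if k > 0 else 0.0)
        return self.tau * dI, np.sqrt(dI)

    def _shifted(self, mu_inc, x_prev):
        """Means of S_k given the previous continuation nodes."""
        if self.k == 0:
            return np.array([mu_inc])
        return x_prev + mu_inc

    # -- crossing probabilities at the next analysis ---------------------------
    def crossing_upper(self, e_k: float) -> float:
        """P(path in continuation through analysis k-1, then Z_k > e_k)."""
        return self._crossing(e_k, upper=True)

    def crossing_lower(self, f_k: float) -> float:
        """P(path in continuation through analysis k-1, then Z_k <= f_k)."""
        return self._crossing(f_k, upper=False)

    def _crossing(self, bound: float, upper: bool) -> float:
        k = self.k
        sqrtI = np.sqrt(self.info[k])
        mu_inc, sd_inc = self._increment()
        if not np.isfinite(bound):
            if upper:
                return 0.0 if bound > 0 else self.mass()
            return 0.0 if bound < 0 else self.mass()
        score_bound = bound * sqrtI
        if k == 0:
            z = (score_bound - mu_inc) / sd_inc
            return float(norm.sf(z) if upper else norm.cdf(z))
        if self._wdens is None or self._wdens.size == 0:
            return 0.0
        z = (score_bound - self._nodes - mu_inc) / sd_inc
        tail = norm.sf(z) if upper else norm.cdf(z)
        return float(self._wdens @ tail)

    def mass(self) -> float:
        """Probability the path is still in the continuation region."""
        if self.k == 0:
            return 1.0
        if self._wdens is None or self._wdens.size == 0:
            return 0.0
        return float(self._wdens.sum())

    # -- state update ----------------------------------------------------------
    def advance(self, f_k: float, e_k: float) -> None:
        """Absorb analysis k with continuation region (f_k, e_k] on the Z scale."""
        k = self.k
        I_k = self.info[k]
        sqrtI = np.sqrt(I_k)
        mu_marg = self.tau * I_k
        lo = max(f_k * sqrtI, mu_marg - _TRUNC * sqrtI) if np.isfinite(f_k) else mu_marg - _TRUNC * sqrtI
        hi = min(e_k * sqrtI, mu_marg + _TRUNC * sqrtI) if np.isfinite(e_k) else mu_marg + _TRUNC * sqrtI
        if hi <= lo or (k > 0 and (self._wdens is None or self._wdens.size == 0)):
            self._nodes = np.empty(0)
            self._wdens = np.empty(0)
            self.k += 1
            return
        half = 0.5 * (hi - lo)
        nodes = 0.5 * (hi + lo) + half * self._gl_x
        weights = half * self._gl_w
        mu_inc, sd_inc = self._increment()
        if k == 0:
            dens = norm.pdf(nodes, loc=mu_inc, scale=sd_inc)
        else:
            diff = nodes[:, None] - self._nodes[None, :] - mu_inc
            dens = norm.pdf(diff / sd_inc) / sd_inc @ self._wdens
        self._nodes = nodes
        self._wdens = weights * dens
        self.k += 1


def first_crossing_probs(info, f, e, tau: float, n_nodes: int = N_NODES):
    """First-exit probabilities at each analysis.

    Returns ``(p_lower, p_upper)`` where ``p_lower[k]`` is the probability the
    path stays in (f, e] at analyses 0..k-1 and exits with Z_k <= f_k at
    analysis k (early acceptance), and ``p_upper[k]`` the analogous
    first-upper-exit probability (early rejection).  With f[-1] == e[-1] the
    two arrays sum to 1 up to quadrature error.
    """
    info = np.asarray(info, dtype=float)
    f = np.asarray(f, dtype=float)
    e = np.asarray(e, dtype=float)
    K = info.size
    state = PathState(tau, info, n_nodes)
    p_lower = np.zeros(K)
    p_upper = np.zeros(K)
    for k in range(K):
        p_lower[k] = state.crossing_lower(f[k])
        p_upper[k] = state.crossing_upper(e[k])
        if k < K - 1:
            state.advance(f[k], e[k])
    return p_lower, p_upper
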