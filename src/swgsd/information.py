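"""Statistical information for the treatment effect at each interim analysis.

Two routes are provided and agree to numerical precision:

* the Hussey-Hughes closed form, written in terms of the treated-cell
  summaries U, V, W of the layout restricted to the first ``t`` periods with
  cell-level variance ``sigma2 = sigma_e2 / m``::

      I_t = [(sigma2 + t*sigma_c2)(C*U - W) + sigma_c2*(U^2 - C*V)]
            / [C*sigma2*(sigma2 + t*sigma_c2)]

* the general GLS route ``I_t = 1 / [(D' Sigma^-1 D)^-1]_{tau,tau}`` for an
  arbitrary linear mixed model, with Moore-Penrose generalised inverses when
  the fixed-effect cross-product is rank-deficient.

The sequential Wald statistics Z_t = tau_hat * sqrt(I_t) follow the canonical
joint distribution: E(Z_t) = tau*sqrt(I_t) and
cov(Z_ti, Z_tj) = sqrt(I_ti / I_tj) for ti <= tj, collected here in the
correlation matrix Lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import ConfigurationError, InestimableEffectError, InvalidDesignError
from .layout_model import MixedModelSpec, SWLayout, VarianceComponents

__all__ = [
    "UVWSummaries",
    "InformationProfile",
    "uvw_summaries",
    "information_closed_form",
    "information_general",
    "information_profile",
]


@dataclass(frozen=True)
class UVWSummaries:
    """Treated cluster-period counts over the first t periods.

    U: total treated cluster-periods; V: sum over clusters of the squared
    per-cluster treated count; W: sum over periods of the squared per-period
    treated count.
    """

    U: int
    V: int
    W: int


@dataclass(frozen=True)
class InformationProfile:
    """Information levels at each analysis and the implied Z covariance Lambda."""

    analyses: tuple[int, ...]
    info: np.ndarray
    Lambda: np.ndarray

    @property
    def fractions(self) -> np.ndarray:
        """Information fractions I_t / I_T used by the spending functions."""
        return self.info / self.info[-1]


def uvw_summaries(layout: SWLayout, t: int) -> UVWSummaries:
    """Compute U, V, W over columns 1..t of the treatment-indicator matrix."""
    if not 1 <= t <= layout.T:
        raise InvalidDesignError(f"analysis period t={t} outside 1..{layout.T}")
    Xt = layout.X[:, :t]
    row_tot = Xt.sum(axis=1)
    col_tot = Xt.sum(axis=0)
    return UVWSummaries(
        U=int(Xt.sum()), V=int((row_tot**2).sum()), W=int((col_tot**2).sum())
    )


def information_closed_form(
    layout: SWLayout, t: int, m: float, vc: VarianceComponents
) -> float:
    """Closed-form Hussey-Hughes information I_t with sigma2 = sigma_e2/m.

    ``m`` may be a non-integer during the continuous sample-size search.
    """
    s = uvw_summaries(layout, t)
    C = layout.C
    sigma2 = vc.sigma_e2 / m
    a = sigma2 + t * vc.sigma_c2
    num = a * (C * s.U - s.W) + vc.sigma_c2 * (s.U**2 - C * s.V)
    den = C * sigma2 * a
    info = num / den
    if not info > 0:
        raise InestimableEffectError(
            f"information non-positive at t={t}; no treated cluster-period contrast"
        )
    return float(info)


def _solve_sigma(model: MixedModelSpec, B: np.ndarray) -> np.ndarray:
    """Sigma^-1 B, exploiting the per-cluster block structure when recorded."""
    if model.block_sizes and sum(model.block_sizes) == model.Sigma.shape[0]:
        out = np.empty_like(B, dtype=float)
        start = 0
        for size in model.block_sizes:
            stop = start + size
            out[start:stop] = scipy.linalg.solve(
                model.Sigma[start:stop, start:stop], B[start:stop], assume_a="pos"
            )
            start = stop
        return out
    return scipy.linalg.solve(model.Sigma, B, assume_a="pos")


def information_general(model: MixedModelSpec) -> float:
    """GLS information for tau: reciprocal (p,p) entry of a g-inverse of D'Sigma^-1 D."""
    D = model.D
    M = D.T @ _solve_sigma(model, D)
    M = (M + M.T) / 2.0
    Minv = np.linalg.pinv(M, hermitian=True)
    # tau is estimable iff e_p lies in the range of M
    e_p = np.zeros(M.shape[0])
    e_p[model.p] = 1.0
    if not np.allclose(M @ (Minv @ e_p), e_p, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise InestimableEffectError("tau is not estimable from this model")
    var_tau = Minv[model.p, model.p]
    if not var_tau > 0:
        raise InestimableEffectError("variance of tau_hat is not positive")
    return float(1.0 / var_tau)


def information_profile(
    layout: SWLayout, analyses, m: float, vc: VarianceComponents
) -> InformationProfile:
    """Information vector over an analysis schedule plus the Z correlation Lambda."""
    analyses = tuple(int(t) for t in analyses)
    if list(analyses) != sorted(set(analyses)):
        raise ConfigurationError("analysis schedule must be strictly increasing")
    if analyses[-1] != layout.T:
        raise ConfigurationError("the final analysis must be at period T")
    info = np.array([information_closed_form(layout, t, m, vc) for t in analyses])
    Lambda = _lambda_from_info(info)
    return InformationProfile(analyses=analyses, info=info, Lambda=Lambda)


def _lambda_from_info(info: np.ndarray) -> np.ndarray:
    """Canonical Z correlation: Lambda[i, j] = sqrt(I_i / I_j) for i <= j."""
    info = np.asarray(info, dtype=float)
    ratio = np.sqrt(np.minimum.outer(info, info) / np.maximum.outer(info, info))
    return ratio
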