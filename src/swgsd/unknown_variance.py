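"""Unknown-variance monitoring: quantile substitution and Monte-Carlo validation.

Designs are calibrated assuming the variance components are known.  In
practice each interim analysis re-estimates them (by ML or REML) and monitors
Z_t = tau_hat * sqrt(I_hat_t) with the observed information, which can
inflate the type-I error.  Two remedies are studied here:

* quantile substitution: replace each normal-based boundary b by b* so that
  the upper-tail probability is preserved between the standard normal and a
  variance-1 (scaled) Student t with nu_t = m*C*t - C - t degrees of freedom,
  the classical ANOVA decomposition for the balanced design;
* REML rather than ML variance estimation.

The Monte-Carlo engine simulates Hussey-Hughes trials (mu = pi_j = 0), fits
the model at each scheduled analysis, applies the stopping rules, and reports
empirical rejection rates with binomial standard errors.

Fitting operates on the per-cell sufficient statistics - cluster-period means
plus the pooled within-cell sum of squares - which give estimates identical
to an individual-level fit at a fraction of the cost.  The (restricted)
likelihood is profiled down to a bounded scalar minimisation over the
cell-level variance ratio lambda = m * sigma_c2 / sigma_e2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from scipy.stats import t as t_dist

from .errors import ConfigurationError, InvalidDesignError, NumericalError
from .information import information_closed_form
from .layout_model import SWLayout, VarianceComponents
from .spending import Boundaries

__all__ = [
    "DegreesOfFreedom",
    "SimulationConfig",
    "FitResult",
    "dof_anova",
    "quantile_substitute",
    "simulate_dataset",
    "fit_hh",
    "run_sequential_replicate",
    "empirical_rejection_rate",
    "simulate_known_variance",
]

_LAMBDA_BRACKETS = (1e2, 1e5, 1e8)  # successive upper bounds for the variance-ratio search


@dataclass(frozen=True)
class DegreesOfFreedom:
    """ANOVA degrees of freedom nu_t = m*C*t - C - t per scheduled analysis."""

    analyses: tuple[int, ...]
    nu: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.nu):
            raise InvalidDesignError("all degrees of freedom must be >= 1")

    @classmethod
    def anova(cls, m: int, C: int, analyses) -> "DegreesOfFreedom":
        analyses = tuple(int(t) for t in analyses)
        return cls(analyses=analyses, nu=tuple(dof_anova(m, C, t) for t in analyses))


@dataclass(frozen=True)
class FitResult:
    """Point estimates, observed information and Wald statistic from one fit."""

    tau_hat: float
    sigma_c2_hat: float
    sigma_e2_hat: float
    info_hat: float
    Z: float
    converged: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol for one empirical-rejection-rate study.

    The design and its boundaries come from upstream, solved under the
    *assumed* variance components; data are generated under the *true* ones.
    """

    design: "DesignSpec"  # noqa: F821 - duck-typed, resolved m required
    boundaries: Boundaries
    true_vc: VarianceComponents
    tau_true: float
    method: str = "REML"
    adjust: bool = False
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ML", "REML"):
            raise ConfigurationError('method must be "ML" or "REML"')
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be at least 1")
        if self.design.m == "search":
            raise ConfigurationError("design must have m resolved before simulation")


def dof_anova(m: int, C: int, t: int) -> int:
    """Classical balanced-ANOVA degrees of freedom m*C*t - C - t."""
    nu = m * C * t - C - t
    if nu < 1:
        raise InvalidDesignError(f"degrees of freedom {nu} < 1 for m={m}, C={C}, t={t}")
    return int(nu)


def _scaled_t_ppf(p: float, nu: float) -> float:
    """Quantile of the Student t scaled to unit variance (requires nu > 2)."""
    return float(t_dist.ppf(p, nu) * np.sqrt((nu - 2.0) / nu))


def quantile_substitute(boundaries: Boundaries, dofs: DegreesOfFreedom) -> Boundaries:
    """Map each finite boundary to the variance-1 t quantile with equal upper tail.

    Infinite boundaries pass through unchanged.  nu_t <= 2 is rejected since
    the variance-1 scaling of the t distribution is undefined there.
    """
    if tuple(dofs.analyses) != tuple(boundaries.analyses):
        raise ConfigurationError("degrees of freedom and boundaries use different schedules")
    if any(n <= 2 for n in dofs.nu):
        raise InvalidDesignError("quantile substitution requires nu > 2 at every analysis")
    f_new = np.array(
        [
            _scaled_t_ppf(norm.cdf(b), nu) if np.isfinite(b) else b
            for b, nu in zip(boundaries.f, dofs.nu)
        ]
    )
    e_new = np.array(
        [
            _scaled_t_ppf(norm.cdf(b), nu) if np.isfinite(b) else b
            for b, nu in zip(boundaries.e, dofs.nu)
        ]
    )
    return boundaries.replace_bounds(f_new, e_new)


def simulate_dataset(
    layout: SWLayout, m: int, tau_true: float, vc: VarianceComponents, rng
) -> np.ndarray:
    """Individual-level Hussey-Hughes trial data, shape (C, T, m), with mu = pi_j = 0."""
    c = rng.normal(0.0, np.sqrt(vc.sigma_c2), size=layout.C)
    eps = rng.normal(0.0, np.sqrt(vc.sigma_e2), size=(layout.C, layout.T, m))
    return tau_true * layout.X[:, :, None] + c[:, None, None] + eps


def _simulate_suffstats(layout: SWLayout, m: int, tau_true: float, vc: VarianceComponents, rng):
    """Cluster-period means and within-cell sums of squares, sampled exactly.

    means[i, j] ~ tau*X_ij + c_i + Normal(0, sigma_e2/m) and
    ssw[i, j] ~ sigma_e2 * chi2_{m-1}, independent - the joint law of the
    sufficient statistics of the individual-level model.
    """
    c = rng.normal(0.0, np.sqrt(vc.sigma_c2), size=layout.C)
    means = (
        tau_true * layout.X
        + c[:, None]
        + rng.normal(0.0, np.sqrt(vc.sigma_e2 / m), size=(layout.C, layout.T))
    )
    if m > 1:
        ssw = vc.sigma_e2 * rng.chisquare(m - 1, size=(layout.C, layout.T))
    else:
        ssw = np.zeros((layout.C, layout.T))
    return means, ssw


class _MeansFitter:
    """Profiled ML/REML fit of the Hussey-Hughes model at one analysis period.

    Precomputes the cell-level design cross-products for the first ``t``
    periods of a layout so each replicate's fit reduces to a scalar
    minimisation over lambda = m*sigma_c2/sigma_e2 with O(p^2) work per
    evaluation.
    """

    def __init__(self, layout: SWLayout, m: int, t: int):
        self.layout = layout
        self.m = int(m)
        self.t = int(t)
        self.C = layout.C
        p = t + 1  # mu, pi_2..pi_t, tau
        D = np.zeros((self.C, t, p))
        D[:, :, 0] = 1.0
        for j in range(1, t):
            D[:, j, j] = 1.0
        D[:, :, p - 1] = layout.X[:, :t]
        self.p = p
        self.D = D
        self.Dsum = D.sum(axis=1)  # (C, p)
        self.M0 = np.einsum("cti,ctj->ij", D, D)
        self.M1 = np.einsum("ci,cj->ij", self.Dsum, self.Dsum)

    def _profiled(self, lam: float, y: np.ndarray, ssw_total: float, reml: bool):
        t, m, C = self.t, self.m, self.C
        clam = lam / (1.0 + t * lam)
        M = self.M0 - clam * self.M1
        ysum = y.sum(axis=1)  # (C,)
        v = np.einsum("cti,ct->i", self.D, y) - clam * self.Dsum.T @ ysum
        beta = np.linalg.solve(M, v)
        resid = y - np.einsum("ctp,p->ct", self.D, beta)
        rsum = resid.sum(axis=1)
        Q = float((resid * resid).sum() - clam * (rsum * rsum).sum())
        ss = ssw_total + m * Q
        n_total = C * t * m
        if reml:
            sign, logdet = np.linalg.slogdet(M)
            obj = (n_total - self.p) * np.log(ss) + C * np.log1p(t * lam) + logdet
            denom = n_total - self.p
        else:
            obj = n_total * np.log(ss) + C * np.log1p(t * lam)
            denom = n_total
        return obj, beta, ss / denom

    def fit(self, means: np.ndarray, ssw_total: float, method: str = "REML") -> FitResult:
        reml = method == "REML"
        obj = lambda lam: self._profiled(lam, means, ssw_total, reml)[0]  # noqa: E731
        best = None
        converged = False
        for hi in _LAMBDA_BRACKETS:
            res = minimize_scalar(obj, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-8})
            if res.success and np.isfinite(res.fun):
                best = res
                converged = True
                # accept unless the optimum is pinned at the bracket top
                if res.x < 0.99 * hi:
                    break
        if best is None:
            raise NumericalError("variance-ratio optimisation failed to converge")
        lam = float(best.x)
        if obj(0.0) <= best.fun:  # boundary solution sigma_c2 = 0
            lam = 0.0
        _, beta, s_hat = self._profiled(lam, means, ssw_total, reml)
        sigma_e2 = float(s_hat)
        sigma_c2 = float(lam * sigma_e2 / self.m)
        vc_hat = VarianceComponents(max(sigma_c2, 0.0), sigma_e2)
        info = information_closed_form(self.layout, self.t, self.m, vc_hat)
        tau_hat = float(beta[-1])
        return FitResult(
            tau_hat=tau_hat,
            sigma_c2_hat=vc_hat.sigma_c2,
            sigma_e2_hat=vc_hat.sigma_e2,
            info_hat=info,
            Z=tau_hat * np.sqrt(info),
            converged=converged,
        )


def fit_hh(y: np.ndarray, layout: SWLayout, method: str = "REML") -> FitResult:
    """Fit the Hussey-Hughes model to individual-level data for periods 1..t.

    ``y`` has shape (C, t, m); the fit collapses to cluster-period means and
    the pooled within-cell sum of squares, which are sufficient.
    """
    if method not in ("ML", "REML"):
        raise ConfigurationError('method must be "ML" or "REML"')
    C, t, m = y.shape
    if C != layout.C or not 1 <= t <= layout.T:
        raise ConfigurationError("data shape inconsistent with the layout")
    means = y.mean(axis=2)
    ssw_total = float(((y - means[:, :, None]) ** 2).sum())
    return _MeansFitter(layout, m, t).fit(means, ssw_total, method)


def run_sequential_replicate(dataset: np.ndarray, design, boundaries: Boundaries, method: str = "REML"):
    """Walk one trial through the analysis schedule; return (omega, psi).

    ``dataset`` is the full (C, T, m) array; at each scheduled analysis t the
    model is refitted to periods 1..t and the stopping rules applied: accept
    iff Z <= f_t, reject iff Z > e_t, forced decision at the final analysis.
    """
    analyses = boundaries.analyses
    for k, t in enumerate(analyses):
        fit = fit_hh(dataset[:, :t, :], design.layout, method)
        if fit.Z <= boundaries.f[k]:
            return t, 0
        if fit.Z > boundaries.e[k]:
            return t, 1
    return analyses[-1], 0  # unreachable when f_T == e_T; kept for safety


def empirical_rejection_rate(config: SimulationConfig):
    """Empirical rejection rate over simulated trials.

    Returns ``(rate, se, table)`` where ``table`` counts stopping analyses and
    decisions.  Replicates use independent spawned random substreams, so the
    result is deterministic given ``seed`` and embarrassingly parallel.
    Non-convergent fits are flagged; affected replicates are excluded when
    they are at most 0.1% of the total and an error is raised otherwise.
    """
    design = config.design
    layout = design.layout
    m = int(design.m)
    bounds = config.boundaries
    if config.adjust:
        bounds = quantile_substitute(bounds, DegreesOfFreedom.anova(m, layout.C, bounds.analyses))
    analyses = bounds.analyses
    fitters = [_MeansFitter(layout, m, t) for t in analyses]
    counts = np.zeros((len(analyses), 2), dtype=int)
    n_flagged = 0
    streams = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    for stream in streams:
        rng = np.random.default_rng(stream)
        means, ssw = _simulate_suffstats(layout, m, config.tau_true, config.true_vc, rng)
        ssw_cum = np.cumsum(ssw.sum(axis=0))
        flagged = False
        for k, (t, fitter) in enumerate(zip(analyses, fitters)):
            try:
                fit = fitter.fit(means[:, :t], float(ssw_cum[t - 1]), config.method)
            except NumericalError:
                flagged = True
                break
            if not fit.converged:
                flagged = True
                break
            if fit.Z <= bounds.f[k]:
                counts[k, 0] += 1
                break
            if fit.Z > bounds.e[k]:
                counts[k, 1] += 1
                break
        if flagged:
            n_flagged += 1
    if n_flagged > 0.001 * config.n_reps:
        raise NumericalError(f"{n_flagged} non-convergent replicates out of {config.n_reps}")
    n_used = config.n_reps - n_flagged
    rate = counts[:, 1].sum() / n_used
    se = float(np.sqrt(rate * (1.0 - rate) / n_used))
    table = pd.DataFrame(
        {
            "analysis_period": analyses,
            "stop_accept": counts[:, 0],
            "stop_reject": counts[:, 1],
        }
    )
    return float(rate), se, table


def simulate_known_variance(profile, boundaries: Boundaries, tau: float, n_reps: int, rng):
    """Vectorised known-variance Z-path simulation; returns (omega, psi) arrays.

    The Z statistics are drawn exactly from their canonical multivariate
    normal law (independent score increments), providing a Monte-Carlo oracle
    for the quadrature-based stopping distribution.
    """
    info = np.asarray(profile.info, dtype=float)
    K = info.size
    dI = np.diff(np.concatenate([[0.0], info]))
    incr = rng.normal(tau * dI, np.sqrt(dI), size=(n_reps, K))
    Z = np.cumsum(incr, axis=1) / np.sqrt(info)
    omega = np.full(n_reps, -1, dtype=int)
    psi = np.zeros(n_reps, dtype=int)
    active = np.ones(n_reps, dtype=bool)
    for k in range(K):
        lower = active & (Z[:, k] <= boundaries.f[k])
        upper = active & (Z[:, k] > boundaries.e[k])
        omega[lower] = k
        psi[lower] = 0
        omega[upper] = k
        psi[upper] = 1
        active &= ~(lower | upper)
    return omega, psi
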