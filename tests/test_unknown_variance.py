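import warnings

import numpy as np
import pytest
from scipy.optimize import brentq, minimize
from scipy.stats import norm
from scipy.stats import t as t_dist

from swgsd import (
    DegreesOfFreedom,
    InvalidDesignError,
    SimulationConfig,
    VarianceComponents,
    build_hh_model,
    build_sw_layout,
    dof_anova,
    empirical_rejection_rate,
    fit_hh,
    quantile_substitute,
    run_sequential_replicate,
    simulate_dataset,
    solve_design,
    stopping_distribution,
)
from swgsd.unknown_variance import _MeansFitter, _simulate_suffstats

from conftest import make_design


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "m, C, t, expected", [(70, 4, 5, 1391), (7, 20, 9, 1231), (104, 4, 2, 826)]
    )
    def test_anova_decomposition(self, m, C, t, expected):
        assert dof_anova(m, C, t) == expected

    def test_degenerate_is_an_error(self):
        with pytest.raises(InvalidDesignError):
            dof_anova(1, 2, 2)


class TestQuantileSubstitution:
    def _bounds(self, values, analyses):
        from swgsd.spending import Boundaries

        arr = np.asarray(values, dtype=float)
        return Boundaries(
            analyses=analyses, f=arr.copy(), e=arr.copy(),
            spent_typeI=np.zeros(arr.size), spent_typeII=np.zeros(arr.size),
        )

    def test_identity_in_large_nu_limit(self):
        b = self._bounds([1.6449], (5,))
        out = quantile_substitute(b, DegreesOfFreedom((5,), (10**7,)))
        assert out.e[0] == pytest.approx(1.6449, abs=1e-4)

    def test_zero_maps_to_zero(self):
        b = self._bounds([0.0], (5,))
        out = quantile_substitute(b, DegreesOfFreedom((5,), (10,)))
        assert out.e[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_root_finding_inversion(self):
        """b* preserves the upper-tail probability between the standard normal
        and the variance-1 t; cross-check by root-finding on the scaled-t CDF."""
        nu, b = 10, 1.6449
        bounds = self._bounds([b], (5,))
        out = quantile_substitute(bounds, DegreesOfFreedom((5,), (nu,)))
        scale = np.sqrt((nu - 2) / nu)
        b_star = brentq(
            lambda x: t_dist.cdf(x / scale, nu) - norm.cdf(b), -10, 10, xtol=1e-12
        )
        assert out.e[0] == pytest.approx(b_star, abs=1e-10)

    def test_infinite_boundaries_pass_through(self):
        b = self._bounds([-np.inf, 1.0], (3, 5))
        out = quantile_substitute(b, DegreesOfFreedom((3, 5), (50, 80)))
        assert np.isneginf(out.f[0])

    def test_small_nu_rejected(self):
        b = self._bounds([1.0], (5,))
        with pytest.raises(InvalidDesignError):
            quantile_substitute(b, DegreesOfFreedom((5,), (2,)))


class TestSimulateDataset:
    def test_noiseless_returns_scaled_indicators(self):
        lay = build_sw_layout(3, 4)
        rng = np.random.default_rng(0)
        y = simulate_dataset(lay, 2, 0.7, VarianceComponents(0.0, 1e-30), rng)
        np.testing.assert_allclose(y - 0.7 * lay.X[:, :, None], 0.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        lay = build_sw_layout(3, 4)
        vc = VarianceComponents(0.1, 0.5)
        y1 = simulate_dataset(lay, 3, 0.2, vc, np.random.default_rng(42))
        y2 = simulate_dataset(lay, 3, 0.2, vc, np.random.default_rng(42))
        np.testing.assert_array_equal(y1, y2)

    def test_law_of_large_numbers(self):
        lay = build_sw_layout(50, 4)
        vc = VarianceComponents(0.0, 0.51)
        y = simulate_dataset(lay, 600, 0.0, vc, np.random.default_rng(7))  # 120k values
        assert y.mean() == pytest.approx(0.0, abs=0.01)
        within = y - y.mean(axis=2, keepdims=True)
        assert (within**2).sum() / (y.size - 50 * 4) == pytest.approx(0.51, rel=0.02)


def dense_fit(y, lay, reml):
    """Independent oracle: optimise the dense individual-level (restricted)
    log-likelihood built from the full covariance matrix."""
    C, t, m = y.shape
    yv = y.reshape(-1)
    mm = build_hh_model(lay, m, VarianceComponents(0.1, 1.0), t)
    D, Z = mm.D, mm.Zmat

    def nll(par):
        sc2, se2 = np.exp(par)
        Sig = se2 * np.eye(yv.size) + sc2 * (Z @ Z.T)
        sign, logdet = np.linalg.slogdet(Sig)
        Si_D = np.linalg.solve(Sig, D)
        M = D.T @ Si_D
        beta = np.linalg.solve(M, Si_D.T @ yv)
        r = yv - D @ beta
        val = logdet + r @ np.linalg.solve(Sig, r)
        if reml:
            val += np.linalg.slogdet(M)[1]
        return val

    res = minimize(
        nll, [np.log(0.05), np.log(0.5)], method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000),
    )
    sc2, se2 = np.exp(res.x)
    Sig = se2 * np.eye(yv.size) + sc2 * (Z @ Z.T)
    Si_D = np.linalg.solve(Sig, D)
    beta = np.linalg.solve(D.T @ Si_D, Si_D.T @ yv)
    return beta[-1], sc2, se2


class TestFitHH:
    def test_matches_dense_likelihood_oracle(self, rng):
        lay = build_sw_layout(4, 5)
        vc = VarianceComponents(0.08, 0.51)
        for _ in range(3):
            y = simulate_dataset(lay, 3, 0.2, vc, rng)
            for method, reml in (("ML", False), ("REML", True)):
                tau_b, sc2_b, se2_b = dense_fit(y, lay, reml)
                fit = fit_hh(y, lay, method)
                assert fit.tau_hat == pytest.approx(tau_b, abs=1e-5)
                assert fit.sigma_c2_hat == pytest.approx(sc2_b, abs=1e-5)
                assert fit.sigma_e2_hat == pytest.approx(se2_b, abs=1e-5)

    def test_matches_statsmodels_mixedlm(self):
        import pandas as pd
        import statsmodels.formula.api as smf

        lay = build_sw_layout(6, 4)
        vc = VarianceComponents(0.4, 1.0)  # interior optimum, away from the boundary
        y = simulate_dataset(lay, 4, 0.3, vc, np.random.default_rng(5))
        C, T, m = y.shape
        df = pd.DataFrame(
            {
                "y": y.reshape(-1),
                "cluster": np.repeat(np.arange(C), T * m),
                "period": np.tile(np.repeat(np.arange(T), m), C),
                "x": np.repeat(lay.X, m).astype(float),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm("y ~ C(period) + x", df, groups=df["cluster"]).fit(reml=True)
        ours = fit_hh(y, lay, "REML")
        assert ours.tau_hat == pytest.approx(sm_fit.params["x"], abs=1e-4)
        assert ours.sigma_c2_hat == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), abs=1e-3)
        assert ours.sigma_e2_hat == pytest.approx(sm_fit.scale, abs=1e-4)

    def test_near_noiseless_recovers_tau(self):
        lay = build_sw_layout(4, 5)
        rng = np.random.default_rng(1)
        y = 0.5 * lay.X[:, :, None] + 1e-6 * rng.normal(size=(4, 5, 3))
        for method in ("ML", "REML"):
            assert fit_hh(y, lay, method).tau_hat == pytest.approx(0.5, abs=1e-4)

    def test_reml_recovers_variances_and_ml_is_biased_down(self):
        """Parameter recovery at the Scenario-1 truth, plus the classical
        ML-below-REML ordering of the cluster-variance estimates."""
        lay = build_sw_layout(4, 5)
        vc = VarianceComponents(0.02, 0.51)
        m, n_reps = 70, 400
        fitter = _MeansFitter(lay, m, 5)
        rng = np.random.default_rng(99)
        se2_reml, sc2_reml, sc2_ml = [], [], []
        for _ in range(n_reps):
            means, ssw = _simulate_suffstats(lay, m, 0.0, vc, rng)
            s = float(ssw.sum())
            fr = fitter.fit(means, s, "REML")
            fm = fitter.fit(means, s, "ML")
            se2_reml.append(fr.sigma_e2_hat)
            sc2_reml.append(fr.sigma_c2_hat)
            sc2_ml.append(fm.sigma_c2_hat)
        se = np.std(se2_reml) / np.sqrt(n_reps)
        assert abs(np.mean(se2_reml) - 0.51) <= 3 * se
        assert np.mean(sc2_ml) < np.mean(sc2_reml)

    def test_observed_information_equals_gls_variance(self, rng):
        """The closed form at the fitted variances equals the reciprocal GLS
        sampling variance of tau_hat from the fitted model."""
        lay = build_sw_layout(4, 5)
        y = simulate_dataset(lay, 4, 0.2, VarianceComponents(0.1, 0.6), rng)
        fit = fit_hh(y, lay, "REML")
        model = build_hh_model(
            lay, 4, VarianceComponents(fit.sigma_c2_hat, fit.sigma_e2_hat), 5
        )
        from swgsd import information_general

        assert fit.info_hat == pytest.approx(information_general(model), rel=1e-8)


class TestSequentialMonitoring:
    def test_stopping_rules_applied_verbatim(self, scenario1):
        spec = make_design(scenario1, (2, 3, 4, 5), "both", 0.5, 0.5, m=104)
        spec, solved = solve_design(spec)
        rng = np.random.default_rng(3)
        big = simulate_dataset(spec.layout, 104, 3.0, VarianceComponents(0.001, 0.05), rng)
        assert run_sequential_replicate(big, spec, solved.boundaries, "REML") == (2, 1)
        small = simulate_dataset(spec.layout, 104, -3.0, VarianceComponents(0.001, 0.05), rng)
        assert run_sequential_replicate(small, spec, solved.boundaries, "REML") == (2, 0)

    def test_known_variance_monitoring_recovers_design_alpha_and_power(self, design1_s1, rng):
        """Central cross-validation: simulating the canonical Z law and applying
        the stopping rules reproduces the quadrature operating characteristics."""
        from swgsd import simulate_known_variance

        spec, solved = design1_s1
        n = 100_000
        for tau, target in ((0.0, 0.05), (0.2, None)):
            dist = stopping_distribution(spec, solved.boundaries, solved.profile, tau)
            omega, psi = simulate_known_variance(solved.profile, solved.boundaries, tau, n, rng)
            rate = psi.mean()
            se = np.sqrt(dist.reject_prob * (1 - dist.reject_prob) / n)
            assert abs(rate - dist.reject_prob) <= 3 * se
            if target is not None:
                assert abs(rate - target) <= 3 * se

    def test_empirical_rate_is_deterministic_given_seed(self, scenario1):
        spec = make_design(scenario1, (5,), "none", m=70)
        spec, solved = solve_design(spec)
        cfg = dict(
            design=spec, boundaries=solved.boundaries, true_vc=scenario1["vc"],
            tau_true=0.0, method="REML", adjust=False, n_reps=300, seed=123,
        )
        r1, _, t1 = empirical_rejection_rate(SimulationConfig(**cfg))
        r2, _, t2 = empirical_rejection_rate(SimulationConfig(**cfg))
        assert r1 == r2
        assert t1.equals(t2)
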