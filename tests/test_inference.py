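"""Gaussian approximation, hyperparameter grid, full fits."""

import numpy as np
import pytest
import scipy.optimize
from scipy.special import gammaln

import stmrf
from stmrf.inference import (
    FIXED_EFFECT_PRECISION,
    ModelSpec,
    _Model,
    gaussian_approximation,
    hyper_posterior_grid,
)
from stmrf.panel import PanelData


def _bare_spec(**kw):
    base = dict(use_v=False, use_u=False, use_gamma=False, use_phi=False,
                interaction=None)
    base.update(kw)
    return ModelSpec(**base)


def _single_area_graph():
    return stmrf.build_adjacency([], ["a"])


def _cell_panel(O, N, e):
    return PanelData(O=np.array([[O]]), N=np.array([[N]]),
                     e=np.array([[e]]), X=np.zeros((1, 0)), area_ids=("a",))


class TestGaussianApproximation:
    def test_single_cell_mode_log2(self):
        panel = _cell_panel(2, 4, 1.0)
        ga = gaussian_approximation(_bare_spec(), panel,
                                    _single_area_graph(), {})
        # 1-D numerical oracle on the same objective
        def neg(b):
            return -(2 * b - np.exp(b) - 0.5 * FIXED_EFFECT_PRECISION * b**2)
        oracle = scipy.optimize.minimize_scalar(neg, bounds=(-5, 5),
                                                method="bounded").x
        assert abs(ga.x_mode[0] - oracle) < 1e-3
        assert abs(ga.x_mode[0] - np.log(2)) < 1e-3

    def test_null_data_flat_mode(self, toy_graph):
        # O = e everywhere: intercept and all effects near zero
        S, T = 5, 3
        N = np.full((S, T), 100)
        O = np.full((S, T), 10)
        e = stmrf.compute_expected_counts(O, N)
        panel = PanelData(O=O, N=N, e=e, X=np.zeros((S * T, 0)),
                          area_ids=tuple("abcde"))
        spec = ModelSpec(interaction=None)
        ga = gaussian_approximation(spec, panel, toy_graph,
                                    {"v": 0.5, "u": 0.5, "gamma": 0.5,
                                     "phi": 0.5})
        np.testing.assert_allclose(ga.x_mode, 0.0, atol=1e-6)

    def test_constraints_enforced(self, toy_panel, toy_graph):
        panel, _ = toy_panel
        spec = ModelSpec(interaction=None)
        ga = gaussian_approximation(spec, panel, toy_graph,
                                    {"v": 0.1, "u": 0.05, "gamma": 0.1,
                                     "phi": 0.02})
        assert ga.constraint_residual < 1e-8
        # per-component sums of v-hat are zero; the isolate is pinned
        model = _Model(spec, panel, toy_graph)
        v = ga.x_mode[model.x_slices["v"]]
        assert abs(v[:4].sum()) < 1e-8
        assert abs(v[4]) < 1e-8


class TestHyperPosteriorGrid:
    def test_weights_normalized(self, toy_panel, toy_graph):
        panel, _ = toy_panel
        grid = hyper_posterior_grid(ModelSpec(interaction=None), panel,
                                    toy_graph)
        assert abs(grid.weights.sum() - 1.0) < 1e-12
        assert len(grid.names) == 4

    def test_one_hyper_matches_quadrature_oracle(self):
        # 3 iid areas, one period: the evidence factorizes into 1-D
        # integrals per area nested inside an intercept integral
        g = stmrf.build_adjacency([], ["a", "b", "c"])
        O = np.array([[12], [30], [7]])
        N = np.array([[100], [150], [80]])
        e = stmrf.compute_expected_counts(O, N)
        panel = PanelData(O=O, N=N, e=e, X=np.zeros((3, 0)),
                          area_ids=("a", "b", "c"))
        spec = _bare_spec(use_u=True)
        grid = hyper_posterior_grid(spec, panel, g, n_per_dim=11, step=0.4)

        def log_evidence(theta):
            s2 = np.exp(-theta)
            b0s = np.linspace(-1.5, 1.5, 241)
            us = np.linspace(-6 * np.sqrt(s2), 6 * np.sqrt(s2), 401)
            du = us[1] - us[0]
            total = np.zeros_like(b0s)
            for i in range(3):
                eta = b0s[:, None] + us[None, :]
                lam = e[i, 0] * np.exp(eta)
                ll = O[i, 0] * np.log(lam) - lam - gammaln(O[i, 0] + 1)
                lp = ll - 0.5 * us**2 / s2 - 0.5 * np.log(2 * np.pi * s2)
                m = lp.max(axis=1, keepdims=True)
                total += (m[:, 0] + np.log(np.sum(np.exp(lp - m), axis=1) * du))
            db = b0s[1] - b0s[0]
            lp0 = total - 0.5 * FIXED_EFFECT_PRECISION * b0s**2
            m = lp0.max()
            return m + np.log(np.sum(np.exp(lp0 - m)) * db)

        a, b = ModelSpec().hyper_a, ModelSpec().hyper_b
        thetas = np.linspace(grid.mode - 2, grid.mode + 2, 81).ravel()
        post = np.array([log_evidence(t) + a * t - b * np.exp(t)
                         for t in thetas])
        oracle_mode = thetas[post.argmax()]
        step_size = 0.4 * grid.mode_sd[0]
        assert abs(grid.mode[0] - oracle_mode) < max(step_size, 0.1)

    def test_grid_refinement_stable(self, toy_panel, toy_graph):
        panel, _ = toy_panel
        spec = _bare_spec(use_u=True, use_gamma=True)
        # doubled resolution over the same span: halve the step
        g1 = hyper_posterior_grid(spec, panel, toy_graph, n_per_dim=5,
                                  step=0.85)
        g2 = hyper_posterior_grid(spec, panel, toy_graph, n_per_dim=9,
                                  step=0.425)
        m1 = g1.weights @ g1.theta
        m2 = g2.weights @ g2.theta
        np.testing.assert_allclose(m1, m2, rtol=0.02, atol=0.02)


class TestFit:
    def test_deterministic(self, toy_panel, toy_graph):
        panel, _ = toy_panel
        spec = ModelSpec(interaction=None)
        s1 = stmrf.fit(spec, panel, toy_graph, seed=0)
        s2 = stmrf.fit(spec, panel, toy_graph, seed=0)
        np.testing.assert_array_equal(s1.fixed_effects.values,
                                      s2.fixed_effects.values)
        np.testing.assert_array_equal(s1.eta_mean, s2.eta_mean)

    def test_null_panel_concentrates(self, default_graph):
        zero = {k: 0.0 for k in ("sigma2_u", "delta2_v", "sigma2_gamma",
                                 "sigma2_phi", "sigma2_psi")}
        panel, _ = stmrf.generate_panel(default_graph, T=4, k=0, hyper=zero,
                                        interaction=None,
                                        n_range=(4000, 8000), seed=17)
        s = stmrf.fit(ModelSpec(interaction=None), panel, default_graph)
        assert np.all(s.hyper["mean"] < 0.05)
        inside = np.mean((s.omega_mean > 0.9) & (s.omega_mean < 1.1))
        assert inside >= 0.95

    def test_interval_ordering_and_positive_rr(self, toy_panel, toy_graph):
        panel, _ = toy_panel
        s = stmrf.fit(ModelSpec(interaction=None), panel, toy_graph)
        fe = s.fixed_effects
        assert np.all(fe["q2.5"] <= fe["mean"])
        assert np.all(fe["mean"] <= fe["q97.5"])
        assert np.all(s.omega_mean > 0)

    def test_monotone_in_observed_count(self, toy_graph):
        panel, _ = stmrf.generate_panel(toy_graph, T=3, k=0, seed=3,
                                        interaction=None)
        spec = ModelSpec(interaction=None)
        s1 = stmrf.fit(spec, panel, toy_graph)
        O2 = panel.O.copy()
        O2[2, 1] += max(5, O2[2, 1] // 5)
        e2 = stmrf.compute_expected_counts(O2, panel.N)
        panel2 = PanelData(O=O2, N=panel.N, e=e2, X=panel.X,
                           area_ids=panel.area_ids)
        s2 = stmrf.fit(spec, panel2, toy_graph)
        cell = 1 * panel.S + 2
        assert s2.omega_mean[cell] >= s1.omega_mean[cell] * 0.999

    def test_split_by_component_fixed_effects(self, default_graph):
        panel, _ = stmrf.generate_panel(default_graph, T=4, k=2, seed=11,
                                        interaction=None)
        spec = ModelSpec(interaction=None, split_intercept=True,
                         split_covariates=True, split_spatial_variance=True)
        s = stmrf.fit(spec, panel, default_graph)
        C = default_graph.n_components
        assert len(s.fixed_effects) == C + 2 * C
        assert sum(n.startswith("variance[v[comp") for n in s.hyper.index) == C
        assert s.diagnostics["constraint_residual"] < 1e-8


class TestOrthogonality:
    def test_vhat_orthogonal_to_X_when_enabled(self, default_graph):
        panel, _ = stmrf.generate_panel(default_graph, T=4, k=1,
                                        beta=[0.3], seed=19,
                                        interaction=None)
        M_space = np.tile(np.eye(panel.S), (panel.T, 1))
        s_on = stmrf.fit(ModelSpec(interaction=None, orthogonalize=True),
                         panel, default_graph)
        dot_on = panel.X.T @ (M_space @ s_on.effect_means["v"])
        assert np.abs(dot_on).max() < 1e-8

        s_off = stmrf.fit(ModelSpec(interaction=None), panel, default_graph)
        dot_off = panel.X.T @ (M_space @ s_off.effect_means["v"])
        assert np.abs(dot_off).max() > 1e-6

    def test_rank_deficient_X_rejected(self):
        from stmrf.inference import apply_orthogonality
        X = np.ones((10, 2))  # duplicate columns
        X[:, 1] = X[:, 0]
        with pytest.raises(ValueError, match="rank deficient"):
            apply_orthogonality(X, np.eye(10))
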