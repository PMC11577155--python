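"""MAP reconstruction (inexact Newton-CG) and expected-error estimation."""

import numpy as np
import pytest

from pactoed.geometry import integrate
from pactoed.map_recon import (MapSolverConfig, expected_mse, map_estimate)
from pactoed.linear_gaussian import DenseGaussianPrior, LinearGaussianModel

AREA = 25 * np.pi


def test_linear_gaussian_map_is_posterior_mean():
    rng = np.random.default_rng(0)
    n, K = 25, 60
    G = rng.standard_normal((K, n))
    model = LinearGaussianModel(G, sigma2=0.3)
    A = rng.standard_normal((n, n))
    prior = DenseGaussianPrior(A @ A.T / n + np.eye(n))
    m_true, _ = prior.sample(rng)
    y = model.simulate_data(m_true, seed=1)
    fit = map_estimate(model, prior, y)
    exact = model.posterior_mean(prior.precision, y)
    assert fit.converged
    assert np.linalg.norm(fit.m1 - exact) <= 1e-4 * np.linalg.norm(exact)


def test_objective_gradient_sign_conventions(tiny_model, coarse_joint_prior):
    """The optimizer's gradient (prior term minus score) matches central
    differences of the full objective."""
    from pactoed.map_recon import _gradient, _objective
    rng = np.random.default_rng(1)
    m = 0.2 * rng.standard_normal(tiny_model.n_latent)
    m1, m2 = tiny_model.split(m)
    y = tiny_model.simulate_data(m1, m2, seed=2)
    F, state = _objective(tiny_model, coarse_joint_prior, m, y)
    g = _gradient(tiny_model, coarse_joint_prior, m, y, state)
    v = rng.standard_normal(m.size)
    v /= np.linalg.norm(v)
    eps = 1e-5
    fp, _ = _objective(tiny_model, coarse_joint_prior, m + eps * v, y)
    fm, _ = _objective(tiny_model, coarse_joint_prior, m - eps * v, y)
    assert abs(g @ v - (fp - fm) / (2 * eps)) <= 1e-5 * abs(g @ v)


def test_gauss_newton_action_symmetric_psd(tiny_model, coarse_joint_prior):
    rng = np.random.default_rng(2)
    m1, m2 = tiny_model.split(0.2 * rng.standard_normal(tiny_model.n_latent))
    state = tiny_model.forward(m1, m2)

    def H(v):
        v1, v2 = tiny_model.split(v)
        h1, _ = tiny_model.gauss_newton_misfit_action(state, v1, v2)
        return h1

    for _ in range(4):
        v = rng.standard_normal(tiny_model.n_latent)
        w = rng.standard_normal(tiny_model.n_latent)
        assert np.isclose(v @ H(w), w @ H(v), rtol=1e-8)
        assert v @ H(v) >= 0


def test_descent_from_truth_with_noise_free_data(tiny_model,
                                                 coarse_joint_prior):
    """Starting at the generating parameter with exact data, the objective
    never increases along accepted steps and ends at or below its start."""
    from pactoed.map_recon import _objective
    rng = np.random.default_rng(3)
    m1 = 0.3 * rng.standard_normal(tiny_model.n_nodes)
    y = tiny_model.simulate_data(m1, None, sigma2=0.0)
    F0, _ = _objective(tiny_model, coarse_joint_prior, m1, y)
    fit = map_estimate(tiny_model, coarse_joint_prior, y, m0=m1)
    assert fit.objective <= F0 + 1e-12
    objs = [rec[2] for rec in fit.history]
    assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))


def test_low_noise_recovery_in_boundary_band(tiny_model, coarse_mesh,
                                             coarse_joint_prior):
    """At sigma^2 = 1e-6 with a fully covering uniform illumination, a
    prior draw is recovered near the boundary, where the measurement
    sensitivity is highest."""
    from pactoed.illumination import make_design
    from pactoed.likelihood import PactModel
    quiet = PactModel(tiny_model.fem, make_design("single_uniform"),
                      tiny_model.crt, sigma2=1e-6)
    rng = np.random.default_rng(4)
    m1, _ = coarse_joint_prior.sample(rng)
    y = quiet.simulate_data(m1, None, seed=5)
    fit = map_estimate(quiet, coarse_joint_prior, y)
    r = np.linalg.norm(coarse_mesh.vertices, axis=1)
    band = r >= 4.0
    err = np.linalg.norm((fit.m1 - m1)[band]) / np.linalg.norm(m1[band])
    assert err < 0.2


def test_high_noise_map_collapses_to_prior_mean(tiny_model,
                                                coarse_joint_prior,
                                                coarse_fem):
    """sigma^2 -> large: the MAP tends to zero and the m1 error second
    moment approaches the integrated prior variance (~0.2 * area)."""
    from pactoed.likelihood import PactModel
    deaf = PactModel(tiny_model.fem, tiny_model.design, tiny_model.crt,
                     sigma2=1e6)
    rng = np.random.default_rng(6)
    n_trials = 40
    vals = []
    for _ in range(n_trials):
        m1, _ = coarse_joint_prior.sample(rng)
        y = deaf.simulate_data(m1, None, rng=rng)
        fit = map_estimate(deaf, coarse_joint_prior, y)
        assert np.linalg.norm(fit.m1) <= 0.05 * np.linalg.norm(m1)
        e = fit.m1 - m1
        vals.append(e @ coarse_fem.mass.dot(e))
    vals = np.asarray(vals)
    target = 0.2 * AREA
    se = vals.std(ddof=1) / np.sqrt(n_trials)
    assert abs(vals.mean() - target) <= 3 * se + 0.05 * target


def test_expected_mse_structure(tiny_model, coarse_joint_prior, coarse_fem):
    mse = expected_mse(tiny_model, coarse_joint_prior, coarse_fem,
                       n_trials=5, seed=7)
    assert mse.n_trials == 5 and mse.n_failed == 0
    assert np.all(mse.pointwise_m1 >= 0)
    assert np.all(mse.pointwise_mua >= 0)
    assert mse.tr_M_m1 > 0 and mse.tr_M_mua > 0
    # integrated values consistent with the pointwise maps in magnitude
    approx = integrate(mse.pointwise_m1, coarse_fem)
    assert 0.5 * approx <= mse.tr_M_m1 <= 2.0 * approx


def test_boundary_error_smaller_than_center(tiny_model, coarse_mesh,
                                            coarse_joint_prior, coarse_fem):
    """Reconstruction error is lowest near the boundary (highest SNR)."""
    mse = expected_mse(tiny_model, coarse_joint_prior, coarse_fem,
                       n_trials=12, seed=8)
    r = np.linalg.norm(coarse_mesh.vertices, axis=1)
    boundary_band = mse.pointwise_m1[r >= 4.2].mean()
    center_disk = mse.pointwise_m1[r <= 2.0].mean()
    assert boundary_band < center_disk


def test_solver_config_validation():
    with pytest.raises(ValueError):
        MapSolverConfig(grad_rtol=-1.0)
    with pytest.raises(NotImplementedError):
        MapSolverConfig(hessian_mode="full")


def test_failed_trials_are_counted(coarse_joint_prior, coarse_fem,
                                   tiny_model):
    class Flaky:
        infer_scattering = False
        n_latent = tiny_model.n_latent

        def split(self, m):
            return m, None

        def simulate_data(self, *a, **k):
            raise RuntimeError("boom")

    with pytest.raises(RuntimeError):
        expected_mse(Flaky(), coarse_joint_prior, coarse_fem, n_trials=10,
                     seed=9)
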