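"""Bayesian information, CRB assembly, change of variable, design metric."""

import numpy as np
import pytest

from pactoed.crb import (assemble_bound, change_of_variable, design_metric,
                         estimate_JD, estimate_scores, jd_from_scores,
                         trace_metric)
from pactoed.geometry import integrate
from pactoed.linear_gaussian import DenseGaussianPrior, LinearGaussianModel
from pactoed.optical import MU_A_BAR

AREA = 25 * np.pi


@pytest.fixture(scope="module")
def lin_problem():
    rng = np.random.default_rng(0)
    n, K = 20, 50
    G = rng.standard_normal((K, n)) / np.sqrt(K)
    A = rng.standard_normal((n, n))
    cov = A @ A.T / n + np.eye(n)
    return LinearGaussianModel(G, sigma2=0.2), DenseGaussianPrior(cov)


def test_jd_converges_to_linear_information(lin_problem):
    model, prior = lin_problem
    JD = estimate_JD(model, prior, 3000, seed=1)
    exact = model.information()
    rel = np.linalg.norm(JD - exact) / np.linalg.norm(exact)
    assert rel < 0.15  # ~ c/sqrt(Ns)


def test_jd_single_sample_is_rank_one_psd(lin_problem):
    model, prior = lin_problem
    JD = estimate_JD(model, prior, 1, seed=2)
    w = np.linalg.eigvalsh(JD)
    assert np.all(w >= -1e-10 * w.max())
    assert np.sum(w > 1e-10 * w.max()) == 1


def test_jd_trace_decreases_with_noise(tiny_model, coarse_joint_prior):
    """Scores scale like residual/sigma^2 ~ 1/sigma, so tr(J_D) falls as
    the noise grows (matched seeds)."""
    traces = [np.trace(estimate_JD(tiny_model, coarse_joint_prior, 10,
                                   seed=3, sigma2=s2))
              for s2 in (1e-3, 1e-1, 10.0)]
    assert traces[0] > traces[1] > traces[2]


def test_zero_data_bound_is_prior(coarse_fem, coarse_joint_prior):
    """J_D = 0 recovers the prior covariance; its m1 mass-weighted trace is
    the integrated prior variance ~ 0.2 * area."""
    n = coarse_joint_prior.n_total
    bound = assemble_bound(np.zeros((n, n)), coarse_joint_prior, coarse_fem)
    var = coarse_joint_prior.prior_m1.pointwise_variance()
    np.testing.assert_allclose(bound.pointwise_m1, var, rtol=1e-8)
    assert abs(bound.tr_M_m1 - 0.2 * AREA) <= 0.1 * 0.2 * AREA
    # tr(M C) differs from the integrated variance field only through the
    # sub-unit correlation between neighbouring nodes (a mesh-size effect)
    assert abs(bound.tr_M_m1 - integrate(var, coarse_fem)) \
        <= 0.1 * bound.tr_M_m1


def test_bound_equals_posterior_covariance_linear(lin_problem, coarse_fem):
    model, prior = lin_problem
    bound = assemble_bound(model.information(), prior)
    exact = model.posterior_covariance(prior.precision)
    assert np.linalg.norm(bound.V_m - exact) <= 1e-8 * np.linalg.norm(exact)


def test_bound_matrices_spd_and_marginal_block(tiny_model_nuisance,
                                               coarse_joint_prior_nuisance,
                                               coarse_fem):
    prior = coarse_joint_prior_nuisance
    JD = estimate_JD(tiny_model_nuisance, prior, 30, seed=4)
    w = np.linalg.eigvalsh(JD)
    assert np.all(w >= -1e-8 * w.max())           # PSD data term
    bound = assemble_bound(JD, prior, coarse_fem)
    assert np.all(np.linalg.eigvalsh(bound.J_m) > 0)
    assert np.all(np.linalg.eigvalsh(bound.V_m) > 0)
    n1 = prior.prior_m1.n_nodes
    np.testing.assert_array_equal(bound.V_m1, bound.V_m[:n1, :n1])
    # data never hurts: marginal bound below the prior-only bound
    prior_only = assemble_bound(np.zeros_like(JD), prior, coarse_fem)
    assert bound.tr_M_m1 <= prior_only.tr_M_m1 + 1e-12


def test_asymmetric_jd_rejected(coarse_joint_prior):
    n = coarse_joint_prior.n_total
    JD = np.zeros((n, n))
    JD[0, 1] = 1.0
    with pytest.raises(ValueError, match="symmetric"):
        assemble_bound(JD, coarse_joint_prior)


# ---------------------------------------------------------------------------
# change of variable
# ---------------------------------------------------------------------------

def test_change_of_variable_closed_form_center(coarse_mesh, coarse_fem,
                                               coarse_joint_prior):
    """Lognormal mean: E[mu_a_bar e^{m1}] = mu_a_bar e^{var/2} ~ e^{-1.9}."""
    n = coarse_joint_prior.n_total
    bound = assemble_bound(np.zeros((n, n)), coarse_joint_prior, coarse_fem)
    change_of_variable(bound, coarse_joint_prior.prior_m1, mode="closed_form",
                       fem=coarse_fem)
    c = coarse_mesh.nearest_vertex((0, 0))
    assert abs(bound.c_hat[c] - np.exp(-1.9)) <= 0.01 * np.exp(-1.9)


def test_change_of_variable_mc_matches_closed_form(coarse_fem,
                                                   coarse_joint_prior):
    n = coarse_joint_prior.n_total
    b1 = assemble_bound(np.zeros((n, n)), coarse_joint_prior, coarse_fem)
    b2 = assemble_bound(np.zeros((n, n)), coarse_joint_prior, coarse_fem)
    change_of_variable(b1, coarse_joint_prior.prior_m1, mode="closed_form")
    n_mc = 5000
    change_of_variable(b2, coarse_joint_prior.prior_m1, mode="monte_carlo",
                       n_samples=n_mc, seed=5)
    # MC standard error of E[e^m]: sd = sqrt(e^{2v}(e^v - 1) * ...) per node
    var = coarse_joint_prior.prior_m1.pointwise_variance()
    se = MU_A_BAR * np.sqrt(np.exp(var) * (np.exp(var) - 1.0) / n_mc) \
        * np.exp(var / 2)
    assert np.all(np.abs(b1.c_hat - b2.c_hat) <= 3.5 * se)


def test_change_of_variable_degenerate_prior():
    """Zero prior variance collapses the congruence to mu_a_bar * I."""

    class _Flat:
        def pointwise_variance(self):
            return np.zeros(4)

    from pactoed.crb import BoundResult
    V = np.eye(4)
    bound = BoundResult(J_D=V * 0, J_m=V, V_m=V, V_m1=V, n1=4)
    change_of_variable(bound, _Flat(), mode="closed_form")
    np.testing.assert_allclose(bound.c_hat, MU_A_BAR)
    np.testing.assert_allclose(bound.V_mua, MU_A_BAR ** 2 * np.eye(4))


def test_prior_only_mua_metric(coarse_fem, coarse_joint_prior):
    """tr_M of the prior-only mu_a bound: the congruence with the lognormal
    mean gives mu_a_bar^2 e^{v} v integrated over the disk (v = 0.2)."""
    n = coarse_joint_prior.n_total
    bound = assemble_bound(np.zeros((n, n)), coarse_joint_prior, coarse_fem)
    change_of_variable(bound, coarse_joint_prior.prior_m1, mode="closed_form",
                       fem=coarse_fem)
    metric = design_metric(bound, coarse_fem)
    expected = MU_A_BAR ** 2 * np.exp(0.2) * 0.2 * AREA
    assert abs(metric - expected) <= 0.1 * expected


def test_metric_invariant_under_node_permutation(coarse_fem,
                                                 coarse_joint_prior):
    rng = np.random.default_rng(6)
    n1 = coarse_fem.n_nodes
    X = rng.standard_normal((n1, n1))
    X = X @ X.T
    perm = rng.permutation(n1)
    M = coarse_fem.mass.toarray()
    direct = float((M @ X).diagonal().sum())
    permuted = float((M[np.ix_(perm, perm)] @ X[np.ix_(perm, perm)])
                     .diagonal().sum())
    assert np.isclose(direct, permuted)
    assert np.isclose(trace_metric(X, coarse_fem), direct)


def test_metric_rejects_mismatched_block(coarse_fem):
    with pytest.raises(ValueError):
        trace_metric(np.eye(coarse_fem.n_nodes + 2), coarse_fem)


# ---------------------------------------------------------------------------
# Monte-Carlo behaviour
# ---------------------------------------------------------------------------

def test_half_sample_stability(tiny_model, coarse_joint_prior, coarse_fem):
    """Two disjoint half-sample bound estimates agree closely."""
    S = estimate_scores(tiny_model, coarse_joint_prior, 400, seed=7)
    metrics = []
    for part in (S[:, :200], S[:, 200:]):
        b = assemble_bound(jd_from_scores(part), coarse_joint_prior,
                           coarse_fem)
        change_of_variable(b, coarse_joint_prior.prior_m1,
                           mode="closed_form", fem=coarse_fem)
        metrics.append(design_metric(b, coarse_fem))
    assert abs(metrics[0] - metrics[1]) <= 0.05 * np.mean(metrics)


def test_score_sampling_reproducible(tiny_model, coarse_joint_prior):
    a = estimate_scores(tiny_model, coarse_joint_prior, 3, seed=8)
    b = estimate_scores(tiny_model, coarse_joint_prior, 3, seed=8)
    np.testing.assert_array_equal(a, b)


def test_bound_hdf5_roundtrip(tmp_path, coarse_fem, coarse_joint_prior):
    from pactoed.crb import load_bound, save_bound
    n = coarse_joint_prior.n_total
    bound = assemble_bound(np.zeros((n, n)), coarse_joint_prior, coarse_fem)
    change_of_variable(bound, coarse_joint_prior.prior_m1,
                       mode="closed_form", fem=coarse_fem)
    path = tmp_path / "bound.h5"
    save_bound(bound, path)
    loaded = load_bound(path)
    np.testing.assert_array_equal(loaded.V_mua, bound.V_mua)
    assert loaded.tr_M_mua == bound.tr_M_mua
    assert loaded.n1 == bound.n1
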