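"""MAP reconstruction and Monte-Carlo expected-error validation.

The MAP estimate minimises the negative log-posterior

    F(m) = 1/(2 sigma^2) sum_i ||H h_i(m) - d_i||^2 + 1/2 m^T C^{-1} m ,

a non-convex PDE-constrained problem solved by an inexact Newton-CG method:
Gauss-Newton Hessian actions (symmetric PSD, matrix-free via one incremental
forward and one incremental adjoint solve per product), Eisenstat-Walker
forcing on the CG tolerance to avoid oversolving, and Armijo backtracking
line search for globalisation.

``expected_mse`` validates the Bayesian CRB: it draws parameters from the
prior, simulates data, reconstructs, and accumulates the mass-weighted
squared error, whose expectation the bound must lie below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FemOperators
from .optical import MU_A_BAR

__all__ = ["MapSolverConfig", "MapResult", "MseEstimate",
           "map_estimate", "expected_mse"]


@dataclass
class MapSolverConfig:
    """Inexact Newton-CG settings.

    The Eisenstat-Walker (choice 2) forcing sequence sets the CG relative
    tolerance from the gradient-norm reduction; Gauss-Newton mode drops the
    second-order PDE terms from the Hessian, which keeps every CG operator
    positive semi-definite (no negative-curvature handling needed).
    """

    max_newton: int = 40
    grad_rtol: float = 1e-6
    grad_atol: float = 1e-12
    eta0: float = 0.5
    eta_max: float = 0.5
    ew_gamma: float = 1.0
    ew_alpha: float = 0.5 * (1 + np.sqrt(5.0))
    cg_maxiter: int = 250
    armijo_c: float = 1e-4
    armijo_shrink: float = 0.5
    armijo_max: int = 30
    hessian_mode: str = "gauss_newton"

    def __post_init__(self):
        if min(self.grad_rtol, self.grad_atol, self.eta0) <= 0:
            raise ValueError("tolerances must be positive")
        if self.hessian_mode != "gauss_newton":
            raise NotImplementedError(
                "only the gauss_newton Hessian mode is implemented")


@dataclass
class MapResult:
    m1: np.ndarray
    m2: np.ndarray | None
    converged: bool
    iterations: int
    grad_norm: float
    objective: float
    history: list = field(default_factory=list)


def _stack(model, g1, g2):
    if g2 is None:
        return g1
    return np.concatenate([g1, g2])


def _objective(model, prior, m, y):
    m1, m2 = model.split(m)
    state = model.forward(m1, m2)
    misfit = -model.log_likelihood(m1, m2, y, state=state)
    p1, p2 = prior.apply_precision(m1, m2)
    reg = 0.5 * float(m1 @ p1)
    if p2 is not None:
        reg += 0.5 * float(m2 @ p2)
    return misfit + reg, state


def _gradient(model, prior, m, y, state):
    m1, m2 = model.split(m)
    sc = model.score(m1, m2, y, state=state)
    p1, p2 = prior.apply_precision(m1, m2)
    g1 = -sc.g1 + p1
    g2 = (-sc.g2 + p2) if sc.g2 is not None else None
    return _stack(model, g1, g2)


def _cg(hess, b, rtol, maxiter):
    """Plain CG with Steihaug-style negative-curvature termination."""
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rr = float(r @ r)
    stop = (rtol * np.sqrt(rr)) ** 2
    for _ in range(maxiter):
        hp = hess(p)
        php = float(p @ hp)
        if php <= 0:
            # direction of nonpositive curvature: return progress so far,
            # falling back on steepest descent from the origin
            return x if np.any(x) else b
        alpha = rr / php
        x += alpha * p
        r -= alpha * hp
        rr_new = float(r @ r)
        if rr_new <= stop:
            break
        p = r + (rr_new / rr) * p
        rr = rr_new
    return x


def map_estimate(model, prior, y, config: MapSolverConfig | None = None,
                 m0: np.ndarray | None = None) -> MapResult:
    """Inexact Newton-CG minimisation of the negative log-posterior.

    ``m0`` defaults to the prior mean (zero).  Non-convergence within the
    iteration budget returns the best iterate with ``converged=False``.
    """
    cfg = config or MapSolverConfig()
    m = np.zeros(model.n_latent) if m0 is None else np.asarray(m0, float).copy()

    F, state = _objective(model, prior, m, y)
    g = _gradient(model, prior, m, y, state)
    gnorm0 = gnorm = float(np.linalg.norm(g))
    tol = max(cfg.grad_rtol * gnorm0, cfg.grad_atol)
    eta = cfg.eta0
    history = []

    it = 0
    for it in range(1, cfg.max_newton + 1):
        if gnorm <= tol:
            return MapResult(*model.split(m), converged=True, iterations=it - 1,
                             grad_norm=gnorm, objective=F, history=history)

        def hess(v):
            v1, v2 = model.split(v)
            h1, h2 = model.gauss_newton_misfit_action(state, v1, v2)
            p1, p2 = prior.apply_precision(v1, v2)
            h1 = h1 + p1
            h2 = (h2 + p2) if h2 is not None else None
            return _stack(model, h1, h2)

        step = _cg(hess, -g, rtol=eta, maxiter=cfg.cg_maxiter)

        # Armijo backtracking
        gs = float(g @ step)
        if gs >= 0:           # not a descent direction; fall back on -g
            step = -g
            gs = -gnorm ** 2
        alpha = 1.0
        for _ in range(cfg.armijo_max):
            F_new, state_new = _objective(model, prior, m + alpha * step, y)
            if F_new <= F + cfg.armijo_c * alpha * gs:
                break
            alpha *= cfg.armijo_shrink
        else:
            history.append((it, gnorm, F, alpha))
            break            # line search failed; return best iterate

        m = m + alpha * step
        F, state = F_new, state_new
        g_new = _gradient(model, prior, m, y, state)
        gnorm_new = float(np.linalg.norm(g_new))
        # Eisenstat-Walker choice 2 with safeguard
        eta_prop = cfg.ew_gamma * (gnorm_new / gnorm) ** cfg.ew_alpha
        safeguard = cfg.ew_gamma * eta ** cfg.ew_alpha
        if safeguard > 0.1:
            eta_prop = max(eta_prop, safeguard)
        eta = float(np.clip(eta_prop, 1e-8, cfg.eta_max))
        g, gnorm = g_new, gnorm_new
        history.append((it, gnorm, F, alpha))

    return MapResult(*model.split(m), converged=bool(gnorm <= tol),
                     iterations=it, grad_norm=gnorm, objective=F,
                     history=history)


@dataclass
class MseEstimate:
    """Monte-Carlo expected squared reconstruction error."""

    pointwise_m1: np.ndarray
    pointwise_mua: np.ndarray
    tr_M_m1: float
    tr_M_mua: float
    pointwise_m2: np.ndarray | None
    tr_M_m2: float | None
    n_trials: int
    n_failed: int
    records: list


def expected_mse(model, prior, fem: FemOperators, n_trials: int, seed: int,
                 config: MapSolverConfig | None = None,
                 mu_a_bar: float = MU_A_BAR,
                 max_failure_fraction: float = 0.01) -> MseEstimate:
    """Estimate ``E[(m_hat - m)(m_hat - m)^T]`` traces for the MAP estimator.

    Each trial samples ``m`` from the prior, simulates data, reconstructs
    from the prior mean, and accumulates nodal squared errors and the
    mass-weighted quadratic error for ``m1`` and ``mu_a`` (and ``m2`` when
    the scattering field is inferred).  Trials raising solver errors are
    excluded; more than ``max_failure_fraction`` failures aborts the run.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    M = fem.mass
    n = fem.n_nodes
    pw1 = np.zeros(n)
    pwa = np.zeros(n)
    infer2 = getattr(model, "infer_scattering", False)
    pw2 = np.zeros(n) if infer2 else None
    tr1 = tra = tr2 = 0.0
    records, n_failed = [], 0
    n_ok = 0
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_trials)):
        rng = np.random.default_rng(ss)
        m1, m2 = prior.sample(rng)
        try:
            y = model.simulate_data(m1, m2, rng=rng)
            fit = map_estimate(model, prior, y, config=config)
        except Exception:
            n_failed += 1
            if n_failed > max(1, max_failure_fraction * n_trials):
                raise
            continue
        e1 = fit.m1 - m1
        ea = mu_a_bar * (np.exp(fit.m1) - np.exp(m1))
        pw1 += e1 ** 2
        pwa += ea ** 2
        tr1 += float(e1 @ M.dot(e1))
        tra += float(ea @ M.dot(ea))
        if infer2:
            e2 = fit.m2 - m2
            pw2 += e2 ** 2
            tr2 += float(e2 @ M.dot(e2))
        n_ok += 1
        records.append((i, fit.iterations, fit.grad_norm, fit.converged))
    if n_ok == 0:
        raise RuntimeError("all reconstruction trials failed")
    return MseEstimate(
        pointwise_m1=pw1 / n_ok, pointwise_mua=pwa / n_ok,
        tr_M_m1=tr1 / n_ok, tr_M_mua=tra / n_ok,
        pointwise_m2=(pw2 / n_ok) if infer2 else None,
        tr_M_m2=(tr2 / n_ok) if infer2 else None,
        n_trials=n_ok, n_failed=n_failed, records=records)
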