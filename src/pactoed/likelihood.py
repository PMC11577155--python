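"""Measurement simulation, log-likelihood, and its adjoint-based score.

The observable for one illumination ``i`` is ``d_i = H h_i + z_i`` with
``H`` the assembled circular Radon transform, ``h_i = mu_a * phi_i`` the
absorbed energy of the ``i``-th illumination, and ``z_i ~ N(0, sigma^2 I)``.
Up to an additive constant,

    log p(y | m) = -1/(2 sigma^2) sum_i || H h_i - d_i ||^2 .

The gradient of this objective with respect to the nodal coefficients of
``(m1, m2)`` -- the (Stein) score of the likelihood -- is computed by the
adjoint method: one extra solve of the (self-adjoint) diffusion operator per
illumination, reusing the forward factorisation.  The implementation is the
*exact discrete adjoint* of the discretised objective, obtained from the
Lagrangian of the algebraic system

    [M(mu_a) + K(D) + B/2] phi_i = 2 B q_i ,

so a central finite-difference directional-derivative check against
:func:`log_likelihood` is part of the test contract and must pass at tight
relative tolerance.

The same Jacobian-transpose machinery provides Gauss-Newton Hessian actions
for the MAP reconstructor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acoustic import CrtOperator
from .geometry import FemOperators
from .illumination import IlluminationDesign, boundary_flux
from .optical import MU_A_BAR, MU_S_BAR, DiffusionSolver, OpticalParameters

__all__ = ["Measurement", "ForwardState", "ScoreResult", "PactModel"]

DEFAULT_SIGMA2 = 1e-3  # measurement noise variance (AU^2 of the data function)


@dataclass
class Measurement:
    """Per-illumination data vectors with their noise level."""

    data: list            # I arrays of length K
    sigma2: float
    seed: int | None = None

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        K = {d.shape[0] for d in self.data}
        if len(K) > 1:
            raise ValueError("all illuminations must share the data length")


@dataclass
class ForwardState:
    """Cached forward solution at one parameter value."""

    params: OpticalParameters
    solver: DiffusionSolver
    phis: list            # fluence per illumination
    hs: list              # absorbed energy per illumination
    predicted: list       # H h_i per illumination


@dataclass
class ScoreResult:
    """Likelihood gradient w.r.t. nodal coefficients, plus diagnostics."""

    g1: np.ndarray
    g2: np.ndarray | None
    fluences: list
    adjoints: list

    def stacked(self) -> np.ndarray:
        if self.g2 is None:
            return self.g1
        return np.concatenate([self.g1, self.g2])


class PactModel:
    """Virtual qPACT system: design + optics + acoustics + noise.

    ``infer_scattering`` selects whether ``m2`` is an unknown nuisance field
    (study 3) or fixed at its reference (studies 1 and 2).
    """

    def __init__(self, fem: FemOperators, design: IlluminationDesign,
                 crt: CrtOperator, sigma2: float = DEFAULT_SIGMA2,
                 mu_a_bar: float = MU_A_BAR, mu_s_bar: float = MU_S_BAR,
                 infer_scattering: bool = False):
        self.fem = fem
        self.design = design
        self.crt = crt
        self.sigma2 = float(sigma2)
        self.mu_a_bar = mu_a_bar
        self.mu_s_bar = mu_s_bar
        self.infer_scattering = infer_scattering
        self.fluxes = [boundary_flux(design, i, fem.mesh)
                       for i in range(design.n_illuminations)]

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.fem.n_nodes

    @property
    def n_latent(self) -> int:
        return self.n_nodes * (2 if self.infer_scattering else 1)

    def split(self, m: np.ndarray):
        """Split a stacked latent vector into ``(m1, m2-or-None)``."""
        if self.infer_scattering:
            return m[:self.n_nodes], m[self.n_nodes:]
        return m, None

    # ------------------------------------------------------------------
    def forward(self, m1: np.ndarray, m2: np.ndarray | None = None) -> ForwardState:
        params = OpticalParameters(m1=m1, m2=m2, mu_a_bar=self.mu_a_bar,
                                   mu_s_bar=self.mu_s_bar)
        solver = DiffusionSolver(params, self.fem)
        phis, hs, predicted = [], [], []
        for q in self.fluxes:
            fl = solver.solve(q)
            phis.append(fl.phi)
            hs.append(fl.h)
            predicted.append(self.crt.apply(fl.h))
        return ForwardState(params=params, solver=solver, phis=phis,
                            hs=hs, predicted=predicted)

    def simulate_data(self, m1, m2=None, seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      sigma2: float | None = None,
                      state: ForwardState | None = None) -> Measurement:
        """Noise-free forward data plus i.i.d. Gaussian noise."""
        if rng is None:
            rng = np.random.default_rng(seed)
        s2 = self.sigma2 if sigma2 is None else float(sigma2)
        if state is None:
            state = self.forward(m1, m2)
        sd = np.sqrt(s2)
        data = [d + sd * rng.standard_normal(d.shape) if s2 > 0 else d.copy()
                for d in state.predicted]
        return Measurement(data=data, sigma2=max(s2, np.finfo(float).tiny),
                           seed=seed)

    def log_likelihood(self, m1, m2, y: Measurement,
                       state: ForwardState | None = None) -> float:
        """``-1/(2 sigma^2) sum_i ||H h_i - d_i||^2`` (constants dropped)."""
        if state is None:
            state = self.forward(m1, m2)
        val = 0.0
        for pred, d in zip(state.predicted, y.data):
            r = pred - d
            val -= 0.5 * float(r @ r) / y.sigma2
        return val

    # ------------------------------------------------------------------
    def jacobian_transpose(self, state: ForwardState, covectors: list):
        """Apply the transposed data Jacobian to data-space covectors.

        For each illumination, ``gh = H^T w`` is lifted to the parameter
        gradient through the adjoint solve ``S p = mu_a * gh`` and the
        derivatives of the bilinear forms with respect to their P1
        coefficients.  Returns ``(g1, g2-or-None, adjoints)``.
        """
        fem = self.fem
        mu_a = state.params.mu_a
        mu_s = state.params.mu_s
        D = state.params.diffusion
        g1 = np.zeros(self.n_nodes)
        g2 = np.zeros(self.n_nodes) if self.infer_scattering else None
        adjoints = []
        for phi, w in zip(state.phis, covectors):
            gh = self.crt.apply_adjoint(w)
            p = state.solver.solve_adjoint(mu_a * gh)
            adjoints.append(p)
            g1 += (mu_a * phi * gh
                   - mu_a * fem.mass_form_derivative(p, phi)
                   + 3.0 * D ** 2 * mu_a * fem.stiffness_form_derivative(p, phi))
            if g2 is not None:
                g2 += 3.0 * D ** 2 * mu_s * fem.stiffness_form_derivative(p, phi)
        return g1, g2, adjoints

    def jacobian_apply(self, state: ForwardState, v1: np.ndarray,
                       v2: np.ndarray | None) -> list:
        """Directional derivative of the noise-free data in ``(v1, v2)``."""
        fem = self.fem
        mu_a = state.params.mu_a
        mu_s = state.params.mu_s
        D = state.params.diffusion
        dmu_a = mu_a * v1
        dmu_s = mu_s * v2 if (v2 is not None) else 0.0
        dD = -3.0 * D ** 2 * (dmu_a + dmu_s)
        out = []
        for phi in state.phis:
            rhs = fem.mass_apply(dmu_a, phi) + fem.stiffness_apply(dD, phi)
            dphi = -state.solver.solve_adjoint(rhs)
            out.append(self.crt.apply(dmu_a * phi + mu_a * dphi))
        return out

    def score(self, m1, m2, y: Measurement,
              state: ForwardState | None = None) -> ScoreResult:
        """Gradient of :func:`log_likelihood` w.r.t. nodal ``(m1, m2)``."""
        if state is None:
            state = self.forward(m1, m2)
        covectors = [(d - pred) / y.sigma2
                     for pred, d in zip(state.predicted, y.data)]
        g1, g2, adjoints = self.jacobian_transpose(state, covectors)
        return ScoreResult(g1=g1, g2=g2, fluences=state.phis,
                           adjoints=adjoints)

    def gauss_newton_misfit_action(self, state: ForwardState, v1, v2):
        """``J^T Sigma_z^{-1} J v`` -- the PSD misfit Hessian action."""
        jv = self.jacobian_apply(state, v1, v2)
        g1, g2, _ = self.jacobian_transpose(
            state, [w / self.sigma2 for w in jv])
        return g1, g2
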