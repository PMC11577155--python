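"""Diffusion-approximation optical forward model.

The fluence ``phi`` satisfies the second-order elliptic PDE

    mu_a phi - div(D grad phi) = 0        in Omega,
    <D grad phi, eta> + phi/2 = 2 q       on the boundary,

with diffusion coefficient ``D = 1/[3 (mu_a + mu_s')]`` and matched
refractive indices (hence the exact 1/2 and 2 Robin coefficients).  The
absorbed energy density is ``h = Gamma * mu_a * phi`` with the Grueneisen
parameter fixed at ``GRUENEISEN = 1``.

Optical coefficients are parameterised exponentially around reference
values, ``mu_a = mu_a_bar * exp(m1)`` and ``mu_s' = mu_s_bar * exp(m2)``,
which guarantees positivity for any latent fields ``m1, m2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import splu

from .geometry import FemOperators

__all__ = ["OpticalParameters", "Fluence", "DiffusionSolver",
           "solve_diffusion", "absorbed_energy",
           "MU_A_BAR", "MU_S_BAR", "GRUENEISEN"]

MU_A_BAR = float(np.exp(-2.0))  # reference absorption, ~0.135 1/cm
MU_S_BAR = 10.0                 # reference reduced scattering, 1/cm
GRUENEISEN = 1.0                # photoacoustic efficiency, assumed unity


@dataclass
class OpticalParameters:
    """Latent log-deviation fields and derived optical coefficients."""

    m1: np.ndarray
    m2: np.ndarray | None = None
    mu_a_bar: float = MU_A_BAR
    mu_s_bar: float = MU_S_BAR

    @property
    def mu_a(self) -> np.ndarray:
        return self.mu_a_bar * np.exp(self.m1)

    @property
    def mu_s(self) -> np.ndarray:
        m2 = 0.0 if self.m2 is None else self.m2
        return self.mu_s_bar * np.exp(m2) * np.ones_like(self.m1)

    @property
    def diffusion(self) -> np.ndarray:
        return 1.0 / (3.0 * (self.mu_a + self.mu_s))

    @classmethod
    def reference(cls, n_nodes: int, **kw) -> "OpticalParameters":
        """Prior-mean parameters (``m1 = m2 = 0``)."""
        return cls(m1=np.zeros(n_nodes), m2=None, **kw)


@dataclass
class Fluence:
    """Fluence field with its source and absorbed energy density."""

    phi: np.ndarray
    q: np.ndarray
    h: np.ndarray


class DiffusionSolver:
    """Factorised diffusion operator for one set of optical parameters.

    The system matrix ``S = M(mu_a) + K(D) + B/2`` is symmetric positive
    definite and depends only on the parameters, so one sparse factorisation
    serves every illumination (right-hand side) and the adjoint problem.
    """

    def __init__(self, params: OpticalParameters, fem: FemOperators):
        mu_a, D = params.mu_a, params.diffusion
        if np.any(mu_a <= 0) or np.any(D <= 0):
            raise ValueError("optical coefficients must be strictly positive")
        self.params = params
        self.fem = fem
        self.system = (fem.assemble(a=mu_a, b=D)
                       + 0.5 * fem.boundary_mass).tocsc()
        self._lu = splu(self.system)

    def solve(self, q: np.ndarray) -> Fluence:
        """Solve for the fluence produced by the nodal boundary flux ``q``."""
        rhs = 2.0 * self.fem.boundary_mass.dot(q)
        phi = self._lu.solve(rhs)
        return Fluence(phi=phi, q=q, h=absorbed_energy(self.params, phi))

    def solve_adjoint(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``S p = rhs`` (the operator is self-adjoint)."""
        return self._lu.solve(rhs)


def solve_diffusion(params: OpticalParameters, q: np.ndarray,
                    fem: FemOperators) -> Fluence:
    """One-shot convenience wrapper around :class:`DiffusionSolver`."""
    return DiffusionSolver(params, fem).solve(q)


def absorbed_energy(params: OpticalParameters, phi: np.ndarray) -> np.ndarray:
    """Absorbed energy density ``h = Gamma * mu_a * phi`` (nodal product)."""
    return GRUENEISEN * params.mu_a * phi
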