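"""Cone-beam light sources and multi-illumination design schemes.

A design is a set of ``I`` illuminations, each a set of ``S`` cone-beam
sources on a ring outside the imaging domain, all pointing at the centre.
Two named layouts are provided, mirroring stop-and-go PACT systems:

* ``contiguous`` -- the sources sit uniformly on a 90-degree arc and the
  whole cluster rotates by pi/2 between illuminations;
* ``interlaced`` -- the sources sit uniformly on the full ring and rotate by
  pi/20 between illuminations, so the union of all illuminations covers
  4 S distinct angles.

Each source contributes an exponentially attenuated monopole flux with a
cosine angular modulation cut off at the aperture half-angle; the boundary
flux entering the diffusion model is the inward projection of the summed
source fluxes, clamped at zero (geometric shadowing of the far side).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import Mesh

__all__ = [
    "ConeBeamSource",
    "IlluminationDesign",
    "cone_beam_flux",
    "boundary_flux",
    "make_design",
    "normalize_power",
]

DEFAULT_APERTURE = np.deg2rad(25.0)   # cone full aperture beta (rad)
DEFAULT_MU_A_PRIME = 1e-3             # exterior absorption (1/cm)
DEFAULT_RING_RADIUS = 10.0            # source ring radius (cm)


@dataclass(frozen=True)
class ConeBeamSource:
    """A cone-beam source at ``position`` pointing along ``direction``."""

    position: tuple
    direction: tuple
    power: float = 1.0                      # P, AU cm
    aperture: float = DEFAULT_APERTURE      # beta, full cone angle (rad)
    mu_a_prime: float = DEFAULT_MU_A_PRIME  # exterior absorption (1/cm)

    def __post_init__(self):
        d = np.linalg.norm(self.direction)
        if not np.isclose(d, 1.0, atol=1e-9):
            object.__setattr__(self, "direction",
                               tuple(np.asarray(self.direction) / d))
        if not 0 < self.aperture < np.pi:
            raise ValueError("aperture must lie in (0, pi)")
        if self.power < 0:
            raise ValueError("power must be nonnegative")


@dataclass(frozen=True)
class IlluminationDesign:
    """A named set of illuminations (each a tuple of sources).

    ``uniform_flux=True`` encodes the single-illumination validation design
    where the boundary flux is identically 1 AU and no discrete sources
    exist.
    """

    scheme_name: str
    illuminations: tuple          # tuple of tuples of ConeBeamSource
    ring_radius: float = DEFAULT_RING_RADIUS
    uniform_flux: bool = False

    @property
    def n_illuminations(self) -> int:
        return max(1, len(self.illuminations))

    def scaled(self, factor: float) -> "IlluminationDesign":
        """Same design with every source power multiplied by ``factor``."""
        if self.uniform_flux:
            return self
        illums = tuple(
            tuple(replace(s, power=s.power * factor) for s in group)
            for group in self.illuminations)
        return replace(self, illuminations=illums)


def cone_beam_flux(x: np.ndarray, source: ConeBeamSource) -> np.ndarray:
    """Flux density vector at boundary point(s) ``x`` from one source.

    ``q(x; s) = P g(theta) exp(-mu_a' |s-x|) / (4 pi |s-x|^2) u`` with
    ``u = (s-x)/|s-x|`` and ``g(theta) = cos(theta) 1(|theta| < beta/2)``,
    ``theta`` the angle between the source pointing direction and the ray
    from the source towards ``x``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    s = np.asarray(source.position, dtype=float)
    d = np.asarray(source.direction, dtype=float)
    diff = s[None, :] - x                       # from x towards the source
    r = np.linalg.norm(diff, axis=1)
    if np.any(r == 0):
        raise ValueError("evaluation point coincides with the source")
    u = diff / r[:, None]
    cos_theta = np.clip(-u @ d, -1.0, 1.0)      # ray from s to x is -u
    g = np.where(np.abs(np.arccos(cos_theta)) < source.aperture / 2,
                 cos_theta, 0.0)
    mag = source.power * g * np.exp(-source.mu_a_prime * r) / (4 * np.pi * r ** 2)
    return mag[:, None] * u


def _node_normals(mesh: Mesh):
    """Outward unit normal per boundary node (mean of adjacent edge normals)."""
    nodes = mesh.boundary_vertices
    acc = np.zeros((mesh.n_vertices, 2))
    for (i, j), n in zip(mesh.boundary_edges, mesh.boundary_normals):
        acc[i] += n
        acc[j] += n
    normals = acc[nodes]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return nodes, normals


def boundary_flux(design: IlluminationDesign, illum_index: int,
                  mesh: Mesh) -> np.ndarray:
    """Nodal boundary flux field ``q`` for one illumination.

    Interior nodes are zero; each boundary node receives the inward
    projection ``max(<q(x; s), eta(x)>, 0)`` summed over the sources.
    """
    if illum_index >= design.n_illuminations:
        raise IndexError("illumination index out of range")
    q = np.zeros(mesh.n_vertices)
    nodes, normals = _node_normals(mesh)
    if design.uniform_flux:
        q[nodes] = 1.0
        return q
    x = mesh.vertices[nodes]
    for source in design.illuminations[illum_index]:
        flux = cone_beam_flux(x, source)
        q[nodes] += np.maximum(np.einsum("ij,ij->i", flux, normals), 0.0)
    return q


def _ring_sources(angles, ring_radius, power, beta, mu_a_prime):
    out = []
    for a in angles:
        pos = (ring_radius * np.cos(a), ring_radius * np.sin(a))
        out.append(ConeBeamSource(position=pos,
                                  direction=(-np.cos(a), -np.sin(a)),
                                  power=power, aperture=beta,
                                  mu_a_prime=mu_a_prime))
    return tuple(out)


def make_design(scheme: str, ring_radius: float = DEFAULT_RING_RADIUS,
                S: int = 10, I: int = 4, beta: float = DEFAULT_APERTURE,
                mu_a_prime: float = DEFAULT_MU_A_PRIME,
                power: float = 1.0) -> IlluminationDesign:
    """Construct a named design scheme with sources pointing at the centre."""
    if S < 1 or I < 1:
        raise ValueError("S and I must be positive")
    if scheme == "single_uniform":
        return IlluminationDesign(scheme_name=scheme, illuminations=((),),
                                  ring_radius=ring_radius, uniform_flux=True)
    if scheme == "contiguous":
        base = np.linspace(-np.pi / 4, np.pi / 4, S)
        alpha = np.pi / 2
    elif scheme == "interlaced":
        base = 2 * np.pi * np.arange(S) / S
        alpha = np.pi / 20
    else:
        raise ValueError(f"unknown design scheme {scheme!r}")
    illums = tuple(
        _ring_sources(base + i * alpha, ring_radius, power, beta, mu_a_prime)
        for i in range(I))
    return IlluminationDesign(scheme_name=scheme, illuminations=illums,
                              ring_radius=ring_radius)


def normalize_power(design: IlluminationDesign, fluence_solver,
                    mesh: Mesh, tol: float = 1e-12) -> IlluminationDesign:
    """Scale the shared source power to the ANSI fluence limit of 1 AU.

    ``fluence_solver(q_nodal)`` must return the nodal fluence at the
    reference (prior-mean) optical parameters.  The maximum nodal fluence
    over all illuminations of the design is brought to exactly 1 AU; the
    diffusion model is linear in the boundary flux, so one solve per
    illumination suffices.
    """
    if design.uniform_flux:
        return design
    peak = 0.0
    for i in range(design.n_illuminations):
        phi = fluence_solver(boundary_flux(design, i, mesh))
        peak = max(peak, float(np.max(phi)))
    if peak <= tol:
        raise ValueError("design produces no fluence; cannot normalize power")
    return design.scaled(1.0 / peak)
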