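"""Disk meshing and first-order continuous Galerkin finite-element assembly.

The imaging domain is a disk of radius ``R`` (cm) centred at the origin.  All
spatial fields in the package -- optical coefficients, fluence, absorbed
energy, latent Gaussian fields -- are piecewise-linear (P1) functions on an
unstructured triangular mesh of this disk, represented by their nodal
coefficient vectors.

The mesher places nodes on concentric rings whose radial spacing follows a
sizing function that interpolates linearly (in radius) between a centre
element diameter and a boundary element diameter, then triangulates the point
cloud with a Delaunay triangulation.  This reproduces the graded-resolution
discretisation used throughout the numerical studies (finer near the boundary
where the measurement sensitivity is highest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay

__all__ = [
    "Mesh",
    "FemOperators",
    "build_disk_mesh",
    "refine_mesh",
    "assemble_fem",
    "integrate",
    "write_vtk",
    "read_vtk",
]


@dataclass
class Mesh:
    """Unstructured triangular mesh of a disk centred at the origin.

    Attributes
    ----------
    vertices : (N, 2) float array, coordinates in cm.
    triangles : (T, 3) int array, CCW-oriented vertex triples.
    boundary_edges : (E, 2) int array, vertex pairs on the boundary circle.
    boundary_normals : (E, 2) float array, outward unit normal per edge.
    radius : disk radius in cm.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    boundary_normals: np.ndarray
    radius: float

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Sorted unique indices of vertices lying on the boundary."""
        return np.unique(self.boundary_edges)

    def nearest_vertex(self, point) -> int:
        """Index of the mesh vertex closest to ``point``."""
        d2 = np.sum((self.vertices - np.asarray(point, dtype=float)) ** 2, axis=1)
        return int(np.argmin(d2))


def _ring_radii(radius: float, h_boundary: float, h_center: float,
                snap_radii=(), sizing=None) -> np.ndarray:
    """Radii of concentric node rings following the sizing law.

    Default law: ``h(r) = h_center + (h_boundary - h_center) * r / radius``
    -- spacing marches outward from the centre and the final ring is scaled
    to land exactly on the boundary circle.  A ``sizing`` callable overrides
    the law.
    """

    def h(r):
        if sizing is not None:
            return sizing(r)
        return h_center + (h_boundary - h_center) * r / radius

    radii = [0.0]
    r = 0.0
    while r < radius:
        step = h(r + 0.5 * h(r))
        r += step
        radii.append(r)
    radii = np.asarray(radii)
    radii *= radius / radii[-1]
    for rs in snap_radii:
        if not (0.0 < rs < radius):
            raise ValueError(f"snap radius {rs} outside (0, {radius})")
        k = int(np.argmin(np.abs(radii - rs)))
        if 0 < k < len(radii) - 1:
            radii[k] = rs
    return radii


def _boundary_from_triangles(vertices: np.ndarray, triangles: np.ndarray):
    """Find edges belonging to exactly one triangle and their outward normals.

    Normals are computed from the mesh geometry (pointing away from the
    opposite vertex of the owning triangle), not from the analytic circle.
    """
    edges = {}
    for t, tri in enumerate(triangles):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            edges.setdefault(key, []).append((t, tri[3 - a - b]))
    bedges, bnormals = [], []
    for (i, j), owners in edges.items():
        if len(owners) != 1:
            continue
        _, opp = owners[0]
        e = vertices[j] - vertices[i]
        n = np.array([e[1], -e[0]])
        n /= np.linalg.norm(n)
        mid = 0.5 * (vertices[i] + vertices[j])
        if np.dot(n, mid - vertices[opp]) < 0:
            n = -n
        bedges.append((i, j))
        bnormals.append(n)
    return np.asarray(bedges, dtype=int), np.asarray(bnormals)


def _orient_ccw(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    v = vertices
    t = triangles
    a = v[t[:, 1]] - v[t[:, 0]]
    b = v[t[:, 2]] - v[t[:, 0]]
    signed = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    flip = signed < 0
    t = t.copy()
    t[flip] = t[flip][:, [0, 2, 1]]
    return t


def build_disk_mesh(radius: float, h_boundary: float, h_center: float,
                    seed: int = 0, snap_radii=(), sizing=None) -> Mesh:
    """Mesh the disk of the given radius with radially graded resolution.

    Parameters
    ----------
    radius : disk radius (cm).
    h_boundary, h_center : target element diameters at the boundary and at
        the centre (cm); must satisfy ``0 < h_boundary <= h_center < radius``.
    seed : seed for the (tiny) deterministic angular jitter that prevents
        degenerate co-circular Delaunay configurations.
    snap_radii : optional radii at which a node ring is forced to lie exactly
        (useful for resolving interfaces of piecewise fields).
    sizing : optional callable ``h(r)`` overriding the linear sizing law
        (e.g. to refine locally around an interface radius).
    """
    if not (0 < h_boundary <= h_center):
        raise ValueError("require 0 < h_boundary <= h_center")
    if h_center > radius:
        raise ValueError(
            f"infeasible sizing: h_center={h_center} must be <= radius={radius}")

    rng = np.random.default_rng(seed)
    radii = _ring_radii(radius, h_boundary, h_center, snap_radii, sizing)

    def h(r):
        if sizing is not None:
            return sizing(r)
        return h_center + (h_boundary - h_center) * r / radius

    pts = [np.zeros((1, 2))]
    for k, r in enumerate(radii[1:], start=1):
        m = max(6, int(round(2 * np.pi * r / h(r))))
        offset = (np.pi / m) * (k % 2) + 1e-3 * rng.uniform(0, 2 * np.pi / m)
        ang = offset + 2 * np.pi * np.arange(m) / m
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    vertices = np.vstack(pts)

    tri = Delaunay(vertices)
    triangles = _orient_ccw(vertices, tri.simplices)
    # drop degenerate slivers (co-circular artefacts), if any
    v = vertices
    a = v[triangles[:, 1]] - v[triangles[:, 0]]
    b = v[triangles[:, 2]] - v[triangles[:, 0]]
    area = 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    triangles = triangles[area > 1e-12 * h_boundary ** 2]

    bedges, bnormals = _boundary_from_triangles(vertices, triangles)
    return Mesh(vertices, triangles, bedges, bnormals, float(radius))


def refine_mesh(mesh: Mesh) -> Mesh:
    """Uniform red refinement: each triangle splits into four.

    Midpoints of boundary edges are projected back onto the boundary circle
    so the refined mesh converges to the true disk.
    """
    boundary = set(map(tuple, np.sort(mesh.boundary_edges, axis=1)))
    verts = [mesh.vertices]
    edge_mid = {}
    next_id = mesh.n_vertices
    new_pts = []

    def midpoint(i, j):
        nonlocal next_id
        key = (min(i, j), max(i, j))
        if key not in edge_mid:
            p = 0.5 * (mesh.vertices[i] + mesh.vertices[j])
            if key in boundary:
                p = p * (mesh.radius / np.linalg.norm(p))
            new_pts.append(p)
            edge_mid[key] = next_id
            next_id += 1
        return edge_mid[key]

    tris = []
    for i, j, k in mesh.triangles:
        a, b, c = midpoint(i, j), midpoint(j, k), midpoint(k, i)
        tris.extend([(i, a, c), (a, j, b), (c, b, k), (a, b, c)])
    vertices = np.vstack(verts + [np.asarray(new_pts)])
    triangles = _orient_ccw(vertices, np.asarray(tris, dtype=int))
    bedges, bnormals = _boundary_from_triangles(vertices, triangles)
    return Mesh(vertices, triangles, bedges, bnormals, mesh.radius)


# ---------------------------------------------------------------------------
# P1 finite-element assembly
# ---------------------------------------------------------------------------

# C3[i, j, k] = 60/area * int_T lambda_i lambda_j lambda_k dx
_C3 = np.ones((3, 3, 3))
for _i in range(3):
    for _j in range(3):
        for _k in range(3):
            _C3[_i, _j, _k] += (_i == _j) + (_j == _k) + (_i == _k)
            if _i == _j == _k:
                _C3[_i, _j, _k] += 2.0


@dataclass
class FemOperators:
    """Assembled P1 structures on a fixed mesh.

    ``mass`` is the consistent mass matrix (Gram matrix of the nodal basis,
    cm^2-weighted inner product); ``boundary_mass`` the analogous Gram matrix
    of the boundary trace on the boundary edges.  ``assemble(a, b)`` builds
    the bilinear form ``int a u v + int b grad(u).grad(v)`` for piecewise
    linear coefficients ``a`` and ``b`` given by nodal vectors (or scalars).
    """

    mesh: Mesh
    mass: sp.csr_matrix
    boundary_mass: sp.csr_matrix
    areas: np.ndarray          # (T,) triangle areas
    grads: np.ndarray          # (T, 3, 2) gradients of barycentric functions
    _tri: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_vertices

    def _coef_on_tri(self, a):
        """Nodal coefficient restricted to triangles: (T, 3)."""
        a = np.asarray(a, dtype=float)
        if a.ndim == 0:
            return np.full((len(self.areas), 3), float(a))
        return a[self._tri]

    def assemble(self, a=None, b=None) -> sp.csr_matrix:
        """Sparse matrix of ``int a u v + int b grad u . grad v``."""
        T = self._tri
        nt = T.shape[0]
        rows = np.repeat(T, 3, axis=1).ravel()
        cols = np.tile(T, (1, 3)).ravel()
        vals = np.zeros(nt * 9)
        if a is not None:
            at = self._coef_on_tri(a)
            local = np.einsum("ijk,ek->eij", _C3, at) * (self.areas / 60.0)[:, None, None]
            vals += local.reshape(nt, 9).ravel()
        if b is not None:
            bt = self._coef_on_tri(b).mean(axis=1)
            local = np.einsum("eid,ejd->eij", self.grads, self.grads)
            local *= (bt * self.areas)[:, None, None]
            vals += local.reshape(nt, 9).ravel()
        A = sp.coo_matrix((vals, (rows, cols)),
                          shape=(self.n_nodes, self.n_nodes))
        return A.tocsr()

    # -- derivatives of the bilinear forms w.r.t. their P1 coefficients ----
    def mass_form_derivative(self, p: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Nodal vector ``w`` with ``w[k] = p^T (dM(a)/da_k) phi``."""
        pt, ft = p[self._tri], phi[self._tri]
        local = np.einsum("ijk,ei,ej->ek", _C3, pt, ft) * (self.areas / 60.0)[:, None]
        out = np.zeros(self.n_nodes)
        np.add.at(out, self._tri.ravel(), local.ravel())
        return out

    def stiffness_form_derivative(self, p: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Nodal vector ``u`` with ``u[k] = p^T (dK(b)/db_k) phi``."""
        pt, ft = p[self._tri], phi[self._tri]
        gpg = np.einsum("ei,eid,ejd,ej->e", pt, self.grads, self.grads, ft)
        local = (gpg * self.areas / 3.0)[:, None] * np.ones((1, 3))
        out = np.zeros(self.n_nodes)
        np.add.at(out, self._tri.ravel(), local.ravel())
        return out

    def mass_apply(self, a, phi: np.ndarray) -> np.ndarray:
        """Matrix-free product ``M(a) phi`` for a P1 coefficient ``a``."""
        at, ft = self._coef_on_tri(a), phi[self._tri]
        local = np.einsum("ijk,ej,ek->ei", _C3, ft, at) * (self.areas / 60.0)[:, None]
        out = np.zeros(self.n_nodes)
        np.add.at(out, self._tri.ravel(), local.ravel())
        return out

    def stiffness_apply(self, b, phi: np.ndarray) -> np.ndarray:
        """Matrix-free product ``K(b) phi`` for a P1 coefficient ``b``."""
        bt = self._coef_on_tri(b).mean(axis=1)
        ft = phi[self._tri]
        gphi = np.einsum("ejd,ej->ed", self.grads, ft)
        local = np.einsum("eid,ed->ei", self.grads, gphi) * (bt * self.areas)[:, None]
        out = np.zeros(self.n_nodes)
        np.add.at(out, self._tri.ravel(), local.ravel())
        return out

    def sample_mass_noise(self, rng: np.random.Generator) -> np.ndarray:
        """Draw spatial white noise ``n ~ N(0, M)`` by element-level assembly.

        Each triangle contributes ``M_T^{1/2} z_T`` with i.i.d. standard
        normal ``z_T``; independence across elements makes the total
        covariance exactly the consistent mass matrix.
        """
        nt = self._tri.shape[0]
        z = rng.standard_normal((nt, 3))
        # sqrt of (area/12) * (I + ones) is sqrt(area/12) * (I + ones/3)
        local = np.sqrt(self.areas / 12.0)[:, None] * (z + z.sum(axis=1, keepdims=True) / 3.0)
        out = np.zeros(self.n_nodes)
        np.add.at(out, self._tri.ravel(), local.ravel())
        return out


def assemble_fem(mesh: Mesh) -> FemOperators:
    """Assemble mass, boundary mass, and element data for a mesh."""
    v, T = mesh.vertices, mesh.triangles
    e1 = v[T[:, 1]] - v[T[:, 0]]
    e2 = v[T[:, 2]] - v[T[:, 0]]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    if np.any(det <= 0):
        bad = int(np.argmin(det))
        raise ValueError(f"degenerate or inverted triangle {bad} "
                         f"(signed area {det[bad] / 2:.3e})")
    areas = 0.5 * det
    # gradients of the three barycentric coordinates
    grads = np.empty((T.shape[0], 3, 2))
    grads[:, 1, 0] = e2[:, 1]
    grads[:, 1, 1] = -e2[:, 0]
    grads[:, 2, 0] = -e1[:, 1]
    grads[:, 2, 1] = e1[:, 0]
    grads[:, 1:] /= det[:, None, None]
    grads[:, 0] = -grads[:, 1] - grads[:, 2]

    fem = FemOperators(mesh=mesh, mass=None, boundary_mass=None,
                       areas=areas, grads=grads, _tri=T)
    fem.mass = fem.assemble(a=1.0)

    # boundary mass: int_dOmega u v over boundary edges
    be = mesh.boundary_edges
    L = np.linalg.norm(v[be[:, 1]] - v[be[:, 0]], axis=1)
    rows = np.concatenate([be[:, 0], be[:, 0], be[:, 1], be[:, 1]])
    cols = np.concatenate([be[:, 0], be[:, 1], be[:, 0], be[:, 1]])
    vals = np.concatenate([L / 3.0, L / 6.0, L / 6.0, L / 3.0])
    fem.boundary_mass = sp.coo_matrix(
        (vals, (rows, cols)), shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()
    return fem


def integrate(field_values: np.ndarray, fem: FemOperators) -> float:
    """Integral of a P1 field over the domain, ``1^T M f``."""
    f = np.asarray(field_values, dtype=float)
    if f.shape != (fem.n_nodes,):
        raise ValueError(f"field has shape {f.shape}, expected ({fem.n_nodes},)")
    return float(fem.mass.dot(f).sum())


def write_vtk(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Write the mesh (and optional nodal fields) as a legacy ASCII VTK file."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\npactoed mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y in mesh.vertices:
            f.write(f"{x:.10g} {y:.10g} 0\n")
        nt = mesh.triangles.shape[0]
        f.write(f"CELLS {nt} {4 * nt}\n")
        for i, j, k in mesh.triangles:
            f.write(f"3 {i} {j} {k}\n")
        f.write(f"CELL_TYPES {nt}\n")
        f.write("\n".join(["5"] * nt) + "\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, vals in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.10g}" for v in np.asarray(vals)) + "\n")


def read_vtk(path, radius: float | None = None) -> Mesh:
    """Read a triangular mesh written by :func:`write_vtk`.

    Boundary edges and normals are rebuilt from the triangulation; the disk
    radius defaults to the largest vertex norm.
    """
    with open(path) as f:
        lines = f.read().split("\n")
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    n_pts = int(lines[i].split()[1])
    vertices = np.array([[float(x) for x in lines[i + 1 + k].split()[:2]]
                         for k in range(n_pts)])
    j = next(k for k, ln in enumerate(lines) if ln.startswith("CELLS"))
    n_cells = int(lines[j].split()[1])
    triangles = np.array([[int(x) for x in lines[j + 1 + k].split()[1:4]]
                          for k in range(n_cells)], dtype=int)
    triangles = _orient_ccw(vertices, triangles)
    bedges, bnormals = _boundary_from_triangles(vertices, triangles)
    if radius is None:
        radius = float(np.linalg.norm(vertices, axis=1).max())
    return Mesh(vertices, triangles, bedges, bnormals, radius)
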