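"""Mesh generation and finite-element assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pactoed.geometry import (Mesh, assemble_fem, build_disk_mesh, integrate,
                              refine_mesh, write_vtk)

AREA = 25 * np.pi


def mesh_invariants(mesh, radius=5.0):
    # boundary vertices on the circle
    bv = mesh.vertices[mesh.boundary_vertices]
    assert np.allclose(np.linalg.norm(bv, axis=1), radius, atol=1e-9)
    # consistent orientation: positive signed areas
    v, T = mesh.vertices, mesh.triangles
    a = v[T[:, 1]] - v[T[:, 0]]
    b = v[T[:, 2]] - v[T[:, 0]]
    assert np.all(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0] > 0)
    # each boundary edge owned by exactly one triangle
    from collections import Counter
    count = Counter()
    for tri in T:
        for i, j in ((0, 1), (1, 2), (2, 0)):
            count[frozenset((tri[i], tri[j]))] += 1
    for i, j in mesh.boundary_edges:
        assert count[frozenset((i, j))] == 1
    # outward unit normals
    n = mesh.boundary_normals
    assert np.allclose(np.linalg.norm(n, axis=1), 1.0)
    mid = 0.5 * (v[mesh.boundary_edges[:, 0]] + v[mesh.boundary_edges[:, 1]])
    assert np.all(np.einsum("ij,ij->i", n, mid) > 0)


def test_study_sizing_vertex_count_and_invariants(study_mesh):
    """Graded 0.08->0.15 sizing lands near the reference dimension 7499."""
    mesh_invariants(study_mesh)
    assert abs(study_mesh.n_vertices - 7499) <= 0.2 * 7499


def test_minimal_coarsest_mesh():
    mesh = build_disk_mesh(5.0, 5.0, 5.0, seed=0)
    assert mesh.n_vertices >= 3
    assert mesh.triangles.shape[0] >= 1
    mesh_invariants(mesh)


def test_infeasible_sizing_rejected():
    with pytest.raises(ValueError, match="sizing"):
        build_disk_mesh(5.0, 0.1, 6.0)
    with pytest.raises(ValueError):
        build_disk_mesh(5.0, 0.3, 0.1)  # h_boundary > h_center


def test_vertex_count_matches_density_oracle():
    """Node count agrees with the sizing-field density integral.

    Oracle: an ideal mesh with local diameter h(r) carries about one vertex
    per h(r)^2 of area, i.e. N ~ int_0^R 2 pi r / h(r)^2 dr.
    """
    h = 0.5
    mesh = build_disk_mesh(5.0, h, h, seed=0)
    expected = np.pi * 5.0 ** 2 / h ** 2
    assert abs(mesh.n_vertices - expected) <= 0.3 * expected


def test_mesh_deterministic_given_seed():
    a = build_disk_mesh(5.0, 0.4, 0.6, seed=7)
    b = build_disk_mesh(5.0, 0.4, 0.6, seed=7)
    c = build_disk_mesh(5.0, 0.4, 0.6, seed=8)
    np.testing.assert_array_equal(a.vertices, b.vertices)
    np.testing.assert_array_equal(a.triangles, b.triangles)
    assert not np.array_equal(a.vertices, c.vertices)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(hb=st.floats(0.3, 0.8), ratio=st.floats(1.0, 2.0))
def test_mesh_invariants_random_sizing(hb, ratio):
    mesh = build_disk_mesh(5.0, hb, hb * ratio, seed=3)
    mesh_invariants(mesh)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_mass_matrix_total_is_domain_area(study_fem, coarse_fem):
    # exact at polygon level everywhere...
    tri_area = coarse_fem.areas.sum()
    assert abs(coarse_fem.mass.sum() - tri_area) <= 1e-10 * tri_area
    # ...and within 1e-4 of the disk area at study sizing
    assert abs(study_fem.mass.sum() - AREA) <= 1e-4 * AREA


def test_mass_is_spd(coarse_fem):
    M = coarse_fem.mass.toarray()
    assert np.allclose(M, M.T)
    assert np.all(np.linalg.eigvalsh(M) > 0)


def test_unit_coefficient_assembly_equals_mass(coarse_fem):
    A = coarse_fem.assemble(a=1.0)
    assert abs(A - coarse_fem.mass).max() < 1e-14


def test_mass_action_on_constant(coarse_fem):
    c = 3.7
    total = coarse_fem.mass.dot(np.full(coarse_fem.n_nodes, c)).sum()
    assert np.isclose(total, c * coarse_fem.areas.sum())


def test_boundary_mass_vanishes_on_interior_nodes(coarse_fem):
    mesh = coarse_fem.mesh
    interior = np.setdiff1d(np.arange(mesh.n_vertices), mesh.boundary_vertices)
    B = coarse_fem.boundary_mass
    assert abs(B[interior]).sum() == 0
    assert abs(B[:, interior]).sum() == 0


def test_degenerate_triangle_aborts_assembly():
    vertices = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 0.0]])
    triangles = np.array([[0, 1, 2], [0, 1, 3]])   # second has zero area
    mesh = Mesh(vertices, triangles, np.empty((0, 2), int),
                np.empty((0, 2)), radius=2.0)
    with pytest.raises(ValueError, match="triangle 1"):
        assemble_fem(mesh)


def test_integrate_closed_forms(study_fem):
    mesh = study_fem.mesh
    one = np.ones(mesh.n_vertices)
    assert abs(integrate(one, study_fem) - AREA) <= 1e-4 * AREA
    assert abs(integrate(mesh.vertices[:, 0], study_fem)) < 1e-6
    # second moment of the disk: int x^2 = pi R^4 / 4
    x2 = integrate(mesh.vertices[:, 0] ** 2, study_fem)
    assert abs(x2 - np.pi * 5.0 ** 4 / 4) <= 1e-3 * x2


def test_integrate_dimension_mismatch(coarse_fem):
    with pytest.raises(ValueError):
        integrate(np.ones(coarse_fem.n_nodes + 1), coarse_fem)


def test_bilinear_form_derivatives_match_assembly(coarse_fem):
    """d/da_k of p^T M(a) phi equals the assembled finite difference."""
    rng = np.random.default_rng(0)
    n = coarse_fem.n_nodes
    p, phi = rng.standard_normal(n), rng.standard_normal(n)
    a = rng.uniform(0.5, 1.5, n)
    wm = coarse_fem.mass_form_derivative(p, phi)
    wk = coarse_fem.stiffness_form_derivative(p, phi)
    eps = 1e-6
    for k in rng.choice(n, 5, replace=False):
        da = np.zeros(n)
        da[k] = eps
        fd_m = (p @ coarse_fem.assemble(a=a + da).dot(phi)
                - p @ coarse_fem.assemble(a=a - da).dot(phi)) / (2 * eps)
        fd_k = (p @ coarse_fem.assemble(b=a + da).dot(phi)
                - p @ coarse_fem.assemble(b=a - da).dot(phi)) / (2 * eps)
        assert np.isclose(wm[k], fd_m, rtol=1e-6, atol=1e-9)
        assert np.isclose(wk[k], fd_k, rtol=1e-6, atol=1e-9)


def test_matrix_free_applications_match_assembly(coarse_fem):
    rng = np.random.default_rng(1)
    n = coarse_fem.n_nodes
    a = rng.uniform(0.5, 1.5, n)
    phi = rng.standard_normal(n)
    np.testing.assert_allclose(coarse_fem.mass_apply(a, phi),
                               coarse_fem.assemble(a=a).dot(phi), atol=1e-12)
    np.testing.assert_allclose(coarse_fem.stiffness_apply(a, phi),
                               coarse_fem.assemble(b=a).dot(phi), atol=1e-12)


def test_refinement_preserves_invariants(coarse_mesh):
    fine = refine_mesh(coarse_mesh)
    mesh_invariants(fine)
    assert fine.triangles.shape[0] == 4 * coarse_mesh.triangles.shape[0]


def test_mass_noise_covariance_is_mass_matrix(coarse_fem):
    """Element-wise white-noise assembly reproduces cov = M."""
    rng = np.random.default_rng(42)
    n_mc = 4000
    X = np.array([coarse_fem.sample_mass_noise(rng) for _ in range(n_mc)])
    probes = np.random.default_rng(0).choice(coarse_fem.n_nodes, 6,
                                             replace=False)
    emp = np.cov(X[:, probes].T)
    exact = coarse_fem.mass.toarray()[np.ix_(probes, probes)]
    scale = np.sqrt(np.outer(np.diag(exact), np.diag(exact)))
    assert np.all(np.abs(emp - exact) / scale < 4 / np.sqrt(n_mc) + 1e-3)


def test_vtk_roundtrip_is_readable(tmp_path, coarse_mesh):
    path = tmp_path / "mesh.vtk"
    write_vtk(coarse_mesh, path, {"r": np.linalg.norm(coarse_mesh.vertices,
                                                      axis=1)})
    text = path.read_text()
    assert f"POINTS {coarse_mesh.n_vertices} double" in text
    assert "SCALARS r double" in text


def test_vtk_mesh_reader_roundtrip(tmp_path, coarse_mesh):
    from pactoed.geometry import read_vtk
    path = tmp_path / "m.vtk"
    write_vtk(coarse_mesh, path)
    back = read_vtk(path, radius=coarse_mesh.radius)
    np.testing.assert_allclose(back.vertices, coarse_mesh.vertices)
    np.testing.assert_array_equal(np.sort(back.triangles, axis=1),
                                  np.sort(coarse_mesh.triangles, axis=1))
    mesh_invariants(back)
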