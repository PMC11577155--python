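"""Shared fixtures: meshes, priors and models reused across the suite.

Everything is generated programmatically; session scope keeps the expensive
objects (study-sized mesh, calibrated priors, assembled operators) to one
construction per run.
"""

import numpy as np
import pytest

from pactoed.acoustic import AcousticGeometry, build_crt
from pactoed.geometry import assemble_fem, build_disk_mesh
from pactoed.illumination import make_design, normalize_power
from pactoed.likelihood import PactModel
from pactoed.optical import DiffusionSolver, OpticalParameters
from pactoed.prior import JointPrior, calibrate_prior


@pytest.fixture(scope="session")
def coarse_mesh():
    """~300-node mesh for cheap operator-level tests."""
    return build_disk_mesh(5.0, 0.5, 0.7, seed=2)


@pytest.fixture(scope="session")
def coarse_fem(coarse_mesh):
    return assemble_fem(coarse_mesh)


@pytest.fixture(scope="session")
def medium_mesh():
    """~750-node mesh where prior calibration is well resolved."""
    return build_disk_mesh(5.0, 0.3, 0.45, seed=1)


@pytest.fixture(scope="session")
def medium_fem(medium_mesh):
    return assemble_fem(medium_mesh)


@pytest.fixture(scope="session")
def study_mesh():
    """The study-scale mesh (element diameter 0.08 cm at the boundary,
    0.15 cm at the centre, ~7.5k nodes)."""
    return build_disk_mesh(5.0, 0.08, 0.15, seed=1)


@pytest.fixture(scope="session")
def study_fem(study_mesh):
    return assemble_fem(study_mesh)


@pytest.fixture(scope="session")
def coarse_prior_m1(coarse_fem):
    return calibrate_prior(coarse_fem, 0.2, 5.0)


@pytest.fixture(scope="session")
def medium_prior_m1(medium_fem):
    return calibrate_prior(medium_fem, 0.2, 5.0)


@pytest.fixture(scope="session")
def medium_prior_m2(medium_fem):
    return calibrate_prior(medium_fem, 0.05, 5.0)


@pytest.fixture(scope="session")
def tiny_model(coarse_mesh, coarse_fem):
    """Small two-illumination contiguous model, known scattering."""
    geom = AcousticGeometry(n_transducers=24, n_times=40, dt=2e-7 * 184 / 40)
    crt = build_crt(coarse_mesh, geom)
    design = make_design("contiguous", I=2)
    ref = DiffusionSolver(OpticalParameters.reference(coarse_fem.n_nodes),
                          coarse_fem)
    design = normalize_power(design, lambda q: ref.solve(q).phi, coarse_mesh)
    return PactModel(coarse_fem, design, crt)


@pytest.fixture(scope="session")
def tiny_model_nuisance(coarse_mesh, coarse_fem, tiny_model):
    """Same system with the scattering field inferred as a nuisance."""
    return PactModel(coarse_fem, tiny_model.design, tiny_model.crt,
                     infer_scattering=True)


@pytest.fixture(scope="session")
def coarse_joint_prior(coarse_fem, coarse_prior_m1):
    return JointPrior(coarse_prior_m1)


@pytest.fixture(scope="session")
def coarse_joint_prior_nuisance(coarse_fem, coarse_prior_m1):
    return JointPrior(coarse_prior_m1, calibrate_prior(coarse_fem, 0.05, 5.0))
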