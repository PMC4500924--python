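"""Shared fixtures: analytic fields, oracle solves, and a test-scale study.

Heavy objects (volume-conductor solves, population threshold runs) are
session-scoped so the acceptance tests and unit tests share them.  The
test-scale solver grid uses 0.5 mm near-lead spacing (the coarsest value
that still resolves the encapsulation shell by element membership) and
faster grading than the production default to keep the suite fast; the
oracle grid keeps the production 0.25 mm near-source spacing.
"""

from __future__ import annotations

import numpy as np
import pytest

from dbsim import solver
from dbsim.cable import build_morphology
from dbsim.phantom import default_lead, default_phantom_spec
from dbsim.pipeline import Study

# solver settings for pipeline-level tests (documented test scale)
TEST_SOLVER_OPTS = {"fine_spacing": 0.5, "growth": 1.5, "coarse_spacing": 1.5}

SEED = 11


def analytic_ve(positions_mm, source_mm, sigma=0.3):
    """Free-space point-source potential per +1 mA (V), for cable tests."""
    r_m = np.linalg.norm(positions_mm - np.asarray(source_mm), axis=1) * 1e-3
    return 1e-3 / (4.0 * np.pi * sigma * r_m)


@pytest.fixture(scope="session")
def straight_trajectory():
    n = 241
    return np.stack(
        [np.zeros(n), np.zeros(n), np.linspace(-30.0, 30.0, n)], axis=1
    )


@pytest.fixture(scope="session")
def axon_57(straight_trajectory):
    return build_morphology(5.7, straight_trajectory)


# ---------------------------------------------------------------------------
# Oracle solves (homogeneous media, closed-form references)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def oracle_grid():
    return solver.build_grid(None, fine_spacing=0.25, fine_margin=3.0)


@pytest.fixture(scope="session")
def iso_oracle(oracle_grid):
    """Homogeneous isotropic solve against the analytic point source."""
    f = solver.isotropic_field(0.3)
    system = solver.assemble_operator(f, None, grid=oracle_grid)
    sol = solver.solve_potential(
        system,
        source_point=(0.0, 0.0, 0.0),
        boundary="shell",
        boundary_values=lambda pts: solver.point_source_potential_iso(
            pts, (0.0, 0.0, 0.0), 0.3
        ),
    )
    return system, sol


ANISO_SIGMA = np.diag([0.45, 0.3, 0.2])


@pytest.fixture(scope="session")
def aniso_oracle(oracle_grid):
    """Homogeneous anisotropic solve against the analytic point source."""
    from dbsim.tensors import ConductivityField

    f = ConductivityField(
        data=np.broadcast_to(ANISO_SIGMA, (21, 21, 21, 3, 3)).copy(),
        voxel_size=2.0,
        origin=-20.0 * np.ones(3),
    )
    system = solver.assemble_operator(f, None, grid=oracle_grid)
    sol = solver.solve_potential(
        system,
        source_point=(0.0, 0.0, 0.0),
        boundary="shell",
        boundary_values=lambda pts: solver.point_source_potential_aniso(
            pts, (0.0, 0.0, 0.0), ANISO_SIGMA
        ),
    )
    return system, sol


# ---------------------------------------------------------------------------
# Phantom studies
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study100():
    """Default brainstem phantom, 100 axons per tract, test-scale solver."""
    return Study(
        phantom_spec=default_phantom_spec(seed=SEED),
        lead=default_lead(),
        n_axons=100,
        seed=SEED,
        solver_opts=dict(TEST_SOLVER_OPTS),
    )


@pytest.fixture(scope="session")
def aniso_curve_c5(study100):
    return study100.curve("ON-like", 5)


@pytest.fixture(scope="session")
def aniso_curve_c6(study100):
    return study100.curve("ON-like", 6)


@pytest.fixture(scope="session")
def tract_dominated_study():
    """Phantom whose conduction medium is dominated by aligned anisotropy.

    A 9 mm-radius anisotropic bed (FA 0.55) surrounds both the lead and an
    embedded fiber bundle with the same orientation, mirroring a
    white-matter-dominated region; used for the anisotropic-vs-isotropic
    conduction comparison, where a thin tube alone would leave the mostly
    isotropic lead-to-axon path unchanged.
    """
    from dbsim.phantom import BACKGROUND_MD, PhantomSpec, TractSpec
    from dbsim.phantom import _line

    md = 1.15 * BACKGROUND_MD
    bed = TractSpec(
        "bed", _line((3.0, 0.0, -16.0), (3.0, 0.0, 16.0)), 9.0, 0.55, md, 8.7
    )
    bundle = TractSpec(
        "ON-like", _line((4.5, 0.5, -14.0), (4.5, -0.5, 14.0)), 1.5, 0.55, md, 8.7
    )
    return Study(
        phantom_spec=PhantomSpec(shape=(40, 40, 40), tracts=[bed, bundle], seed=SEED),
        lead=default_lead(),
        n_axons=100,
        seed=SEED,
        solver_opts=dict(TEST_SOLVER_OPTS),
    )
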