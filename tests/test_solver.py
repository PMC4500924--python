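"""Volume conductor: operator structure, interpolation, linearity, export."""

import numpy as np
import pytest

from dbsim import solver
from dbsim.phantom import default_lead
from dbsim.tensors import ConductivityField


def random_tensor_field(rng, shape=(5, 5, 5), scale=0.3, voxel=2.0):
    a = rng.normal(size=shape + (3, 3))
    data = scale * (np.einsum("...ij,...kj->...ik", a, a) / 3.0 + 0.2 * np.eye(3))
    origin = -0.5 * voxel * (np.asarray(shape) - 1)
    return ConductivityField(data=data, voxel_size=voxel, origin=origin)


@pytest.fixture(scope="module")
def small_system():
    rng = np.random.default_rng(0)
    f = random_tensor_field(rng)
    g = solver.RectilinearGrid(
        np.linspace(-4, 4, 9), np.linspace(-4, 4, 9), np.linspace(-4, 4, 9)
    )
    return solver.assemble_operator(f, None, grid=g, domain_radius=100.0)


class TestOperator:
    def test_symmetric(self, small_system):
        K = small_system.K
        assert abs(K - K.T).max() < 1e-14 * abs(K).max()

    def test_row_sums_vanish(self, small_system):
        # constants are in the kernel of the pure-Neumann operator
        rs = np.abs(np.asarray(small_system.K.sum(axis=1))).max()
        assert rs < 1e-12

    def test_exact_on_linear_potentials(self):
        # uniform anisotropic medium: sigma grad v constant, so interior
        # nodal residuals vanish exactly for a linear potential
        S = np.array([[0.4, 0.05, 0.0], [0.05, 0.3, 0.02], [0.0, 0.02, 0.2]])
        f = ConductivityField(
            data=np.broadcast_to(S, (5, 5, 5, 3, 3)).copy(),
            voxel_size=2.0, origin=-4.0 * np.ones(3),
        )
        g = solver.RectilinearGrid(
            np.linspace(-4, 4, 9), np.linspace(-4, 4, 9), np.linspace(-4, 4, 9)
        )
        system = solver.assemble_operator(f, None, grid=g, domain_radius=100.0)
        coords = g.node_coordinates()
        v = coords @ np.array([1.0, -2.0, 0.5])
        r = system.K @ v
        interior = np.all(np.abs(coords) < 4 - 1e-9, axis=1)
        assert np.abs(r[interior]).max() < 1e-12

    def test_positive_semidefinite(self, small_system):
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.normal(size=small_system.K.shape[0])
            assert v @ (small_system.K @ v) >= -1e-12

    def test_near_lead_spacing_guard(self):
        f = solver.isotropic_field(0.3)
        with pytest.raises(ValueError, match="0.5 mm"):
            solver.assemble_operator(f, default_lead(), fine_spacing=0.8)


class TestSmallSolveAgainstDense:
    def test_cg_matches_dense_solve(self, small_system):
        rng = np.random.default_rng(2)
        coords = small_system.grid.node_coordinates()
        dir_mask = np.abs(coords[:, 0]) > 4 - 1e-9  # two opposite faces
        sol = solver.solve_potential(
            small_system, source_point=(0.3, -0.2, 0.1),
            dirichlet_mask=dir_mask,
        )
        K = small_system.K.toarray()
        b = solver._trilinear_source(small_system.grid, np.array([0.3, -0.2, 0.1]), 1e-3)
        free = ~dir_mask
        x = np.zeros(K.shape[0])
        x[free] = np.linalg.solve(K[np.ix_(free, free)], b[free])
        assert np.allclose(sol.potential_v.ravel(), x, atol=1e-9)

    def test_linearity_in_current(self, small_system):
        coords = small_system.grid.node_coordinates()
        dir_mask = np.abs(coords[:, 0]) > 4 - 1e-9
        s1 = solver.solve_potential(
            small_system, source_point=(0, 0, 0), dirichlet_mask=dir_mask,
            current_ma=1.0,
        )
        s2 = solver.solve_potential(
            small_system, source_point=(0, 0, 0), dirichlet_mask=dir_mask,
            current_ma=2.0,
        )
        assert np.allclose(s2.potential_v, 2.0 * s1.potential_v, atol=1e-12)
        assert np.allclose(s1.scaled(2.0).potential_v, s2.potential_v, atol=1e-12)


class TestSampling:
    def make_solution(self):
        g = solver.RectilinearGrid(
            np.linspace(0, 2, 3), np.linspace(0, 2, 3), np.linspace(0, 2, 3)
        )
        v = g.node_coordinates()[:, 0].reshape(3, 3, 3)  # V = x
        return solver.FieldSolution(
            grid=g, potential_v=v, contact=None, current_ma=1.0,
            residual=0.0, source_mm=np.zeros(3),
        )

    def test_exact_at_nodes(self):
        sol = self.make_solution()
        assert solver.sample_potential(sol, [[1.0, 1.0, 1.0]])[0] == 1.0

    def test_midpoint_is_mean_in_linear_field(self):
        sol = self.make_solution()
        assert solver.sample_potential(sol, [[0.5, 0.0, 0.0]])[0] == pytest.approx(0.5)

    def test_outside_domain_rejected(self):
        sol = self.make_solution()
        with pytest.raises(ValueError):
            solver.sample_potential(sol, [[5.0, 0.0, 0.0]])


class TestGradedGrid:
    def test_fine_core_spacing(self):
        lead = default_lead()
        g = solver.build_grid(lead, fine_spacing=0.5)
        # the interval containing each contact center is at (or finer than)
        # the requested near-lead spacing; the uniform core divides the fine
        # region evenly so it can land slightly below the nominal value
        for c in lead.contact_centers():
            for a, p in zip(g.axes, c):
                i = np.searchsorted(a, p) - 1
                h = a[i + 1] - a[i]
                assert 0.3 <= h <= 0.5 + 1e-9

    def test_covers_domain_box(self):
        g = solver.build_grid(default_lead(), fine_spacing=0.5)
        for a in g.axes:
            assert a[0] <= -21 + 1e-9 and a[-1] >= 21 - 1e-9
            assert np.all(np.diff(a) > 0)


class TestExports:
    def make_small_solution(self):
        g = solver.RectilinearGrid(
            np.linspace(-2, 2, 5), np.linspace(-2, 2, 5), np.linspace(-2, 2, 5)
        )
        rng = np.random.default_rng(3)
        return solver.FieldSolution(
            grid=g, potential_v=rng.normal(size=(5, 5, 5)), contact=2,
            current_ma=1.0, residual=1e-11, source_mm=np.array([0.0, 0.0, 0.5]),
        )

    def test_hdf5_round_trip(self, tmp_path):
        sol = self.make_small_solution()
        p = tmp_path / "sol.h5"
        sol.to_hdf5(p)
        back = solver.FieldSolution.from_hdf5(p)
        assert np.allclose(back.potential_v, sol.potential_v)
        assert back.contact == 2
        assert np.allclose(back.source_mm, sol.source_mm)

    def test_vtk_header(self, tmp_path):
        sol = self.make_small_solution()
        p = tmp_path / "sol.vtk"
        sol.to_vtk(p)
        text = p.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert "DATASET RECTILINEAR_GRID" in text
        assert "DIMENSIONS 5 5 5" in text

    def test_nifti_export(self, tmp_path):
        import nibabel as nib

        sol = self.make_small_solution()
        p = tmp_path / "sol.nii.gz"
        sol.to_nifti(p, spacing=1.0)
        img = nib.load(p)
        assert img.shape == (5, 5, 5)


def test_empty_dirichlet_rejected(small_system):
    with pytest.raises(ValueError, match="Dirichlet"):
        solver.solve_potential(
            small_system, source_point=(0, 0, 0),
            dirichlet_mask=np.zeros(small_system.grid.n_nodes, bool),
        )


class TestHomogeneousFieldShape:
    """Qualitative invariants of the solved fields (shared oracle solves)."""

    def test_monotone_decay_with_distance(self, iso_oracle):
        _, sol = iso_oracle
        rng = np.random.default_rng(4)
        dirs = rng.normal(size=(10, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = np.linspace(1.0, 15.0, 30)
        for d in dirs:
            v = np.abs(sol.sample(radii[:, None] * d[None, :]))
            assert (np.diff(v) < 0).all()

    def test_anisotropic_isosurfaces_elongated(self, aniso_oracle):
        # at a fixed potential the isosurface radius along each principal
        # axis scales as sqrt(sigma_axis): max/min ratio beats 1 + FA/2
        from dbsim.tensors import fractional_anisotropy

        _, sol = aniso_oracle
        sig = np.diag(np.asarray(
            __import__("conftest").ANISO_SIGMA
        ))
        v0 = float(sol.sample([[0.0, 0.0, 6.0]])[0])

        def radius_along(axis):
            lo, hi = 1.0, 15.0
            e = np.zeros(3)
            e[axis] = 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if sol.sample([mid * e])[0] > v0:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        radii = np.array([radius_along(k) for k in range(3)])
        fa = fractional_anisotropy(sig)
        assert radii.max() / radii.min() > 1.0 + fa / 2.0
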