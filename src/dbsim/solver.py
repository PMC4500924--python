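"""Quasi-static anisotropic volume conductor on a graded rectilinear grid.

Solves ``div(sigma grad V) = -I delta(x - x_c)`` for monopolar stimulation:
a point current source at the geometric center of the active contact, a
250 um encapsulation shell (0.18 S/m) around the insulating lead shaft,
metal contact bands, a 20 mm tissue sphere, and a grounded return patch on
the sphere boundary where the lead trajectory exits (the stand-in for a
grounded cranial chamber).

Discretization: trilinear hexahedral finite elements with 2x2x2 Gauss
quadrature on a tensor-product grid graded from 0.25 mm near the lead to
~1 mm at the domain boundary.  The element conductivity is sampled by
nearest-neighbor lookup from the (coarser) conductivity-tensor voxel grid,
with geometric overrides for the lead, encapsulation, and out-of-sphere
region (where sigma = 0, so exterior nodes drop out and the staircase
sphere surface is a natural no-flux boundary).  The assembled operator is
symmetric positive definite on the active nodes and is solved by
Jacobi-preconditioned conjugate gradients to a 1e-10 relative tolerance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .lead import LeadSpec
from .tensors import ConductivityField

__all__ = [
    "RectilinearGrid",
    "DiscreteSystem",
    "FieldSolution",
    "build_grid",
    "assemble_operator",
    "solve_potential",
    "sample_potential",
    "isotropic_field",
    "point_source_potential_iso",
    "point_source_potential_aniso",
    "surface_flux",
]

CG_TOL = 1e-10          # relative CG tolerance
RESIDUAL_LIMIT = 1e-8   # acceptance limit on the reported relative residual


@dataclass
class RectilinearGrid:
    """Tensor-product grid given by node coordinates along each axis (mm)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.x), len(self.y), len(self.z))

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.x, self.y, self.z)

    def node_coordinates(self) -> np.ndarray:
        gx, gy, gz = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    def min_spacing(self) -> float:
        return float(min(np.diff(a).min() for a in self.axes))


def _graded_axis(
    fine_lo: float,
    fine_hi: float,
    fine_spacing: float,
    lo: float,
    hi: float,
    coarse_spacing: float,
    growth: float,
) -> np.ndarray:
    """Node coordinates: uniform fine core, geometrically graded flanks."""
    n_fine = max(1, int(np.ceil((fine_hi - fine_lo) / fine_spacing)))
    core = np.linspace(fine_lo, fine_hi, n_fine + 1)
    right = [core[-1]]
    h = fine_spacing
    while right[-1] < hi:
        h = min(h * growth, coarse_spacing)
        right.append(right[-1] + h)
    right[-1] = hi
    if len(right) > 2 and right[-1] - right[-2] < 0.3 * coarse_spacing:
        del right[-2]
    left = [core[0]]
    h = fine_spacing
    while left[-1] > lo:
        h = min(h * growth, coarse_spacing)
        left.append(left[-1] - h)
    left[-1] = lo
    if len(left) > 2 and left[-2] - left[-1] < 0.3 * coarse_spacing:
        del left[-2]
    return np.concatenate([left[::-1][:-1], core, right[1:]])


def build_grid(
    lead: LeadSpec | None = None,
    fine_spacing: float = 0.25,
    fine_margin: float = 3.0,
    coarse_spacing: float = 1.0,
    growth: float = 1.4,
    box_halfwidth: float = 21.0,
    center=(0.0, 0.0, 0.0),
    fine_box: tuple | None = None,
) -> RectilinearGrid:
    """Grid graded around the lead (or an explicit fine box).

    The fine region covers the lead's bounding box plus ``fine_margin`` at
    ``fine_spacing``; spacing grows geometrically to ``coarse_spacing``
    toward the domain box.
    """
    center = np.asarray(center, dtype=float)
    if fine_box is not None:
        lo_f, hi_f = (np.asarray(v, dtype=float) for v in fine_box)
    elif lead is not None:
        pts = np.vstack([lead.tip, lead.shaft_top()])
        lo_f = pts.min(axis=0) - fine_margin
        hi_f = pts.max(axis=0) + fine_margin
    else:
        lo_f = center - fine_margin
        hi_f = center + fine_margin
    axes = []
    for d in range(3):
        axes.append(
            _graded_axis(
                lo_f[d],
                hi_f[d],
                fine_spacing,
                center[d] - box_halfwidth,
                center[d] + box_halfwidth,
                coarse_spacing,
                growth,
            )
        )
    return RectilinearGrid(*axes)


def isotropic_field(
    sigma_s_per_m: float,
    shape=(21, 21, 21),
    voxel_size: float = 2.0,
    origin=None,
) -> ConductivityField:
    """Homogeneous isotropic conductivity field (testing and the iso model)."""
    shape = tuple(shape)
    if origin is None:
        origin = -0.5 * voxel_size * (np.asarray(shape, dtype=float) - 1)
    data = np.broadcast_to(
        sigma_s_per_m * np.eye(3), shape + (3, 3)
    ).copy()
    return ConductivityField(
        data=data, voxel_size=voxel_size, origin=np.asarray(origin, float),
        isotropic=True,
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

_GAUSS = 0.5 + np.array([-1.0, 1.0]) / (2.0 * np.sqrt(3.0))


def _reference_gradients() -> np.ndarray:
    """dN/dxi for the 8 trilinear basis functions at the 8 Gauss points.

    Returns G with shape (8 gauss, 3 dims, 8 basis); node a = (da, db, dc)
    has flat index da*4 + db*2 + dc.
    """
    G = np.empty((8, 3, 8))
    gi = 0
    for g1 in _GAUSS:
        for g2 in _GAUSS:
            for g3 in _GAUSS:
                xi = (g1, g2, g3)
                for a in range(8):
                    dd = ((a >> 2) & 1, (a >> 1) & 1, a & 1)
                    for d in range(3):
                        val = 1.0
                        for e in range(3):
                            w = xi[e] if dd[e] else 1.0 - xi[e]
                            if e == d:
                                val *= 1.0 if dd[e] else -1.0
                            else:
                                val *= w
                        G[gi, d, a] = val
                gi += 1
    return G


_G_REF = _reference_gradients()


@dataclass
class DiscreteSystem:
    """Assembled FEM operator plus the geometry needed for solves."""

    grid: RectilinearGrid
    K: sp.csr_matrix
    field: ConductivityField
    lead: LeadSpec | None
    domain_center: np.ndarray
    domain_radius: float

    def sigma_at(self, points: np.ndarray) -> np.ndarray:
        """Effective conductivity tensors (S/m) at world points."""
        return _sigma_lookup(
            np.atleast_2d(np.asarray(points, dtype=float)),
            self.field,
            self.lead,
            self.domain_center,
            self.domain_radius,
        )

    @property
    def active(self) -> np.ndarray:
        """Nodes touched by at least one conducting element."""
        return np.asarray(self.K.diagonal() > 0.0)

    def boundary_mask(self, mode: str = "cap") -> np.ndarray:
        """Dirichlet node mask: 'cap' ground patch or full 'shell'.

        Only active nodes are eligible; the staircase sphere surface is
        otherwise a natural no-flux boundary.
        """
        coords = self.grid.node_coordinates()
        r = np.linalg.norm(coords - self.domain_center, axis=1)
        act = self.active
        if mode == "shell":
            return act & (r >= self.domain_radius - 1e-9)
        if mode == "cap":
            if self.lead is None:
                raise ValueError("cap boundary requires a lead (entry direction)")
            gp = self.lead.ground_point()
            return (
                act
                & (r >= self.domain_radius - 1.0)
                & (np.linalg.norm(coords - gp, axis=1) <= self.lead.ground_patch_radius)
            )
        raise ValueError("boundary mode must be 'cap' or 'shell'")


def _sigma_lookup(
    centers: np.ndarray,
    fieldc: ConductivityField,
    lead: LeadSpec | None,
    domain_center: np.ndarray,
    domain_radius: float,
) -> np.ndarray:
    idx = np.rint((centers - fieldc.origin) / fieldc.voxel_size).astype(int)
    for d in range(3):
        idx[:, d] = np.clip(idx[:, d], 0, fieldc.shape[d] - 1)
    sig = fieldc.data[idx[:, 0], idx[:, 1], idx[:, 2]].copy()
    eye = np.eye(3)
    r = np.linalg.norm(centers - domain_center, axis=1)
    # outside the tissue sphere: sigma = 0, i.e. the staircase sphere surface
    # becomes a natural no-flux boundary and exterior nodes drop out
    sig[r > domain_radius] = 0.0
    if lead is not None:
        d_ax = lead.axis_distance(centers)
        enc = (d_ax > lead.radius) & (
            d_ax <= lead.radius + lead.encapsulation_thickness
        )
        sig[enc] = lead.encapsulation_sigma * eye
        body = d_ax <= lead.radius
        sig[body] = lead.lead_body_sigma * eye
        s_ax = (centers - lead.tip) @ lead.direction
        for c in lead.contact_centers():
            s_c = (c - lead.tip) @ lead.direction
            band = body & (np.abs(s_ax - s_c) <= lead.contact_height / 2.0)
            sig[band] = lead.contact_sigma * eye
    return sig


def assemble_operator(
    fieldc: ConductivityField,
    lead: LeadSpec | None = None,
    grid: RectilinearGrid | None = None,
    fine_spacing: float = 0.25,
    domain_center=(0.0, 0.0, 0.0),
    domain_radius: float = 20.0,
    chunk: int = 80_000,
) -> DiscreteSystem:
    """Assemble the stiffness operator for ``div(sigma grad V)``.

    ``fine_spacing`` must resolve the encapsulation shell near the lead
    (<= 0.5 mm); the default 0.25 mm matches the shell thickness.
    """
    if lead is not None and fine_spacing > 0.5 + 1e-12:
        raise ValueError("near-lead grid spacing must be <= 0.5 mm")
    domain_center = np.asarray(domain_center, dtype=float)
    if grid is None:
        grid = build_grid(lead, fine_spacing=fine_spacing, center=domain_center,
                          box_halfwidth=domain_radius + 1.0)
    nx, ny, nz = grid.shape
    hx, hy, hz = (np.diff(a) for a in grid.axes)
    cx, cy, cz = (0.5 * (a[:-1] + a[1:]) for a in grid.axes)
    ne = (nx - 1) * (ny - 1) * (nz - 1)

    # flat element index -> (i, j, k)
    ejk = (ny - 1) * (nz - 1)
    rows_all, cols_all, vals_all = [], [], []
    for start in range(0, ne, chunk):
        stop = min(start + chunk, ne)
        e = np.arange(start, stop)
        ei = e // ejk
        ej = (e % ejk) // (nz - 1)
        ek = e % (nz - 1)
        centers = np.stack([cx[ei], cy[ej], cz[ek]], axis=1)
        h = np.stack([hx[ei], hy[ej], hz[ek]], axis=1)  # (m, 3)
        sig = _sigma_lookup(centers, fieldc, lead, domain_center, domain_radius)
        lam = np.linalg.eigvalsh(sig)
        inside = np.linalg.norm(centers - domain_center, axis=1) <= domain_radius
        if inside.any() and lam[inside].min() <= 0:
            bad = e[inside][np.nonzero(lam[inside].min(axis=1) <= 0)[0][0]]
            raise ValueError(
                f"non-positive-definite conductivity in element {bad}"
            )
        vol = h.prod(axis=1)
        Kloc = np.zeros((len(e), 8, 8))
        for g in range(8):
            B = _G_REF[g][None, :, :] / h[:, :, None]  # (m, 3, 8)
            Kloc += np.einsum("mda,mde,meb->mab", B, sig * 1e-3, B)
        Kloc *= (vol / 8.0)[:, None, None]
        # global node ids for the 8 element corners
        base = (ei * ny + ej) * nz + ek
        offs = np.array(
            [((a >> 2) & 1) * ny * nz + ((a >> 1) & 1) * nz + (a & 1) for a in range(8)]
        )
        nodes = base[:, None] + offs[None, :]  # (m, 8)
        rows_all.append(np.repeat(nodes, 8, axis=1).ravel())
        cols_all.append(np.tile(nodes, (1, 8)).ravel())
        vals_all.append(Kloc.ravel())
    n = grid.n_nodes
    K = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n),
    ).tocsr()
    return DiscreteSystem(
        grid=grid,
        K=K,
        field=fieldc,
        lead=lead,
        domain_center=domain_center,
        domain_radius=domain_radius,
    )


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------


@dataclass
class FieldSolution:
    """Nodal potential (V) for a unit stimulus current through one contact."""

    grid: RectilinearGrid
    potential_v: np.ndarray   # (nx, ny, nz), volts
    contact: int | None
    current_ma: float
    residual: float
    source_mm: np.ndarray

    def sample(self, points: np.ndarray) -> np.ndarray:
        return sample_potential(self, points)

    def scaled(self, current_ma: float) -> "FieldSolution":
        """Linearity in the injected current."""
        f = current_ma / self.current_ma
        return FieldSolution(
            grid=self.grid,
            potential_v=self.potential_v * f,
            contact=self.contact,
            current_ma=current_ma,
            residual=self.residual,
            source_mm=self.source_mm,
        )

    # -- export ------------------------------------------------------------

    def to_vtk(self, path) -> None:
        """Legacy-ASCII VTK rectilinear grid with the potential as a scalar."""
        nx, ny, nz = self.grid.shape
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("potential per unit current (V/mA)\nASCII\n")
            fh.write("DATASET RECTILINEAR_GRID\n")
            fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
            for name, a in zip("XYZ", self.grid.axes):
                fh.write(f"{name}_COORDINATES {len(a)} float\n")
                fh.write(" ".join(f"{v:.6g}" for v in a) + "\n")
            fh.write(f"POINT_DATA {self.grid.n_nodes}\n")
            fh.write("SCALARS potential float 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest; our array is z fastest
            vals = np.transpose(self.potential_v, (2, 1, 0)).ravel()
            fh.write("\n".join(f"{v:.8g}" for v in vals) + "\n")

    def to_nifti(self, path, spacing: float = 0.5) -> None:
        """Resample onto a uniform grid and save as NIfTI."""
        import nibabel as nib
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(self.grid.axes, self.potential_v)
        axes = [
            np.arange(a[0], a[-1] + spacing / 2, spacing) for a in self.grid.axes
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        vol = interp(np.stack([gx, gy, gz], axis=-1))
        affine = np.diag([spacing] * 3 + [1.0])
        affine[:3, 3] = [a[0] for a in axes]
        nib.save(nib.Nifti1Image(vol, affine), str(path))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name, a in zip("xyz", self.grid.axes):
                f.create_dataset(f"grid/{name}", data=a)
            f.create_dataset("potential_v", data=self.potential_v)
            f.attrs["contact"] = -1 if self.contact is None else self.contact
            f.attrs["current_ma"] = self.current_ma
            f.attrs["residual"] = self.residual
            f.attrs["source_mm"] = self.source_mm

    @classmethod
    def from_hdf5(cls, path) -> "FieldSolution":
        import h5py

        with h5py.File(path, "r") as f:
            grid = RectilinearGrid(
                f["grid/x"][:], f["grid/y"][:], f["grid/z"][:]
            )
            contact = int(f.attrs["contact"])
            return cls(
                grid=grid,
                potential_v=f["potential_v"][:],
                contact=None if contact < 0 else contact,
                current_ma=float(f.attrs["current_ma"]),
                residual=float(f.attrs["residual"]),
                source_mm=np.asarray(f.attrs["source_mm"]),
            )


def _trilinear_source(grid: RectilinearGrid, point: np.ndarray, current_a: float):
    """Distribute a point current over the corners of its containing cell."""
    idx = []
    w = []
    for a, p in zip(grid.axes, point):
        i = int(np.clip(np.searchsorted(a, p) - 1, 0, len(a) - 2))
        t = (p - a[i]) / (a[i + 1] - a[i])
        idx.append(i)
        w.append(np.clip(t, 0.0, 1.0))
    nx, ny, nz = grid.shape
    b = np.zeros(grid.n_nodes)
    for da in range(2):
        for db in range(2):
            for dc in range(2):
                weight = (
                    (w[0] if da else 1 - w[0])
                    * (w[1] if db else 1 - w[1])
                    * (w[2] if dc else 1 - w[2])
                )
                node = ((idx[0] + da) * ny + idx[1] + db) * nz + idx[2] + dc
                b[node] += current_a * weight
    return b


def solve_potential(
    system: DiscreteSystem,
    contact: int | None = 0,
    current_ma: float = 1.0,
    source_point=None,
    boundary: str = "cap",
    boundary_values=None,
    dirichlet_mask=None,
) -> FieldSolution:
    """Solve for the potential of one monopolar source.

    ``contact`` selects the lead contact (0 distal ... 7 proximal) whose
    geometric center carries the point source; ``source_point`` overrides
    it for lead-free oracle runs.  ``boundary_values`` may be a callable
    ``V(points) -> volts`` imposed on the Dirichlet nodes (closed-form
    verification); by default the boundary is grounded (V = 0).
    """
    if source_point is not None:
        src = np.asarray(source_point, dtype=float)
    else:
        if system.lead is None:
            raise ValueError("no lead in system; pass source_point")
        if not 0 <= contact < system.lead.n_contacts:
            raise ValueError(f"contact must be in 0..{system.lead.n_contacts - 1}")
        src = system.lead.contact_centers()[contact]

    K = system.K
    n = K.shape[0]
    b = _trilinear_source(system.grid, src, current_ma * 1e-3)

    if dirichlet_mask is not None:
        dir_mask = np.asarray(dirichlet_mask, dtype=bool)
    else:
        dir_mask = system.boundary_mask(boundary)
    if not dir_mask.any():
        raise ValueError("empty Dirichlet boundary; system would be singular")
    free = system.active & ~dir_mask
    x = np.zeros(n)
    if boundary_values is not None:
        coords = system.grid.node_coordinates()[dir_mask]
        x[dir_mask] = boundary_values(coords)
    b_f = b[free] - K[free][:, dir_mask] @ x[dir_mask]
    K_ff = K[free][:, free].tocsr()

    nf = K_ff.shape[0]
    diag = K_ff.diagonal()
    M = spla.LinearOperator((nf, nf), lambda v: v / diag)
    xf, info = spla.cg(K_ff, b_f, rtol=CG_TOL, maxiter=20000, M=M)
    scale = max(np.linalg.norm(b_f), 1e-300)
    residual = float(np.linalg.norm(K_ff @ xf - b_f) / scale)
    if info != 0 or residual > RESIDUAL_LIMIT:
        raise RuntimeError(
            f"solver failed to converge (info={info}, residual={residual:.2e})"
        )
    x[free] = xf
    return FieldSolution(
        grid=system.grid,
        potential_v=x.reshape(system.grid.shape),
        contact=None if source_point is not None else contact,
        current_ma=current_ma,
        residual=residual,
        source_mm=src,
    )


def sample_potential(solution: FieldSolution, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the potential (V); exact at grid nodes."""
    from scipy.interpolate import RegularGridInterpolator

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    interp = RegularGridInterpolator(
        solution.grid.axes, solution.potential_v, bounds_error=True
    )
    return interp(pts)


# ---------------------------------------------------------------------------
# Closed-form oracles and diagnostics
# ---------------------------------------------------------------------------


def point_source_potential_iso(
    points_mm,
    source_mm,
    sigma_s_per_m: float,
    current_ma: float = 1.0,
    ground_radius_mm: float | None = None,
):
    """Free-space (or grounded-sphere) potential of a point source, volts."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    r_m = np.linalg.norm(pts - np.asarray(source_mm, float), axis=1) * 1e-3
    v = current_ma * 1e-3 / (4.0 * np.pi * sigma_s_per_m * r_m)
    if ground_radius_mm is not None:
        v = v - current_ma * 1e-3 / (
            4.0 * np.pi * sigma_s_per_m * ground_radius_mm * 1e-3
        )
    return v


def point_source_potential_aniso(
    points_mm, source_mm, sigma_tensor_s_per_m, current_ma: float = 1.0
):
    """Free-space potential of a point source in a homogeneous anisotropic
    medium: ``V = I / (4 pi sqrt(det S) sqrt(x^T S^-1 x))``."""
    S = np.asarray(sigma_tensor_s_per_m, dtype=float)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    x_m = (pts - np.asarray(source_mm, float)) * 1e-3
    Sinv = np.linalg.inv(S)
    q = np.einsum("ni,ij,nj->n", x_m, Sinv, x_m)
    return current_ma * 1e-3 / (4.0 * np.pi * np.sqrt(np.linalg.det(S)) * np.sqrt(q))


def surface_flux(
    solution: FieldSolution,
    system: DiscreteSystem,
    center,
    halfwidth: float,
    n_per_edge: int = 40,
    eps_mm: float = 0.05,
) -> float:
    """Total current (mA) through the boundary of a box around ``center``.

    The flux of ``-sigma grad V`` is integrated with a midpoint rule; the
    gradient is taken by central differences of the interpolated potential.
    An independent discrete-conservation check: for any box enclosing the
    source the result should equal the injected current.
    """
    center = np.asarray(center, dtype=float)
    total = 0.0
    for d in range(3):
        for sgn in (-1.0, 1.0):
            u = np.linspace(-halfwidth, halfwidth, n_per_edge + 1)
            u = 0.5 * (u[:-1] + u[1:])
            uu, vv = np.meshgrid(u, u, indexing="ij")
            pts = np.tile(center, (uu.size, 1))
            pts[:, d] += sgn * halfwidth
            o1, o2 = [(1, 2), (0, 2), (0, 1)][d]
            pts[:, o1] += uu.ravel()
            pts[:, o2] += vv.ravel()
            grad = np.empty((len(pts), 3))
            for dd in range(3):
                lo = pts.copy()
                hi = pts.copy()
                lo[:, dd] -= eps_mm
                hi[:, dd] += eps_mm
                grad[:, dd] = (
                    sample_potential(solution, hi) - sample_potential(solution, lo)
                ) / (2.0 * eps_mm * 1e-3)  # V/m
            sig = system.sigma_at(pts)
            jn = -np.einsum("nij,nj->ni", sig, grad)[:, d] * sgn  # A/m^2
            dA = (2.0 * halfwidth * 1e-3 / n_per_edge) ** 2
            total += jn.sum() * dA
    return total * 1e3  # A -> mA


def config_hash(*parts) -> str:
    """Stable hash for caching solved fields on disk."""
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]
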