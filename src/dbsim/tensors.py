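"""Diffusion-tensor algebra and the diffusion-to-conductivity mapping.

The volume conductor model derives its tissue conductivity tensor field from
a diffusion-tensor volume via the linear mapping ``sigma = s * D`` (Tuch's
effective-medium relationship): conductivity and water diffusion share
eigenvectors, and conductivity eigenvalues are proportional to diffusion
eigenvalues.  With ``D`` in mm^2/s and the scaling factor ``s`` in
S*s/mm^3, ``s * D`` carries S/mm; values are reported in S/m.

Fractional anisotropy (FA) is the Pierpaoli normalized eigenvalue
dispersion: 0 for an isotropic tensor, 1 in the rank-one limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TensorVolume",
    "ConductivityField",
    "HistogramSummary",
    "eigendecompose",
    "fractional_anisotropy",
    "conductivity_from_diffusion",
    "conductivity_histograms",
    "DEFAULT_SCALING_FACTOR",
    "ISOTROPIC_SIGMA",
]

#: Conductivity scaling factor s (S*s/mm^3), center of the reported
#: empirical range s = 0.844 +/- 0.0545.
DEFAULT_SCALING_FACTOR = 0.844

#: Homogeneous isotropic tissue conductivity (S/m) used by the isotropic
#: volume conductor variant.
ISOTROPIC_SIGMA = 0.3

# Lower-triangular component order used for NIfTI serialization:
# (xx, xy, yy, xz, yz, zz) -- the standard NIfTI tensor intent layout.
_LOWER_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]

_EIG_FLOOR = 1e-12  # clamp for numerically negative diffusion eigenvalues


def _check_symmetric(t: np.ndarray, tol: float = 1e-8) -> None:
    if t.shape[-2:] != (3, 3):
        raise ValueError(f"expected trailing (3, 3) tensor shape, got {t.shape}")
    asym = np.abs(t - np.swapaxes(t, -1, -2)).max()
    scale = max(np.abs(t).max(), 1.0)
    if asym > tol * scale:
        raise ValueError(f"tensor not symmetric (max asymmetry {asym:.3e})")


def eigendecompose(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose symmetric 3x3 tensors, eigenvalues sorted descending.

    Parameters
    ----------
    tensor : array, shape (..., 3, 3)
        Symmetric tensors.

    Returns
    -------
    eigenvalues : array, shape (..., 3)
        Sorted so ``lam[..., 0] >= lam[..., 1] >= lam[..., 2]``.
    eigenvectors : array, shape (..., 3, 3)
        Orthonormal; column ``[..., :, k]`` pairs with eigenvalue ``k``.
    """
    tensor = np.asarray(tensor, dtype=float)
    _check_symmetric(tensor)
    lam, vec = np.linalg.eigh(tensor)  # ascending
    lam = lam[..., ::-1]
    vec = vec[..., ::-1]
    return lam, vec


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """Pierpaoli fractional anisotropy of eigenvalue triples.

    FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, in [0, 1].  Invariant to
    a common positive rescaling of the eigenvalues and to their order.
    All-zero triples are defined as FA = 0 (with a warning): a null tensor
    carries no orientation information.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalue array must have trailing dimension 3")
    norm2 = np.sum(lam * lam, axis=-1)
    zero = norm2 == 0.0
    if np.any(zero):
        warnings.warn("all-zero eigenvalue triple(s); FA defined as 0", stacklevel=2)
    mean = lam.mean(axis=-1, keepdims=True)
    dev2 = np.sum((lam - mean) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.where(zero, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)


@dataclass
class TensorVolume:
    """Regular 3D grid of symmetric diffusion tensors.

    Attributes
    ----------
    data : array, shape (nx, ny, nz, 3, 3)
        Diffusion tensors, mm^2/s.
    voxel_size : float
        Isotropic voxel edge, mm.
    origin : array, shape (3,)
        World position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 5 or self.data.shape[-2:] != (3, 3):
            raise ValueError("data must have shape (nx, ny, nz, 3, 3)")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        _check_symmetric(self.data)
        # symmetrize exactly and clamp tiny negative eigenvalues
        self.data = 0.5 * (self.data + np.swapaxes(self.data, -1, -2))
        lam = np.linalg.eigvalsh(self.data)
        if lam.min() < -_EIG_FLOOR * max(1.0, np.abs(self.data).max()):
            raise ValueError("diffusion tensors must be positive semidefinite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers along each axis."""
        return tuple(
            self.origin[i] + self.voxel_size * np.arange(self.shape[i])
            for i in range(3)
        )

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        return eigendecompose(self.data)

    def fa(self) -> np.ndarray:
        lam, _ = self.eigensystem()
        return fractional_anisotropy(np.clip(lam, 0.0, None))

    # -- NIfTI round trip (6-component lower-triangular layout) ------------

    def to_nifti(self, path) -> None:
        import nibabel as nib

        comp = np.stack([self.data[..., i, j] for i, j in _LOWER_TRI], axis=-1)
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(comp.astype(np.float64), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "TensorVolume":
        import nibabel as nib

        img = nib.load(str(path))
        comp = np.asarray(img.dataobj, dtype=float)
        if comp.ndim != 4 or comp.shape[-1] != 6:
            raise ValueError("expected a 4D NIfTI with 6 tensor components")
        data = np.empty(comp.shape[:3] + (3, 3))
        for k, (i, j) in enumerate(_LOWER_TRI):
            data[..., i, j] = comp[..., k]
            data[..., j, i] = comp[..., k]
        vox = float(img.affine[0, 0])
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(data=data, voxel_size=vox, origin=origin)


@dataclass
class ConductivityField(TensorVolume):
    """Symmetric conductivity tensors (S/m) on a regular grid.

    ``isotropic`` marks fields whose tensors are all scalar multiples of the
    identity; the solver exploits this only for bookkeeping (both paths run
    the same discretization).
    """

    isotropic: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        floor = 1e-6  # S/m; keeps the discrete operator positive definite
        lam, vec = np.linalg.eigh(self.data)
        if lam.min() < floor:
            lam = np.clip(lam, floor, None)
            self.data = np.einsum("...ik,...k,...jk->...ij", vec, lam, vec)


def conductivity_from_diffusion(
    volume: TensorVolume, s: float = DEFAULT_SCALING_FACTOR
) -> ConductivityField:
    """Map a diffusion-tensor volume to a conductivity field, sigma = s * D.

    The map is linear, so it can be applied componentwise to the full
    tensor; eigenvectors (and hence FA) are preserved.  ``D`` in mm^2/s with
    ``s`` in S*s/mm^3 gives sigma in S/mm, converted here to S/m.
    """
    if s <= 0:
        raise ValueError("scaling factor s must be positive")
    sigma = s * volume.data * 1000.0  # S/mm -> S/m
    iso = bool(fractional_anisotropy(np.linalg.eigvalsh(sigma)).max() < 1e-9)
    return ConductivityField(
        data=sigma,
        voxel_size=volume.voxel_size,
        origin=volume.origin.copy(),
        isotropic=iso,
    )


@dataclass
class HistogramSummary:
    """Per-eigenvalue-rank conductivity histograms over a voxel mask."""

    bin_edges: np.ndarray          # (nbins + 1,)
    counts: np.ndarray             # (3, nbins); rank 0 = principal
    means: np.ndarray              # (3,)
    sds: np.ndarray                # (3,)
    n_voxels: int

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        names = ("primary", "secondary", "tertiary")
        for r, name in enumerate(names):
            for b in range(self.counts.shape[1]):
                rows.append(
                    {
                        "rank": name,
                        "bin_left": self.bin_edges[b],
                        "bin_right": self.bin_edges[b + 1],
                        "count": int(self.counts[r, b]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def conductivity_histograms(
    field: ConductivityField,
    mask: np.ndarray | None = None,
    bins: int = 50,
) -> HistogramSummary:
    """Histograms of conductivities along the primary/secondary/tertiary axes.

    Mirrors the standard brainstem summary: eigen-decompose every masked
    voxel's conductivity tensor and histogram the three eigenvalue ranks
    separately.
    """
    if mask is None:
        mask = np.ones(field.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.shape:
        raise ValueError("mask shape must match the field grid")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    lam = np.linalg.eigvalsh(field.data[mask])[:, ::-1]  # (n, 3) descending
    lo, hi = lam.min(), lam.max()
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    counts = np.stack([np.histogram(lam[:, r], bins=edges)[0] for r in range(3)])
    return HistogramSummary(
        bin_edges=edges,
        counts=counts,
        means=lam.mean(axis=0),
        sds=lam.std(axis=0),
        n_voxels=int(mask.sum()),
    )
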