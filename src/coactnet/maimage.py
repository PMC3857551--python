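"""Modeled-activation (MA) images from peak coordinates.

Coordinate-based meta-analysis represents each experiment's reported peak
activation foci as a smooth 3D volume: a Gaussian kernel of fixed FWHM is
dropped on every peak and the per-peak kernels are combined voxelwise.
Stacking the masked volumes of all experiments column-wise yields the
voxels x experiments matrix that spatial ICA decomposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = [
    "VolumeGrid",
    "MAMatrix",
    "fwhm_to_sigma",
    "modeled_activation",
    "stack_corpus",
]

# Talairach-like bounding box in mm: x -90..90, y -126..90, z -72..108.
TALAIRACH_BBOX = ((-90.0, 90.0), (-126.0, 90.0), (-72.0, 108.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum (mm) to its sigma (mm)."""
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class VolumeGrid:
    """Isotropic voxel grid with an analysis mask.

    Parameters
    ----------
    origin : world-space (mm) coordinate of voxel (0, 0, 0).
    spacing : isotropic voxel size in mm.
    dims : grid extents (nx, ny, nz).
    mask : boolean array of shape ``dims``; analysis is restricted to
        True voxels.
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.dims):
            raise ValueError(f"mask shape {mask.shape} != dims {self.dims}")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        object.__setattr__(self, "mask", mask)

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing * np.arange(self.dims[axis])

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world coordinates (no bounds check)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return np.rint((xyz - np.asarray(self.origin)) / self.spacing).astype(int)

    def mask_coords(self) -> np.ndarray:
        """World coordinates (n_mask_voxels x 3) of in-mask voxel centers."""
        idx = np.argwhere(self.mask)
        return np.asarray(self.origin) + self.spacing * idx

    def clip_to_mask(self, xyz: np.ndarray) -> tuple[np.ndarray, int]:
        """Snap out-of-mask points to the nearest in-mask voxel center.

        Returns the (possibly modified) coordinates and the number of
        points that had to be moved.
        """
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float)).copy()
        idx = self.world_to_index(xyz)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)
        in_mask = np.zeros(len(xyz), dtype=bool)
        in_mask[inside] = self.mask[tuple(idx[inside].T)]
        n_clipped = int((~in_mask).sum())
        if n_clipped:
            centers = self.mask_coords()
            for i in np.flatnonzero(~in_mask):
                j = np.argmin(np.sum((centers - xyz[i]) ** 2, axis=1))
                xyz[i] = centers[j]
        return xyz, n_clipped

    def to_nifti_mask(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)

    @classmethod
    def talairach(cls, spacing: float = 2.0, mask: str = "ellipsoid") -> "VolumeGrid":
        """Default analysis grid over a Talairach-like bounding box.

        ``mask='ellipsoid'`` inscribes an ellipsoid in the bounding box
        (a crude brain-shaped mask); ``mask='full'`` keeps every voxel.
        """
        origin = tuple(lo for lo, _ in TALAIRACH_BBOX)
        dims = tuple(int(math.floor((hi - lo) / spacing)) + 1 for lo, hi in TALAIRACH_BBOX)
        if mask == "full":
            m = np.ones(dims, dtype=bool)
        elif mask == "ellipsoid":
            axes = [np.linspace(-1.0, 1.0, n) for n in dims]
            xx, yy, zz = np.meshgrid(*axes, indexing="ij")
            m = xx**2 + yy**2 + zz**2 <= 1.0
        else:
            raise ValueError(f"unknown mask kind {mask!r}")
        return cls(origin=origin, spacing=spacing, dims=dims, mask=m)


@dataclass
class MAMatrix:
    """Masked modeled-activation values, voxels x experiments."""

    values: np.ndarray
    grid: VolumeGrid
    experiment_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (voxels x experiments)")
        if self.values.shape[0] != self.grid.n_mask_voxels:
            raise ValueError("row count must equal number of in-mask voxels")
        if (self.values < 0).any():
            raise ValueError("modeled-activation values must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    def voxel_index(self) -> np.ndarray:
        """Row -> (i, j, k) voxel index mapping."""
        return np.argwhere(self.grid.mask)

    def to_nifti(self) -> nib.Nifti1Image:
        """Stacked volumes as 4D NIfTI, experiment as the 4th dimension."""
        vol = np.zeros(self.grid.dims + (self.n_experiments,), dtype=np.float32)
        vol[self.grid.mask, :] = self.values
        return nib.Nifti1Image(vol, self.grid.affine)


def _kernel_box(center: float, sigma: float, axis_coords: np.ndarray, radius_sd: float):
    lo = np.searchsorted(axis_coords, center - radius_sd * sigma, side="left")
    hi = np.searchsorted(axis_coords, center + radius_sd * sigma, side="right")
    sl = slice(lo, hi)
    x = axis_coords[sl]
    return sl, np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def modeled_activation(
    peaks: np.ndarray,
    grid: VolumeGrid,
    fwhm: float = 12.0,
    combine: str = "max",
    kernel_radius_sd: float = 5.0,
) -> np.ndarray:
    """Modeled-activation volume for one experiment's peaks.

    Each peak contributes an unnormalized Gaussian of unit peak height
    (sigma from :func:`fwhm_to_sigma`) evaluated at voxel centers;
    contributions are combined voxelwise with ``max`` (default, so the
    value is a per-voxel activation probability proxy in [0, 1]) or
    ``sum``. Voxels outside the mask are zero. The kernel is truncated at
    ``kernel_radius_sd`` standard deviations.
    """
    peaks = np.atleast_2d(np.asarray(peaks, dtype=float))
    if peaks.size == 0:
        raise ValueError("at least one peak is required")
    if peaks.shape[1] != 3:
        raise ValueError("peaks must be (n, 3)")
    if combine not in ("max", "sum"):
        raise ValueError(f"combine must be 'max' or 'sum', got {combine!r}")
    sigma = fwhm_to_sigma(fwhm)
    vol = np.zeros(grid.dims, dtype=float)
    ax = [grid.axis_coords(a) for a in range(3)]
    for p in peaks:
        slx, kx = _kernel_box(p[0], sigma, ax[0], kernel_radius_sd)
        sly, ky = _kernel_box(p[1], sigma, ax[1], kernel_radius_sd)
        slz, kz = _kernel_box(p[2], sigma, ax[2], kernel_radius_sd)
        if kx.size == 0 or ky.size == 0 or kz.size == 0:
            continue
        blob = np.einsum("i,j,k->ijk", kx, ky, kz)
        if combine == "max":
            np.maximum(vol[slx, sly, slz], blob, out=vol[slx, sly, slz])
        else:
            vol[slx, sly, slz] += blob
    vol[~grid.mask] = 0.0
    return vol


def stack_corpus(corpus, grid: VolumeGrid, fwhm: float = 12.0, combine: str = "max") -> MAMatrix:
    """Stack the masked MA volumes of all experiments into an MAMatrix.

    Column j is the masked flattening of ``modeled_activation`` applied to
    experiment j's peaks; column order follows the corpus experiment order.
    """
    experiments = corpus.experiments
    mask = grid.mask
    values = np.empty((grid.n_mask_voxels, len(experiments)), dtype=float)
    for j, exp in enumerate(experiments):
        if len(exp.peaks) == 0:
            raise ValueError(f"experiment {exp.experiment_id!r} has no peaks")
        values[:, j] = modeled_activation(exp.peaks, grid, fwhm=fwhm, combine=combine)[mask]
    return MAMatrix(values=values, grid=grid, experiment_ids=[e.experiment_id for e in experiments])
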