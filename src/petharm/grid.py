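"""Regular voxel grids and activity-concentration volumes.

World coordinates are in millimetres, RAS-like axis order.  A grid is fully
described by its shape, per-axis spacing and the world coordinate of the
*center* of voxel (0, 0, 0); the center of voxel (i, j, k) is then exactly
``origin + (i, j, k) * spacing``.  Volumes carry activity concentrations in
kBq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "ActivityVolume", "load_volume", "save_volume"]


@dataclass(frozen=True)
class Grid:
    """A regular 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; every component >= 1.
    spacing : tuple of float
        Voxel edge length per axis in mm; every component > 0.
    origin : tuple of float
        World coordinate (mm) of the center of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing and origin must each have 3 components")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_coordinates(self, world: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates (..., 3) to fractional voxel indices."""
        pts = np.asarray(world, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-center world coordinates."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (1 mm^3 == 1e-3 mL)."""
        return float(np.prod(self.spacing)) * 1e-3

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """Per-axis (low, high) world coordinates of the outermost voxel centers."""
        return tuple(
            (self.origin[a], self.origin[a] + self.spacing[a] * (self.shape[a] - 1))
            for a in range(3)
        )

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal; RAS-like)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "Grid":
        """Build a grid from an image shape and a diagonal affine."""
        aff = np.asarray(affine, dtype=float)
        offdiag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
        if not np.allclose(offdiag, 0.0, atol=1e-9):
            raise ValueError("only axis-aligned (diagonal) affines are supported")
        spacing = np.diag(aff[:3, :3])
        if np.any(spacing <= 0):
            raise ValueError("affine must have positive diagonal spacing")
        return cls(tuple(shape), tuple(spacing), tuple(aff[:3, 3]))


@dataclass
class ActivityVolume:
    """A 3D scalar field of activity concentration (kBq/mL) on a :class:`Grid`.

    Ground-truth volumes are non-negative by construction; observed volumes
    may contain small negative excursions from noise, which are flagged via
    :attr:`has_negatives` rather than clipped.
    """

    grid: Grid
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def has_negatives(self) -> bool:
        return bool(np.any(self.values < 0))

    @property
    def total_activity_kbq(self) -> float:
        """Sum of voxel values times voxel volume (kBq)."""
        return float(self.values.sum() * self.grid.voxel_volume_ml)

    def copy(self) -> "ActivityVolume":
        return ActivityVolume(self.grid, self.values.copy(), dict(self.meta))


def save_volume(volume: ActivityVolume, path) -> None:
    """Write a volume as NIfTI-1, spacing/origin encoded in the affine."""
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.grid.affine())
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_volume(path) -> ActivityVolume:
    """Read a NIfTI-1 volume written by :func:`save_volume`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = Grid.from_affine(data.shape, img.affine)
    return ActivityVolume(grid, data)
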