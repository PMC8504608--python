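"""Voxel-grid containers shared by every stage.

All quantities live on a regular 3D lattice in patient-space millimetres.
The array index convention is ``values[ix, iy, iz]``; the world coordinate of
voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.  Boolean set algebra
between masks and isodose volumes requires *identical* grids; resampling only
ever happens in :mod:`icksim.transforms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "DoseGrid", "StructureMask"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular dose-calculation lattice.

    Parameters
    ----------
    shape
        Voxel counts per axis (nx, ny, nz).
    spacing
        Voxel size in mm per axis; isotropic 1.25 mm by default, matching the
        finest calculation grid of clinical SRS dose engines.
    origin
        World coordinates (mm) of the *center* of voxel (0, 0, 0).
    isocenter
        World coordinates (mm) of the treatment isocenter, the pivot of every
        setup-error rotation.  Stored as a point; not forced to the origin.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        for name in ("spacing", "origin", "isocenter"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on every axis, got {self.spacing}")
        lo, hi = self.bounds
        if not all(l - 1e-9 <= c <= h + 1e-9 for c, l, h in zip(self.isocenter, lo, hi)):
            raise ValueError(
                f"isocenter {self.isocenter} lies outside the grid bounding box {lo}..{hi}"
            )

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the outermost voxel centers."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate 1D axes of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sparse broadcastable meshgrid of voxel-center world coordinates."""
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    @classmethod
    def centered_cube(
        cls,
        half_extent_mm: float,
        spacing_mm: float = 1.25,
        isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "GridSpec":
        """Cubic grid of voxel centers spanning ±half_extent_mm around the isocenter."""
        n = 2 * int(np.ceil(half_extent_mm / spacing_mm)) + 1
        half = (n - 1) / 2 * spacing_mm
        origin = tuple(c - half for c in isocenter)
        return cls(
            shape=(n, n, n),
            spacing=(spacing_mm,) * 3,
            origin=origin,
            isocenter=tuple(isocenter),
        )


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a :class:`GridSpec` lattice."""

    values: np.ndarray
    grid: GridSpec
    #: fraction of resampled voxels that fell outside the source grid (0 for
    #: freshly synthesized dose; set by :func:`icksim.transforms.apply_setup_error`)
    clip_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose contains non-finite values")
        if self.values.min() < 0:
            raise ValueError("dose contains negative values")

    @property
    def max(self) -> float:
        return float(self.values.max())


@dataclass
class StructureMask:
    """Named binary structure (GTV, PTV, brain, OAR or isodose volume)."""

    name: str
    voxels: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask array shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def volume_cc(self) -> float:
        """Volume as true-voxel count x voxel volume, in cc."""
        return int(self.voxels.sum()) * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def centroid(self) -> np.ndarray:
        """World-coordinate centroid of the true voxels (mm)."""
        if self.is_empty:
            raise ValueError(f"mask '{self.name}' is empty")
        idx = np.argwhere(self.voxels).mean(axis=0)
        return np.asarray(self.grid.origin) + idx * np.asarray(self.grid.spacing)

    def _require_same_grid(self, other: "StructureMask | DoseGrid") -> None:
        if other.grid != self.grid:
            raise ValueError("boolean algebra requires identical grids; resample first")

    def intersect(self, other: "StructureMask", name: str | None = None) -> "StructureMask":
        self._require_same_grid(other)
        return StructureMask(name or f"{self.name}&{other.name}", self.voxels & other.voxels, self.grid)

    def subtract(self, other: "StructureMask", name: str | None = None) -> "StructureMask":
        self._require_same_grid(other)
        return StructureMask(name or f"{self.name}-{other.name}", self.voxels & ~other.voxels, self.grid)

    def union(self, other: "StructureMask", name: str | None = None) -> "StructureMask":
        self._require_same_grid(other)
        return StructureMask(name or f"{self.name}|{other.name}", self.voxels | other.voxels, self.grid)

    def contains(self, other: "StructureMask") -> bool:
        self._require_same_grid(other)
        return bool(np.all(self.voxels[other.voxels]))
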