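"""6-DOF setup-error transforms and rigid dose resampling.

A setup error is a rigid transform about the isocenter: rotations pitch
(y-z plane, about x), roll (x-z plane, about y) and yaw (x-y plane, about z),
plus translations (dx, dy, dz).  Angles are degrees everywhere in the public
interface.  Applying an error moves the *dose cloud* relative to the fixed
anatomy (the planned dose is resampled at transformed voxel centers), which is
equivalent to the patient being set up with that error while the plan's
isocenter stays put.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grid import DoseGrid, StructureMask

__all__ = [
    "Transform6DOF",
    "build_matrix",
    "inverse",
    "apply_setup_error",
    "resample_mask",
    "error_vector",
]

_MAX_ANGLE_DEG = 10.0  # guard; the study range is <= 2 degrees
_AXIS_SEQ = {"pitch": "X", "roll": "Y", "yaw": "Z"}


@dataclass(frozen=True)
class Transform6DOF:
    """Setup-error vector: mm translations and degree rotations about a pivot.

    ``order`` is the intrinsic rotation composition, default pitch->roll->yaw
    ("XYZ").  At study magnitudes (<= 2 degrees) the order dependence of any
    point displacement is below 0.01 mm, but the order is configurable so the
    convention is explicit.
    """

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)
    order: str = "XYZ"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pivot", tuple(float(p) for p in self.pivot))
        for name in ("pitch", "roll", "yaw"):
            if abs(getattr(self, name)) > _MAX_ANGLE_DEG:
                raise ValueError(
                    f"|{name}| = {abs(getattr(self, name))} deg exceeds the "
                    f"{_MAX_ANGLE_DEG} deg guard for small setup errors"
                )
        if sorted(self.order) != ["X", "Y", "Z"]:
            raise ValueError(f"order must be a permutation of 'XYZ', got {self.order!r}")

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw], dtype=float)

    def rotation(self) -> Rotation:
        by_axis = {"X": self.pitch, "Y": self.roll, "Z": self.yaw}
        return Rotation.from_euler(self.order, [by_axis[a] for a in self.order], degrees=True)

    @property
    def is_identity(self) -> bool:
        return not np.any(self.translation) and not np.any(self.angles_deg)

    def to_json(self) -> str:
        return json.dumps(
            {
                "dx": self.dx, "dy": self.dy, "dz": self.dz,
                "pitch": self.pitch, "roll": self.roll, "yaw": self.yaw,
                "pivot": list(self.pivot), "order": self.order,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Transform6DOF":
        d = json.loads(text)
        d["pivot"] = tuple(d.get("pivot", (0.0, 0.0, 0.0)))
        return cls(**d)


def build_matrix(t: Transform6DOF) -> np.ndarray:
    """4x4 homogeneous matrix: rotate about the pivot, then translate.

    Maps a point x to ``R (x - pivot) + pivot + translation``.
    """
    m = np.eye(4)
    rot = t.rotation().as_matrix()
    pivot = np.asarray(t.pivot)
    m[:3, :3] = rot
    m[:3, 3] = pivot - rot @ pivot + t.translation
    return m


def inverse(t: Transform6DOF) -> Transform6DOF:
    """Exact group inverse with the same pivot and rotation order."""
    r_inv = t.rotation().inv()
    by_axis = dict(zip(t.order, r_inv.as_euler(t.order, degrees=True)))
    t_inv = -(r_inv.as_matrix() @ t.translation)
    return Transform6DOF(
        dx=t_inv[0], dy=t_inv[1], dz=t_inv[2],
        pitch=by_axis["X"], roll=by_axis["Y"], yaw=by_axis["Z"],
        pivot=t.pivot, order=t.order,
    )


def transform_points(t: Transform6DOF, points: np.ndarray) -> np.ndarray:
    """Apply the transform to world points of shape (..., 3)."""
    pts = np.asarray(points, dtype=float)
    m = build_matrix(t)
    return pts @ m[:3, :3].T + m[:3, 3]


def apply_setup_error(
    dose: DoseGrid,
    t: Transform6DOF,
    stat_mask: StructureMask | None = None,
    warn_clip_fraction: float = 0.01,
) -> DoseGrid:
    """Resample the planned dose under a setup error (structures stay fixed).

    The output dose at anatomy point x is the planned dose at ``T(x)``,
    evaluated by trilinear interpolation; samples falling outside the grid are
    filled with 0 Gy and counted in the returned grid's ``clip_fraction``
    (computed over ``stat_mask`` if given, typically the brain).  A clip
    fraction above ``warn_clip_fraction`` raises a warning rather than
    silently extrapolating.
    """
    if t.is_identity:
        return DoseGrid(dose.values.copy(), dose.grid)
    grid = dose.grid
    x, y, z = grid.voxel_centers()
    m = build_matrix(t)
    rot, off = m[:3, :3], m[:3, 3]
    # mapped world coords, then fractional indices into the source grid
    coords = np.empty((3,) + grid.shape)
    for a in range(3):
        coords[a] = (
            rot[a, 0] * x + rot[a, 1] * y + rot[a, 2] * z + off[a] - grid.origin[a]
        ) / grid.spacing[a]
    inside = np.ones(grid.shape, dtype=bool)
    for a in range(3):
        inside &= (coords[a] >= 0) & (coords[a] <= grid.shape[a] - 1)
    out = ndimage.map_coordinates(dose.values, coords, order=1, mode="constant", cval=0.0)
    np.maximum(out, 0.0, out=out)  # clamp interpolation round-off
    if stat_mask is not None:
        sel = stat_mask.voxels
        clip = float((~inside & sel).sum()) / max(int(sel.sum()), 1)
    else:
        clip = float((~inside).sum()) / inside.size
    if clip > warn_clip_fraction:
        warnings.warn(
            f"setup error clipped {100 * clip:.2f}% of voxels outside the dose grid",
            stacklevel=2,
        )
    return DoseGrid(out, grid, clip_fraction=clip)


def resample_mask(mask: StructureMask, t: Transform6DOF) -> StructureMask:
    """Move a structure instead of the dose (nearest-neighbour resample).

    ``resample_mask(m, inverse(t))`` against a fixed dose is the symmetric
    counterpart of :func:`apply_setup_error`; provided for cross-checks.
    """
    grid = mask.grid
    x, y, z = grid.voxel_centers()
    m = build_matrix(t)
    rot, off = m[:3, :3], m[:3, 3]
    coords = np.empty((3,) + grid.shape)
    for a in range(3):
        coords[a] = (
            rot[a, 0] * x + rot[a, 1] * y + rot[a, 2] * z + off[a] - grid.origin[a]
        ) / grid.spacing[a]
    vox = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), coords, order=0, mode="constant", cval=0
    )
    return StructureMask(mask.name, vox.astype(bool), grid)


def error_vector(
    magnitude_mm: float,
    magnitude_deg: float,
    signs="positive",
    seed: int | None = None,
    pivot=(0.0, 0.0, 0.0),
    convention: str = "norm",
    order: str = "XYZ",
) -> Transform6DOF:
    """Build the coupled setup-error transform for one sweep point.

    ``signs`` is a sequence of six +/-1 (dx, dy, dz, pitch, roll, yaw),
    ``"positive"`` for all +, or ``"random"`` (reproducible from ``seed``).

    ``convention`` fixes how a scalar magnitude maps onto six axes:

    * ``"norm"`` (default): each component is ``sign * magnitude / sqrt(3)``,
      so the translation *vector* has norm ``magnitude_mm`` and the three
      small rotations compose to a total rotation of ``magnitude_deg`` (to
      second order).  A nominal "2 mm" error then displaces every point by
      2 mm plus the rotation lever-arm effect, which is what the calibrated
      covering-dose decline of 3.3 Gy per mm of error magnitude assumes.
    * ``"component"``: each component is ``sign * magnitude`` (literally
      +/-magnitude in all six directions), giving a sqrt(3)-times-larger
      geometric displacement.
    """
    if magnitude_mm < 0 or magnitude_deg < 0:
        raise ValueError("magnitudes must be >= 0")
    if convention not in ("norm", "component"):
        raise ValueError(f"convention must be 'norm' or 'component', got {convention!r}")
    if isinstance(signs, str):
        if signs == "positive":
            sgn = np.ones(6)
        elif signs == "random":
            if seed is None:
                raise ValueError("signs='random' requires a seed")
            rng = np.random.default_rng(seed)
            sgn = rng.choice([-1.0, 1.0], size=6)
        else:
            raise ValueError(f"signs must be 'positive', 'random' or six signs, got {signs!r}")
    else:
        sgn = np.asarray(signs, dtype=float)
        if sgn.shape != (6,) or not np.all(np.abs(sgn) == 1):
            raise ValueError("signs must be six values of +/-1")
    scale = 1.0 / math.sqrt(3.0) if convention == "norm" else 1.0
    mm = magnitude_mm * scale
    deg = magnitude_deg * scale
    return Transform6DOF(
        dx=sgn[0] * mm, dy=sgn[1] * mm, dz=sgn[2] * mm,
        pitch=sgn[3] * deg, roll=sgn[4] * deg, yaw=sgn[5] * deg,
        pivot=tuple(pivot), order=order,
    )
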