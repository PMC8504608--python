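"""Synthetic multi-lesion brain phantoms with SRS-like dose distributions.

A phantom stands in for a treatment-planning-system export: a 3D dose grid plus
binary structure masks (GTVs, PTVs, whole brain, optional OARs) on a common
lattice.  The geometry sampler emulates a nine-patient single-isocenter
multitarget SRS cohort (2-16 lesions per patient, GTV 0.02-11.5 cc, lesion
centers 2.2-8.9 cm from the isocenter, 1 mm GTV-to-PTV margin, 20 Gy
prescribed to a 70-80% isodose line on a 1.25 mm grid).

The dose model is an analytic radial kernel per target:

* a plateau at ``D_max = prescription / idl_fraction`` inside the GTV,
* a linear descent to ``boundary_min_dose`` (default 19.2 Gy) at the PTV
  surface, and
* a linear peripheral fall-off of ``falloff_gradient`` (default 3.3 Gy/mm)
  beyond the PTV, clipped at zero.

The two calibration defaults make the phantom's minimum covering dose decline
by about 3.3 Gy per millimetre of setup error from a 19.2 Gy baseline, the
behaviour of steep-gradient single-isocenter SRS plans.  Per-target kernels
are summed by default (dose is additive); a voxelwise-max combination mode is
available for sensitivity checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import DoseGrid, GridSpec, StructureMask

__all__ = [
    "TargetSpec",
    "PatientPhantom",
    "PlacementError",
    "REFERENCE_COHORT",
    "sample_cohort_geometry",
    "voxelize_sphere",
    "synthesize_dose",
    "build_phantom",
    "generate_cohort",
]

#: Per-patient characteristics of the reference single-isocenter multitarget
#: SRS cohort used to parameterize the generator: lesion count, per-patient
#: average 3D distance to isocenter (cm), per-lesion mean GTV and PTV volume
#: (cc), and adjacent organs at risk.
REFERENCE_COHORT = pd.DataFrame(
    {
        "patient": ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"],
        "n_lesions": [2, 3, 4, 5, 6, 7, 8, 10, 16],
        "avg_distance_cm": [2.2, 5.7, 6.5, 8.9, 5.4, 5.0, 4.3, 5.5, 5.4],
        "mean_gtv_cc": [2.2, 0.43, 3.90, 3.30, 1.30, 0.75, 0.51, 0.39, 0.43],
        "mean_ptv_cc": [3.70, 0.93, 6.50, 4.90, 2.10, 1.40, 1.00, 0.86, 0.83],
        "adjacent_oar": [
            "Hippocampi",
            "Hippocampi",
            "Hippocampi, Optic apparatus",
            "Hippocampi",
            "Hippocampi",
            "Brainstem, Hippocampi",
            "Brainstem, Hippocampi",
            "Hippocampi",
            "Optic apparatus, Hippocampi, Brainstem",
        ],
    }
)


class PlacementError(RuntimeError):
    """Rejection sampling could not satisfy a placement constraint."""


@dataclass(frozen=True)
class TargetSpec:
    """One spherical lesion and its prescription.

    ``boundary_min_dose`` is the dose on the PTV surface and
    ``falloff_gradient`` the peripheral dose gradient (Gy/mm) beyond it; both
    are calibration knobs of the analytic kernel.
    """

    center: tuple[float, float, float]
    gtv_radius: float
    ptv_margin: float = 1.0
    prescription: float = 20.0
    idl_fraction: float = 0.75
    boundary_min_dose: float = 19.2
    falloff_gradient: float = 3.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.gtv_radius <= 0:
            raise ValueError("gtv_radius must be > 0")
        if self.ptv_margin < 0:
            raise ValueError("ptv_margin must be >= 0")
        if not 0 < self.idl_fraction <= 1:
            raise ValueError("idl_fraction must be in (0, 1]")
        if not 0 < self.boundary_min_dose <= self.prescription:
            raise ValueError("need 0 < boundary_min_dose <= prescription")
        if self.falloff_gradient <= 0:
            raise ValueError("falloff_gradient must be > 0")

    @property
    def ptv_radius(self) -> float:
        return self.gtv_radius + self.ptv_margin

    @property
    def d_max(self) -> float:
        """Plateau dose: prescription normalized to the isodose-line fraction."""
        return self.prescription / self.idl_fraction

    def kernel(self, r: np.ndarray) -> np.ndarray:
        """Dose (Gy) at radial distance ``r`` (mm) from the target center."""
        r = np.asarray(r, dtype=float)
        d = np.empty_like(r)
        rg, rp = self.gtv_radius, self.ptv_radius
        plateau = r <= rg
        margin = (r > rg) & (r <= rp)
        outside = r > rp
        d[plateau] = self.d_max
        if self.ptv_margin > 0:
            frac = (r[margin] - rg) / self.ptv_margin
            d[margin] = self.d_max + (self.boundary_min_dose - self.d_max) * frac
        else:
            d[margin] = self.d_max
        d[outside] = np.maximum(
            0.0, self.boundary_min_dose - self.falloff_gradient * (r[outside] - rp)
        )
        return d


def voxelize_sphere(grid: GridSpec, center, radius: float, name: str = "sphere") -> StructureMask:
    """Mask of voxels whose centers lie within ``radius`` mm of ``center``.

    Membership is voxel-center-in-sphere (closed ball, no partial volume),
    matching TPS contour-rasterization behaviour at study resolution.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    cx, cy, cz = (float(c) for c in center)
    x, y, z = grid.voxel_centers()
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    mask = StructureMask(name, r2 <= radius**2, grid)
    if mask.is_empty:
        warnings.warn(
            f"sphere '{name}' (center {center}, r={radius} mm) contains no voxel centers",
            stacklevel=2,
        )
    return mask


def synthesize_dose(
    grid: GridSpec, targets: list[TargetSpec], combine: str = "sum"
) -> DoseGrid:
    """Analytic SRS-like dose: per-target radial kernels combined voxelwise.

    ``combine`` is ``"sum"`` (dose is additive; the default) or ``"max"``
    (sensitivity-check mode that ignores cross-target tails).
    """
    if not targets:
        raise ValueError("synthesize_dose requires at least one target")
    if combine not in ("sum", "max"):
        raise ValueError(f"combine must be 'sum' or 'max', got {combine!r}")
    x, y, z = grid.voxel_centers()
    total = np.zeros(grid.shape, dtype=float)
    for t in targets:
        r = np.sqrt((x - t.center[0]) ** 2 + (y - t.center[1]) ** 2 + (z - t.center[2]) ** 2)
        k = t.kernel(r)
        if combine == "sum":
            total += k
        else:
            np.maximum(total, k, out=total)
    return DoseGrid(total, grid)


def _radius_from_volume_cc(volume_cc: float) -> float:
    """Radius (mm) of a sphere of the given volume (cc)."""
    return (3.0 * volume_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def sample_cohort_geometry(
    n_lesions: int,
    seed: int,
    gtv_cc_range: tuple[float, float] = (0.02, 11.5),
    distance_mm_range: tuple[float, float] = (22.0, 89.0),
    isocenter=(0.0, 0.0, 0.0),
    brain_radius_mm: float = 100.0,
    spacing_mm: float = 1.25,
    max_attempts: int = 10_000,
    target_kwargs: dict | None = None,
) -> list[TargetSpec]:
    """Rejection-sample lesion geometry with the study cohort's statistics.

    GTV volumes are drawn log-uniformly over ``gtv_cc_range`` (brain-metastasis
    volumes are right-skewed, so a log-uniform draw keeps small lesions
    frequent); centers are drawn isotropically at a distance uniform over
    ``distance_mm_range`` from the isocenter.  Placements are rejected until
    all PTVs are pairwise disjoint (center separation greater than the sum of
    PTV radii plus two voxels) and every PTV fits inside the brain sphere.
    Identical seeds give identical cohorts.
    """
    if not 1 <= n_lesions <= 16:
        raise ValueError("n_lesions must be between 1 and 16")
    lo_v, hi_v = gtv_cc_range
    lo_d, hi_d = distance_mm_range
    if lo_v <= 0 or hi_v < lo_v or lo_d < 0 or hi_d < lo_d:
        raise ValueError("invalid cohort ranges")
    rng = np.random.default_rng(seed)
    iso = np.asarray(isocenter, dtype=float)
    kwargs = dict(target_kwargs or {})
    margin = kwargs.get("ptv_margin", 1.0)

    placed: list[TargetSpec] = []
    attempts = 0
    while len(placed) < n_lesions:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place lesion {len(placed) + 1}/{n_lesions} after "
                f"{max_attempts} attempts (violated constraint: pairwise PTV "
                f"separation or brain containment within {brain_radius_mm} mm)"
            )
        attempts += 1
        vol = math.exp(rng.uniform(math.log(lo_v), math.log(hi_v)))
        gtv_r = _radius_from_volume_cc(vol)
        dist = rng.uniform(lo_d, hi_d)
        if dist == 0:
            direction = np.zeros(3)
        else:
            direction = rng.standard_normal(3)
            norm = np.linalg.norm(direction)
            if norm == 0:  # pragma: no cover - measure-zero draw
                continue
            direction /= norm
        center = iso + dist * direction
        ptv_r = gtv_r + margin
        if dist + ptv_r > brain_radius_mm - spacing_mm:
            continue
        ok = True
        for other in placed:
            sep = np.linalg.norm(center - np.asarray(other.center))
            if sep <= ptv_r + other.ptv_radius + 2 * spacing_mm:
                ok = False
                break
        if ok:
            placed.append(TargetSpec(center=tuple(center), gtv_radius=gtv_r, **kwargs))
    return placed


@dataclass
class PatientPhantom:
    """One synthetic patient: grid, targets, dose and structure masks."""

    grid: GridSpec
    targets: list[TargetSpec]
    dose: DoseGrid
    brain_mask: StructureMask
    gtv_masks: list[StructureMask]
    ptv_masks: list[StructureMask]
    oar_masks: dict[str, StructureMask] = field(default_factory=dict)
    patient_id: str = "phantom"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            # imported plans carry masks but no analytic target specs; the
            # per-target invariants below only apply to generated phantoms
            return
        n = len(self.targets)
        if len(self.gtv_masks) != n or len(self.ptv_masks) != n:
            raise ValueError("per-target mask count must equal target count")
        for gtv, ptv in zip(self.gtv_masks, self.ptv_masks):
            if not ptv.contains(gtv):
                raise ValueError(f"GTV mask '{gtv.name}' not contained in its PTV")
            if not self.brain_mask.contains(ptv):
                raise ValueError(f"PTV mask '{ptv.name}' not contained in the brain mask")

    @property
    def isocenter(self) -> np.ndarray:
        return np.asarray(self.grid.isocenter)


def build_phantom(
    targets: list[TargetSpec],
    spacing_mm: float = 1.25,
    brain_radius_mm: float = 100.0,
    grid: GridSpec | None = None,
    isocenter=(0.0, 0.0, 0.0),
    oar_specs: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] | None = None,
    combine: str = "sum",
    patient_id: str = "phantom",
    seed: int | None = None,
) -> PatientPhantom:
    """Assemble a :class:`PatientPhantom` from target specs.

    If ``grid`` is omitted, a cubic grid centered on the isocenter and padded
    one voxel beyond the brain sphere is built.  ``oar_specs`` maps a name to
    an ellipsoid ``(center_mm, semi_axes_mm)``.
    """
    if not targets:
        raise ValueError("build_phantom requires at least one target")
    if grid is None:
        grid = GridSpec.centered_cube(
            brain_radius_mm + spacing_mm, spacing_mm=spacing_mm, isocenter=tuple(isocenter)
        )
    brain = voxelize_sphere(grid, grid.isocenter, brain_radius_mm, name="brain")
    gtvs, ptvs = [], []
    for i, t in enumerate(targets):
        gtvs.append(voxelize_sphere(grid, t.center, t.gtv_radius, name=f"GTV_{i + 1}"))
        ptvs.append(voxelize_sphere(grid, t.center, t.ptv_radius, name=f"PTV_{i + 1}"))
    oars: dict[str, StructureMask] = {}
    for name, (center, semi) in (oar_specs or {}).items():
        x, y, z = grid.voxel_centers()
        q = (
            ((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2
        )
        oars[name] = StructureMask(name, q <= 1.0, grid)
    dose = synthesize_dose(grid, targets, combine=combine)
    return PatientPhantom(
        grid=grid,
        targets=list(targets),
        dose=dose,
        brain_mask=brain,
        gtv_masks=gtvs,
        ptv_masks=ptvs,
        oar_masks=oars,
        patient_id=patient_id,
        seed=seed,
    )


def generate_cohort(
    seed: int,
    lesion_counts: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 10, 16),
    spacing_mm: float = 1.25,
    brain_radius_mm: float = 100.0,
    gtv_cc_range: tuple[float, float] = (0.02, 11.5),
    distance_mm_range: tuple[float, float] = (22.0, 89.0),
    target_kwargs: dict | None = None,
) -> list[PatientPhantom]:
    """Generate one phantom per entry of ``lesion_counts`` (study cohort by default).

    Per-patient seeds are derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    patient_seeds = rng.integers(0, 2**31 - 1, size=len(lesion_counts))
    cohort = []
    for i, (n, s) in enumerate(zip(lesion_counts, patient_seeds)):
        targets = sample_cohort_geometry(
            n_lesions=n,
            seed=int(s),
            gtv_cc_range=gtv_cc_range,
            distance_mm_range=distance_mm_range,
            brain_radius_mm=brain_radius_mm,
            spacing_mm=spacing_mm,
            target_kwargs=target_kwargs,
        )
        cohort.append(
            build_phantom(
                targets,
                spacing_mm=spacing_mm,
                brain_radius_mm=brain_radius_mm,
                patient_id=f"P{i + 1:02d}",
                seed=int(s),
            )
        )
    return cohort
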