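"""Phantom serialization and run configuration.

A phantom is stored as one directory per patient:

* ``manifest.json`` — grid spec, target specs, patient id, seed and the list
  of stored structure names;
* ``arrays.npz`` — compressed numpy archive holding ``dose`` (float64 Gy) and
  one boolean array per structure (``brain``, ``gtv_1`` ..., ``ptv_1`` ...,
  plus any OARs), all on the manifest's grid.

Configs are YAML or JSON mappings; keys mirror the generator and sweep
signatures (``n_patients``/``lesion_counts``, ``gtv_cc_range``,
``distance_cm_range``, ``spacing_mm``, ``prescription_gy``, ``idl_fraction``,
``boundary_min_dose_gy``, ``falloff_gradient_gy_per_mm``, ``seed``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .grid import DoseGrid, GridSpec, StructureMask
from .phantom import PatientPhantom, TargetSpec, generate_cohort

__all__ = ["save_phantom", "load_phantom", "load_config", "cohort_from_config"]


def save_phantom(phantom: PatientPhantom, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "patient_id": phantom.patient_id,
        "seed": phantom.seed,
        "grid": dataclasses.asdict(phantom.grid),
        "targets": [dataclasses.asdict(t) for t in phantom.targets],
        "oar_names": sorted(phantom.oar_masks),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    arrays = {"dose": phantom.dose.values, "brain": phantom.brain_mask.voxels}
    for i, (g, p) in enumerate(zip(phantom.gtv_masks, phantom.ptv_masks), start=1):
        arrays[f"gtv_{i}"] = g.voxels
        arrays[f"ptv_{i}"] = p.voxels
    for name, m in phantom.oar_masks.items():
        arrays[f"oar_{name}"] = m.voxels
    np.savez_compressed(outdir / "arrays.npz", **arrays)
    return outdir


def load_phantom(indir) -> PatientPhantom:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    g = manifest["grid"]
    grid = GridSpec(
        shape=tuple(g["shape"]), spacing=tuple(g["spacing"]),
        origin=tuple(g["origin"]), isocenter=tuple(g["isocenter"]),
    )
    targets = [
        TargetSpec(**{**t, "center": tuple(t["center"])}) for t in manifest["targets"]
    ]
    with np.load(indir / "arrays.npz") as npz:
        dose = DoseGrid(npz["dose"], grid)
        brain = StructureMask("brain", npz["brain"], grid)
        gtvs = [
            StructureMask(f"GTV_{i + 1}", npz[f"gtv_{i + 1}"], grid)
            for i in range(len(targets))
        ]
        ptvs = [
            StructureMask(f"PTV_{i + 1}", npz[f"ptv_{i + 1}"], grid)
            for i in range(len(targets))
        ]
        oars = {
            name: StructureMask(name, npz[f"oar_{name}"], grid)
            for name in manifest["oar_names"]
        }
    return PatientPhantom(
        grid=grid, targets=targets, dose=dose, brain_mask=brain,
        gtv_masks=gtvs, ptv_masks=ptvs, oar_masks=oars,
        patient_id=manifest["patient_id"], seed=manifest["seed"],
    )


def load_config(path) -> dict:
    """Load a YAML or JSON config mapping."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def cohort_from_config(cfg: dict) -> list[PatientPhantom]:
    """Build a cohort from a generator config mapping."""
    target_kwargs = {}
    for src, dst in (
        ("prescription_gy", "prescription"),
        ("idl_fraction", "idl_fraction"),
        ("boundary_min_dose_gy", "boundary_min_dose"),
        ("falloff_gradient_gy_per_mm", "falloff_gradient"),
        ("ptv_margin_mm", "ptv_margin"),
    ):
        if src in cfg:
            target_kwargs[dst] = cfg[src]
    lesion_counts = cfg.get("lesion_counts")
    if lesion_counts is None and "n_patients" in cfg:
        lesion_counts = (2, 3, 4, 5, 6, 7, 8, 10, 16)[: int(cfg["n_patients"])]
    dist_cm = cfg.get("distance_cm_range", (2.2, 8.9))
    return generate_cohort(
        seed=int(cfg.get("seed", 0)),
        lesion_counts=tuple(lesion_counts) if lesion_counts else (2, 3, 4, 5, 6, 7, 8, 10, 16),
        spacing_mm=float(cfg.get("spacing_mm", 1.25)),
        brain_radius_mm=float(cfg.get("brain_radius_mm", 100.0)),
        gtv_cc_range=tuple(cfg.get("gtv_cc_range", (0.02, 11.5))),
        distance_mm_range=(10.0 * dist_cm[0], 10.0 * dist_cm[1]),
        target_kwargs=target_kwargs or None,
    )
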