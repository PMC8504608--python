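# icksim

Setup-error propagation and indirect-cell-kill dose analysis for
single-isocenter, multitarget stereotactic radiosurgery (SIMT SRS).

When several brain metastases are treated through one isocenter, a residual
rotational setup error displaces each lesion by a chord `2R·sin(θ/2)` that
grows with its distance `R` from the isocenter, and translational errors shift
the whole dose cloud. `icksim` simulates these 6-DOF errors (Δx, Δy, Δz in mm;
pitch/roll/yaw in degrees about the isocenter), resamples the planned dose,
and quantifies the radiobiological consequences per target:

* **DCK** — the fraction of the PTV inside the 20 Gy prescription isodose
  volume, attributed to direct cell kill;
* **ICK** — the fraction inside the 15 Gy isodose volume but outside the
  20 Gy one, attributed to indirect cell kill (devascularization and
  immune-mediated death at single doses ≥ 15 Gy);
* the **minimum covering dose** — the highest isodose level that still fully
  contains the PTV — and the error magnitude at which its mean crosses the
  15 Gy ICK threshold;
* normal-brain radionecrosis risk through a logistic NTCP model of
  whole-brain V14Gy,

  `NTCP = 1 / (1 + (Vx50 / Vx)^(4·γ50))`, with Vx50 = 45.8 cc, γ50 = 0.88.

It is aimed at medical physicists and researchers studying setup-margin
tolerances for SIMT VMAT radiosurgery. Because clinical dose grids are rarely
shareable, the package ships a synthetic-phantom generator that emulates a
nine-patient cohort (2–16 lesions, GTV 0.02–11.5 cc, lesions 2.2–8.9 cm from
the isocenter, 20 Gy to a 70–80% isodose line, 1.25 mm grid) with an analytic
per-lesion dose kernel calibrated so the covering dose starts at 19.2 Gy and
declines ≈ 3.3 Gy per millimetre of setup error. DICOM-RT Dose/Structure-Set
import lets the same pipeline run on real plan exports.

## Worked example

```python
from icksim import (TargetSpec, build_phantom, error_vector,
                    apply_setup_error, dck_ick_partition, min_covering_dose)

phantom = build_phantom([TargetSpec(center=(0, 0, 0), gtv_radius=8.0)],
                        brain_radius_mm=30.0)
ptv = phantom.ptv_masks[0]
for mm in (0.0, 0.5, 1.0, 2.0):
    t = error_vector(mm, mm, pivot=phantom.grid.isocenter)
    dose = apply_setup_error(phantom.dose, t, stat_mask=phantom.brain_mask)
    part = dck_ick_partition(dose, ptv)
    print(f"{mm:3.1f} mm/{mm:3.1f} deg: covering dose {min_covering_dose(dose, ptv):5.1f} Gy "
          f"| DCK {part['dck_fraction']:5.1f}% ICK {part['ick_fraction']:5.1f}%")
```

prints (covering dose in Gy, DCK/ICK in % of PTV volume):

```
0.0 mm/0.0 deg: covering dose  19.7 Gy | DCK  96.9% ICK   3.1%
0.5 mm/0.5 deg: covering dose  18.0 Gy | DCK  95.3% ICK   4.7%
1.0 mm/1.0 deg: covering dose  16.3 Gy | DCK  92.0% ICK   8.0%
2.0 mm/2.0 deg: covering dose  13.2 Gy | DCK  82.1% ICK  15.5%
```

The covering dose falls by ≈ 3.3 Gy per millimetre of error: past ~1.3 mm/1.3°
part of the target drops below the 15 Gy ICK threshold, i.e. setup errors must
stay below that magnitude to preserve the indirect-cell-kill contribution.
The small offsets above the ideal 19.2/17.55/15.9/12.6 Gy line are lattice
sampling effects of the 1.25 mm grid (the outermost PTV voxel center sits
slightly inside the PTV surface).

More narrative scripts live in `examples/` (phantom construction, error
sweeps, threshold + NTCP, DICOM round trip). A thin CLI wraps the pipeline:

```bash
icksim generate --config cohort.yaml --out cohort/
icksim sweep --cohort cohort/ --config sweep.yaml --out results/
icksim analyze --rtdose dose.dcm --rtstruct ss.dcm --out results/
```

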