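# Methods

## Problem and model

Single-isocenter multitarget (SIMT) radiosurgery treats every brain
metastasis through one isocenter, so a residual rigid setup error — three
translations (mm) and three rotations (pitch in the y–z plane, roll in x–z,
yaw in x–y, degrees, about the isocenter) — displaces each lesion relative to
its planned dose. A rotation by θ moves a lesion at distance R from the
isocenter along a chord `2R·sin(θ/2)`, so distal lesions lose coverage
fastest. The package partitions each planning target volume (PTV) into a
direct-cell-kill region (dose ≥ prescription, 20 Gy) and an
indirect-cell-kill region (15–20 Gy; single doses ≥ 15 Gy are associated
with tumor devascularization and immune-mediated death), tracks the minimum
covering dose of each PTV under increasing error magnitudes, and evaluates
normal-brain radionecrosis risk as a logistic function of whole-brain V14Gy.

## Synthetic phantom

Clinical SIMT plans are rarely shareable, so every pipeline stage runs on a
synthetic patient: a regular lattice (default isotropic 1.25 mm, the finest
grid of clinical dose engines) holding an analytic dose plus voxel masks.

Geometry is sampled to match a reference nine-patient SIMT cohort whose
per-patient characteristics (2–16 lesions, 61 total; per-lesion GTV means
0.39–3.9 cc; per-patient average distances to isocenter 2.2–8.9 cm) are
embedded as `REFERENCE_COHORT`. Defaults: GTV volumes log-uniform on
0.02–11.5 cc (metastasis volumes are right-skewed; a log-uniform draw keeps
small lesions frequent while covering the full range), isotropic directions,
distance uniform on 22–89 mm, PTV = GTV + 1 mm margin, rejection sampling
until PTVs are pairwise separated by at least two voxels and contained in
the brain sphere (capped at 10 000 attempts, then a `PlacementError` naming
the constraint). The brain is a sphere of default radius 100 mm — larger
than anatomical (~1400 cc) so that lesions out to 89 mm plus their PTVs fit
inside it; brain-volume-dependent quantities (V14Gy, NTCP) are therefore
phantom-scale quantities, compared only between perturbed and unperturbed
states of the same phantom.

Each lesion contributes a radial dose kernel: a plateau at
`D_max = prescription / idl_fraction` (default 20 Gy / 0.75, emulating
prescription to a 70–80% isodose line) inside the GTV, a linear descent to
`boundary_min_dose` = 19.2 Gy at the PTV surface, then a linear peripheral
fall-off of `falloff_gradient` = 3.3 Gy/mm clipped at zero. The two numbers
are a deliberate calibration: they make the unperturbed covering dose
≈ 19.2 Gy and make it decline ≈ 3.3 Gy per millimetre of error magnitude,
the behaviour of steep-gradient SIMT plans; both are per-target parameters.
Kernels are summed voxelwise (dose is additive; at cohort separations the
cross-target tail is negligible); a voxelwise-max mode exists for
sensitivity checks. Masks are voxel-center-in-sphere with volume = count ×
voxel volume — exactly testable and matching TPS rasterization at this
resolution.

What the phantom does *not* emulate: arc geometry, MLC modulation,
heterogeneity, anisotropic or non-monotone dose fall-off, contour
irregularity, and the patient-to-patient variability behind the reference
cohort's ± SDs. Passing tests therefore demonstrate the correctness of the
error-propagation and dose-accounting machinery under calibrated conditions,
not the dosimetry of any real plan.

## Error application and resampling

A setup error is applied by moving the *dose cloud* against fixed anatomy:
the perturbed dose at anatomy point x is the planned dose at `T(x)`, where
`T` rotates about the isocenter (intrinsic pitch→roll→yaw; at ≤ 2° any
composition order changes point displacements by < 0.01 mm, but the order is
configurable) and then translates. Interpolation is trilinear, matching the
C⁰ nature of TPS dose grids; samples outside the grid become 0 Gy and are
counted in a clipping fraction (warning above 1% of the brain by default) —
failing loudly rather than extrapolating.

A scalar "x mm / x°" sweep magnitude maps onto six axes by the **norm
convention**: each component is `±x/√3`, so the translation vector has norm
x mm and the three small rotations compose to ≈ x° total. This keeps the
geometric displacement of a pure translation equal to the nominal magnitude,
which is what the 3.3 Gy/mm covering-dose calibration presumes; the literal
component-wise reading (±x on all six axes, a √3-larger displacement) is
available as `convention="component"`. Sign patterns are all-positive by
default (flagged as an assumption in reports) or drawn reproducibly from the
run seed.

## Metrics

Isodose volumes use the closed threshold dose ≥ level, which makes the
partition algebra exact: `dck + ick = v15` holds identically because the
fractions come from disjoint voxel counts on one lattice (Boolean operations
refuse mismatched grids; resampling only ever happens in the transform
stage). The minimum covering dose retains the iterative Boolean formulation
— the largest level `k·step` (step 0.1 Gy) whose isodose volume contains the
PTV — implemented as bisection over the monotone predicate and tested
against the floor-to-step voxel-minimum oracle on hundreds of random
instances. "Fully cover" means 100% of PTV voxel centers by default; a
`covered_fraction` knob (e.g. 0.999) exists because a single cold voxel can
dominate sub-0.1 cc targets at 1.25 mm resolution. DVHs are cumulative with
0.1 Gy bins; Vx is the absolute volume (cc) receiving ≥ x Gy.

The NTCP model is `1/(1 + (Vx50/Vx)^(4·γ50))` with literature parameters
Vx50 = 45.8 cc and γ50 = 0.88 for brain-metastasis radionecrosis, applied to
whole-brain V14Gy with GTVs included (pass a different mask for a
GTV-excluded convention). The exponent `4·γ50` is used exactly as published;
the model is strictly increasing, 0.5 at Vx50, and log-symmetric
(`p(kV₅₀) + p(V₅₀/k) = 1`), all of which are asserted as identities. Both
absolute and relative NTCP differences are reported.

## Pipeline and aggregation

The sweep couples magnitudes (default 0, 0.5, 1, 2 mm with the same degrees)
and aggregates target-weighted: every lesion counts once in per-magnitude
means and sample SDs (patient-weighted aggregation is a config option). The
headline threshold is the piecewise-linear crossing of the mean covering-dose
curve with the 15 Gy ICK level, reported unrounded and at one decimal, with
no extrapolation outside the swept range; applied to the reference study's
printed curve (19.2, 17.8, 15.9, 12.6 Gy) it gives 1.27 → 1.3 mm/1.3°.
Cohort tables are aggregated by summing lesion counts, averaging per-patient
mean distances across patients, and lesion-count-weighting per-lesion volume
means. Reports write byte-reproducible CSV/JSON (fixed seed ⇒ identical
bytes) and three figures; calibrated quantities are labelled as such.

## Numerical choices and tolerances

* Lattice sampling bias: the outermost PTV voxel center sits up to ~0.35 mm
  inside the spherical PTV surface on a 1.25 mm grid, so measured covering
  doses exceed the ideal `19.2 − 3.3·s` line by up to ≈ 1.2 Gy (and the
  baseline sits near 19.7 Gy on the steep intra-margin gradient). Tests and
  comparisons use this half-voxel × gradient slack plus the 0.1 Gy search
  step.
* Trilinear resampling across a slope discontinuity Δg errs by ≤ Δg·h/4; the
  kernel's largest kink is ≈ 10.8 Gy/mm at the PTV surface, giving a
  round-trip (two resamples) worst-case bound of ≈ 6.7 Gy confined to a thin
  shell around the kinks, with near-zero error in the bulk. The round-trip
  property test asserts exactly this analytic bound.
* Opposite-sign error vectors mirror exactly for translations and to second
  order (≤ R·θ²) for composed Euler rotations.
* Degenerate inputs fail explicitly: empty PTV/OAR masks, non-monotone
  threshold curves, levels outside the observed dose range, zero DICOM dose
  scaling, mismatched frames of reference.
* DICOM export quantizes dose to uint32 (quantum = max dose / (2³² − 1));
  contours are extracted at the mask's 0.5 iso-level per slice and
  re-voxelized by point-in-polygon, which reproduces masks to Dice ≈ 1 at
  study resolution. Interior holes are not subtracted on import.

## Problem sizes

Default phantoms use the study's 1.25 mm grid (≈ 163³ voxels for the full
100 mm brain). The test suite and examples use single-lesion phantoms at
1.25 mm on compact 30 mm grids and small multi-lesion cohorts at 2.5 mm —
sizes chosen so the full property suite (including 200-instance oracle
equivalence and end-to-end sweeps) documents the same physics at desk scale.

## Known limitations

Only rigid, time-invariant setup errors are modelled — no deformation,
intrafraction drift, or delineation uncertainty. The linear fall-off is a
surrogate for real plan gradients; whether a 70% vs 80% isodose-line
normalization shifts the threshold is exposed as a sensitivity experiment
(`idl_fraction`), not a claim. The reference cohort's inter-patient SDs
cannot be reproduced by calibration and are not asserted anywhere. The NTCP
parameters are literature constants; no fitting to outcome data is
performed, and no TCP/linear-quadratic modelling is attempted.
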