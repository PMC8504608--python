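"""Propagate a 6-DOF setup error and partition a target into DCK vs ICK.

A single 8 mm GTV sphere is perturbed by a coupled 1 mm / 1 degree setup
error about the isocenter; the dose is resampled, and the PTV is split into
the fraction receiving at least the 20 Gy prescription (direct cell kill) and
the 15-20 Gy fraction (indirect cell kill via devascularization).
"""

from icksim import (
    TargetSpec,
    apply_setup_error,
    build_phantom,
    dck_ick_partition,
    error_vector,
    min_covering_dose,
)

phantom = build_phantom([TargetSpec(center=(0, 0, 0), gtv_radius=8.0)], brain_radius_mm=30.0)
ptv = phantom.ptv_masks[0]

for mm, deg in [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0), (2.0, 2.0)]:
    t = error_vector(mm, deg, pivot=phantom.grid.isocenter)
    perturbed = apply_setup_error(phantom.dose, t, stat_mask=phantom.brain_mask)
    part = dck_ick_partition(perturbed, ptv)
    mcd = min_covering_dose(perturbed, ptv)
    print(
        f"{mm:3.1f} mm/{deg:3.1f} deg: covering dose {mcd:5.1f} Gy | "
        f"DCK {part['dck_fraction']:5.1f}% ICK {part['ick_fraction']:5.1f}%"
    )
# the covering dose declines ~3.3 Gy per mm of error magnitude; once it falls
# below 15 Gy the indirect-cell-kill threshold is lost for part of the target
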