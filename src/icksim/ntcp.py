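"""Logistic NTCP model for brain radionecrosis.

Risk is a logistic function of the normal-brain volume receiving at least
x Gy (Vx, default x = 14):

    NTCP(Vx) = 1 / (1 + (Vx50 / Vx)^(4 * gamma50))

with literature parameters Vx50 = 45.8 cc (volume at 50% risk) and
gamma50 = 0.88 (slope) for brain metastases.  The "normal brain" is the
whole brain with GTVs included by default; a GTV-excluded variant is a
matter of passing a different mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, StructureMask
from .metrics import v_x

__all__ = ["NTCPParams", "ntcp", "ntcp_delta", "NTCPDelta"]


@dataclass(frozen=True)
class NTCPParams:
    """Logistic model constants: dose level x (Gy), Vx50 (cc), gamma50."""

    x: float = 14.0
    vx50: float = 45.8
    gamma50: float = 0.88

    def __post_init__(self) -> None:
        if self.vx50 <= 0:
            raise ValueError("vx50 must be > 0")
        if self.gamma50 <= 0:
            raise ValueError("gamma50 must be > 0")


def ntcp(vx, params: NTCPParams = NTCPParams()):
    """Radionecrosis probability in [0, 1] for volume ``vx`` (cc).

    Strictly increasing in ``vx``; exactly 0.5 at ``vx = vx50``; defined as 0
    at ``vx = 0`` (the limit).  Accepts scalars or arrays.
    """
    v = np.asarray(vx, dtype=float)
    if np.any(v < 0):
        raise ValueError("vx must be >= 0")
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = 1.0 / (1.0 + (params.vx50 / v[pos]) ** (4.0 * params.gamma50))
    return float(out) if np.isscalar(vx) or out.ndim == 0 else out


@dataclass
class NTCPDelta:
    """NTCP of a reference and a perturbed plan, and their differences."""

    vx_ref: float
    vx_perturbed: float
    ntcp_ref: float
    ntcp_perturbed: float
    abs_diff: float
    pct_diff: float  # NaN when the reference risk is zero

    @property
    def pct_diff_defined(self) -> bool:
        return not np.isnan(self.pct_diff)


def ntcp_delta(
    dose_ref: DoseGrid,
    dose_perturbed: DoseGrid,
    brain: StructureMask,
    params: NTCPParams = NTCPParams(),
) -> NTCPDelta:
    """Compare brain-toxicity risk before/after a setup error.

    Computes brain Vx (default V14Gy) for each dose, maps both through the
    logistic, and reports the absolute difference (percentage points on the
    probability scale is ``100 * abs_diff``) and the relative percent
    difference ``100 * (p2 - p1) / p1``.
    """
    if brain.is_empty:
        raise ValueError("brain mask is empty")
    if dose_ref.grid != dose_perturbed.grid or dose_ref.grid != brain.grid:
        raise ValueError("both doses and the brain mask must share one grid")
    v1 = v_x(dose_ref, brain, params.x)
    v2 = v_x(dose_perturbed, brain, params.x)
    p1 = ntcp(v1, params)
    p2 = ntcp(v2, params)
    pct = 100.0 * (p2 - p1) / p1 if p1 > 0 else float("nan")
    return NTCPDelta(
        vx_ref=v1, vx_perturbed=v2, ntcp_ref=p1, ntcp_perturbed=p2,
        abs_diff=p2 - p1, pct_diff=pct,
    )
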