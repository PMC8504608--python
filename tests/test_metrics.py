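import math

import numpy as np
import pytest

from icksim import (
    DoseGrid,
    GridSpec,
    StructureMask,
    Transform6DOF,
    apply_setup_error,
    dck_ick_partition,
    dvh,
    isodose_volume,
    min_covering_dose,
    oar_max_dose,
    v_x,
)
from conftest import random_dose_and_mask


class TestIsodoseVolume:
    def test_level_zero_is_entire_grid(self, sphere_phantom):
        m = isodose_volume(sphere_phantom.dose, 0.0)
        assert m.voxels.all()

    def test_level_above_max_is_empty(self, sphere_phantom):
        m = isodose_volume(sphere_phantom.dose, sphere_phantom.dose.max + 1.0)
        assert m.is_empty

    def test_15_gy_volume_matches_inverted_kernel_radius(self, sphere_phantom):
        # the kernel crosses 15 Gy at r = ptv_radius + (19.2 - 15)/3.3
        t = sphere_phantom.targets[0]
        r15 = t.ptv_radius + (t.boundary_min_dose - 15.0) / t.falloff_gradient
        analytic_cc = 4 / 3 * math.pi * r15**3 / 1000.0
        m = isodose_volume(sphere_phantom.dose, 15.0)
        shell_cc = 4 * math.pi * r15**2 * 1.25 * math.sqrt(3) / 2 / 1000.0
        assert abs(m.volume_cc - analytic_cc) < shell_cc

    def test_volume_monotone_nonincreasing_in_level(self, sphere_phantom):
        vols = [isodose_volume(sphere_phantom.dose, lv).volume_cc for lv in (0, 5, 10, 15, 20, 25)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestDckIckPartition:
    def test_ptv_inside_prescription_idv_is_pure_dck(self):
        g = GridSpec(shape=(6, 6, 6))
        dose = DoseGrid(np.full(g.shape, 21.0), g)
        ptv = StructureMask("PTV", np.ones(g.shape, bool), g)
        part = dck_ick_partition(dose, ptv)
        assert part["dck_fraction"] == 100.0
        assert part["ick_fraction"] == 0.0

    def test_unperturbed_phantom_is_nearly_all_dck(self, sphere_phantom):
        # the PTV rim receives 19.2-20 Gy by construction, so a thin shell
        # (~3% of a 9 mm PTV) counts as ICK even with no setup error
        part = dck_ick_partition(sphere_phantom.dose, sphere_phantom.ptv_masks[0])
        assert part["dck_fraction"] > 95.0
        assert part["v15_fraction"] == 100.0

    def test_uniform_intermediate_dose_is_pure_ick(self):
        g = GridSpec(shape=(6, 6, 6))
        dose = DoseGrid(np.full(g.shape, 17.0), g)
        ptv = StructureMask("PTV", np.ones(g.shape, bool), g)
        part = dck_ick_partition(dose, ptv)
        assert part["dck_fraction"] == 0.0
        assert part["ick_fraction"] == 100.0

    def test_empty_ptv_rejected(self):
        g = GridSpec(shape=(4, 4, 4))
        dose = DoseGrid(np.zeros(g.shape), g)
        with pytest.raises(ValueError, match="empty"):
            dck_ick_partition(dose, StructureMask("PTV", np.zeros(g.shape, bool), g))

    @pytest.mark.parametrize("seed", range(10))
    def test_fractions_match_brute_force_voxel_count(self, seed):
        rng = np.random.default_rng(seed)
        dose, mask = random_dose_and_mask(rng)
        part = dck_ick_partition(dose, mask, rx=20.0, ick_level=15.0)
        n = dck = ick = 0
        for idx in np.ndindex(*dose.grid.shape):
            if not mask.voxels[idx]:
                continue
            n += 1
            d = dose.values[idx]
            if d >= 20.0:
                dck += 1
            elif d >= 15.0:
                ick += 1
        assert part["dck_fraction"] == pytest.approx(100 * dck / n)
        assert part["ick_fraction"] == pytest.approx(100 * ick / n)
        # conservation is exact voxel algebra, not approximate
        assert part["dck_fraction"] + part["ick_fraction"] == part["v15_fraction"]


class TestMinCoveringDose:
    def test_uniform_dose_returns_that_level(self):
        g = GridSpec(shape=(5, 5, 5))
        dose = DoseGrid(np.full(g.shape, 20.0), g)
        ptv = StructureMask("PTV", np.ones(g.shape, bool), g)
        assert min_covering_dose(dose, ptv) == pytest.approx(20.0)

    def test_iterative_search_equals_voxel_min_oracle(self):
        # the Boolean bisection must agree exactly with floor-to-step of the
        # minimum PTV voxel dose, across 200 random instances
        rng = np.random.default_rng(42)
        for _ in range(200):
            dose, mask = random_dose_and_mask(rng, shape=(6, 6, 6))
            got = min_covering_dose(dose, mask, step=0.1)
            oracle = math.floor(dose.values[mask.voxels].min() / 0.1 + 1e-12) * 0.1
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_unperturbed_sphere_covered_near_boundary_dose(self, sphere_phantom):
        mcd = min_covering_dose(sphere_phantom.dose, sphere_phantom.ptv_masks[0])
        t = sphere_phantom.targets[0]
        in_margin_gradient = (t.d_max - t.boundary_min_dose) / t.ptv_margin
        assert 19.2 <= mcd <= 19.2 + in_margin_gradient * 0.625 + 0.1

    def test_monotone_nonincreasing_in_translation_magnitude(self, sphere_phantom):
        ptv = sphere_phantom.ptv_masks[0]
        doses = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            out = apply_setup_error(
                sphere_phantom.dose, Transform6DOF(dx=shift), warn_clip_fraction=1.0
            )
            doses.append(min_covering_dose(out, ptv))
        assert all(a >= b for a, b in zip(doses, doses[1:]))

    def test_covered_fraction_knob_ignores_single_cold_voxel(self):
        g = GridSpec(shape=(12, 12, 12))
        vals = np.full(g.shape, 20.0)
        vals[0, 0, 0] = 5.0
        dose = DoseGrid(vals, g)
        ptv = StructureMask("PTV", np.ones(g.shape, bool), g)
        assert min_covering_dose(dose, ptv) == pytest.approx(5.0)
        assert min_covering_dose(dose, ptv, covered_fraction=0.999) == pytest.approx(20.0)


class TestDvhAndVx:
    def test_uniform_dose_gives_step_function(self):
        g = GridSpec(shape=(5, 5, 5), spacing=(2.0, 2.0, 2.0))
        dose = DoseGrid(np.full(g.shape, 10.0), g)
        mask = StructureMask("m", np.ones(g.shape, bool), g)
        table = dvh(dose, mask, bin_width=0.5)
        assert table.volume_pct.iloc[0] == 100.0
        below = table[table.dose_gy <= 10.0]
        above = table[table.dose_gy > 10.0]
        assert (below.volume_pct == 100.0).all()
        assert (above.volume_pct == 0.0).all()

    def test_dvh_starts_at_mask_volume_and_is_monotone(self, sphere_phantom):
        table = dvh(sphere_phantom.dose, sphere_phantom.brain_mask)
        assert table.volume_cc.iloc[0] == pytest.approx(sphere_phantom.brain_mask.volume_cc)
        assert (np.diff(table.volume_cc.to_numpy()) <= 1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_dvh_and_vx_match_brute_force_counts(self, seed):
        rng = np.random.default_rng(100 + seed)
        dose, mask = random_dose_and_mask(rng)
        table = dvh(dose, mask, bin_width=1.0)
        vox_cc = dose.grid.voxel_volume_cc
        for level in rng.uniform(0, 25, size=5):
            expected = (dose.values[mask.voxels] >= level).sum() * vox_cc
            assert v_x(dose, mask, level) == pytest.approx(expected)
        for _, row in table.iloc[:: max(1, len(table) // 7)].iterrows():
            assert row.volume_cc == pytest.approx(v_x(dose, mask, row.dose_gy))

    def test_vx_edge_levels(self, sphere_phantom):
        brain = sphere_phantom.brain_mask
        assert v_x(sphere_phantom.dose, brain, 0.0) == pytest.approx(brain.volume_cc)
        assert v_x(sphere_phantom.dose, brain, sphere_phantom.dose.max + 1) == 0.0

    def test_empty_mask_rejected(self):
        g = GridSpec(shape=(4, 4, 4))
        dose = DoseGrid(np.zeros(g.shape), g)
        empty = StructureMask("m", np.zeros(g.shape, bool), g)
        with pytest.raises(ValueError):
            dvh(dose, empty)


class TestOarMaxDose:
    def test_uniform_field_and_scaling(self):
        g = GridSpec(shape=(4, 4, 4))
        dose = DoseGrid(np.full(g.shape, 7.5), g)
        oar = StructureMask("brainstem", np.ones(g.shape, bool), g)
        assert oar_max_dose(dose, oar) == 7.5
        scaled = DoseGrid(dose.values * 3.0, g)
        assert oar_max_dose(scaled, oar) == pytest.approx(3.0 * 7.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_max(self, seed):
        rng = np.random.default_rng(200 + seed)
        dose, mask = random_dose_and_mask(rng)
        assert oar_max_dose(dose, mask) == pytest.approx(dose.values[mask.voxels].max())

    def test_empty_oar_rejected(self):
        g = GridSpec(shape=(4, 4, 4))
        dose = DoseGrid(np.zeros(g.shape), g)
        with pytest.raises(ValueError, match="empty"):
            oar_max_dose(dose, StructureMask("oar", np.zeros(g.shape, bool), g))
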