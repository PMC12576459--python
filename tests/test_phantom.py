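import math

import numpy as np
import pytest

from ctdosim.attenuation import MATERIALS
from ctdosim.phantom import (ABDOMEN_ORGAN_LABELS, CTDI_BORE_LABELS,
                             SchneiderCalibration, add_table, coarse_grain,
                             hu_to_material, load_default_calibration,
                             make_ctdi_phantom, make_free_air_phantom,
                             make_synthetic_abdomen)
from tests.conftest import uniform_phantom


@pytest.fixture(scope="module")
def calib():
    return load_default_calibration()


class TestHUCalibration:
    def test_hu_minus_1000_is_air(self, calib):
        mat, rho = hu_to_material(-1000.0, calib)
        assert mat == "air"
        assert rho == pytest.approx(0.0012, abs=2e-4)

    def test_hu_zero_is_soft_tissue_near_unit_density(self, calib):
        mat, rho = hu_to_material(0.0, calib)
        assert mat == "soft_tissue"
        assert rho == pytest.approx(1.00, abs=0.01)

    def test_density_monotone_over_sweep(self, calib):
        hu = np.linspace(-1000.0, 1500.0, 500)
        _, rho = calib.lookup(hu)
        assert np.all(np.diff(rho) >= -1e-6)

    def test_pure_function(self, calib):
        assert hu_to_material(123.0, calib) == hu_to_material(123.0, calib)

    def test_out_of_range_clamped_with_warning(self, calib):
        with pytest.warns(UserWarning):
            mat, _ = hu_to_material(5000.0, calib)
        assert mat == "bone_cortical"

    def test_bins_must_be_contiguous(self):
        with pytest.raises(ValueError):
            SchneiderCalibration(np.array([-1000.0, 0.0]), np.array([-500.0, 100.0]),
                                 ["air", "water"], np.array([0.001, 1.0]),
                                 np.array([0.001, 1.0]))

    def test_covers_standard_range(self, calib):
        assert calib.hu_lo[0] <= -1024
        assert calib.hu_hi[-1] >= 3000


class TestCoarseGrain:
    def test_spacing_068_to_272(self, calib):
        ph = uniform_phantom("soft_tissue", 1.06, dims=(8, 8, 4),
                             voxel_mm=(0.68, 0.68, 5.0))
        coarse = coarse_grain(ph, (4, 4, 1))
        np.testing.assert_allclose(coarse.spacing, [2.72, 2.72, 5.0])
        assert coarse.dims == (2, 2, 4)

    def test_uniform_phantom_unchanged_except_dims(self):
        ph = uniform_phantom("pmma", 1.19, dims=(8, 8, 4))
        coarse = coarse_grain(ph, (4, 4, 1))
        assert coarse.materials[int(coarse.material_id[0, 0, 0])] == "pmma"
        np.testing.assert_allclose(coarse.density, 1.19, rtol=1e-6)

    def test_mass_conserved(self, rng):
        ph = uniform_phantom("water", 1.0, dims=(8, 8, 4))
        ph.density = rng.uniform(0.5, 2.0, ph.dims).astype(np.float32)
        coarse = coarse_grain(ph, (4, 4, 2))
        assert coarse.total_mass_g() == pytest.approx(ph.total_mass_g(), rel=1e-6)

    def test_block_material_rebinned_from_mean_hu(self, calib):
        ph = uniform_phantom("water", 1.0, dims=(4, 4, 1))
        # half the block bone-like, half lung-like: mean HU is soft-tissue range
        hu = np.full(ph.dims, 800.0, dtype=np.float32)
        hu[:2] = -700.0
        ph.hu = hu
        ids, rho = calib.lookup(hu)
        ph.density = rho
        coarse = coarse_grain(ph, (4, 4, 1), calib=calib)
        name = coarse.materials[int(coarse.material_id[0, 0, 0])]
        assert name == "soft_tissue"  # mean HU = 50

    def test_padding_flagged(self):
        ph = uniform_phantom("water", 1.0, dims=(7, 8, 4))
        with pytest.warns(UserWarning):
            coarse = coarse_grain(ph, (4, 4, 1))
        assert coarse.dims == (2, 2, 4)


class TestCTDIPhantom:
    def test_pmma_density_outside_bores(self):
        ph, _ = make_ctdi_phantom()
        pmma_id = ph.materials.index("pmma")
        assert np.all(ph.density[ph.material_id == pmma_id] == pytest.approx(1.19))

    def test_mass_oracle(self):
        ph, _ = make_ctdi_phantom()
        r, length, rho = 16.0, 15.0, 1.19
        analytic = math.pi * r**2 * length * rho
        analytic -= 5 * math.pi * 0.65**2 * length * rho  # air bores remove PMMA
        assert ph.total_mass_g() == pytest.approx(analytic, rel=0.01)

    def test_bore_positions(self):
        ph, bore_xy = make_ctdi_phantom()
        assert set(bore_xy) == set(CTDI_BORE_LABELS.values())
        for name in ("12oclock", "3oclock", "6oclock", "9oclock"):
            assert math.hypot(*bore_xy[name]) == pytest.approx(150.0)
        assert bore_xy["center"] == (0.0, 0.0)

    def test_all_five_chambers_labeled(self):
        ph, _ = make_ctdi_phantom()
        assert set(np.unique(ph.organ_label)) == {0, 1, 2, 3, 4, 5}

    def test_solid_bore_option(self):
        ph, _ = make_ctdi_phantom(bore_material="pmma")
        assert np.all(ph.density[ph.organ_label == 1] == pytest.approx(1.19))


class TestSyntheticAbdomen:
    def test_six_organs_present_and_disjoint(self, abdomen):
        ph, _ = abdomen
        present = set(np.unique(ph.organ_label))
        assert set(ABDOMEN_ORGAN_LABELS) <= present | {0}
        for label in range(1, 7):
            assert (ph.organ_label == label).sum() > 0

    def test_deterministic_from_seed(self):
        a, _ = make_synthetic_abdomen(seed=7)
        b, _ = make_synthetic_abdomen(seed=7)
        np.testing.assert_array_equal(a.material_id, b.material_id)
        np.testing.assert_array_equal(a.organ_label, b.organ_label)
        c, _ = make_synthetic_abdomen(seed=8)
        assert not np.array_equal(a.organ_label, c.organ_label)

    def test_organ_volumes_match_ellipsoid_oracle(self):
        ph, organ_geometry = make_synthetic_abdomen(seed=3)
        label_of = {v: k for k, v in ABDOMEN_ORGAN_LABELS.items()}
        vv = ph.voxel_volume_cm3
        for name, parts in organ_geometry.items():
            analytic = sum(4.0 / 3.0 * math.pi * np.prod(semi) / 1000.0
                           for _, semi in parts)
            voxelized = (ph.organ_label == label_of[name]).sum() * vv
            assert voxelized == pytest.approx(analytic, rel=0.05), name

    def test_spine_is_bone(self, abdomen):
        ph, _ = abdomen
        spine = ph.organ_label == 7
        assert spine.sum() > 0
        bone_id = ph.materials.index("bone_cortical")
        assert np.all(ph.material_id[spine] == bone_id)


class TestFreeAirPhantom:
    def test_all_air_with_chamber(self):
        ph = make_free_air_phantom()
        assert ph.materials == ["air"]
        assert (ph.organ_label == 1).sum() > 0
        # chamber spans 100 mm of the z axis
        nvox = (ph.organ_label == 1).sum()
        assert nvox * ph.spacing[2] >= 100.0


class TestAddTable:
    def test_table_materials_added_below_phantom(self):
        ph, _ = make_ctdi_phantom()
        with_table = add_table(ph)
        assert "carbon_fiber" in with_table.materials
        assert "foam" in with_table.materials
        shell_id = with_table.materials.index("carbon_fiber")
        assert (with_table.material_id == shell_id).sum() > 0
        # table voxels sit below the phantom (negative y side)
        assert with_table.origin[1] < ph.origin[1]

    def test_table_attenuates_bottom_rays(self):
        ph, _ = make_ctdi_phantom()
        with_table = add_table(ph)
        # integrate mass thickness along a vertical ray through the center
        j_col = with_table.density[with_table.dims[0] // 2, :,
                                   with_table.dims[2] // 2]
        ph_col = ph.density[ph.dims[0] // 2, :, ph.dims[2] // 2]
        assert j_col.sum() * with_table.spacing[1] > ph_col.sum() * ph.spacing[1]
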