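import numpy as np
import pytest

import bolusforge as bf
from bolusforge.core import Volume3D
from bolusforge.dose_model import DoseGrid, Prescription


def grid_of(values):
    return DoseGrid(Volume3D(values, (1.0, 1.0, 1.0)), Prescription())


def random_dose(rng, shape=(12, 12, 8), scale=50.0):
    return grid_of(rng.random(shape) * scale)


class TestDifferentialDVH:
    def test_uniform_dose_single_bin(self):
        dose = grid_of(np.full((4, 4, 4), 10.0))
        mask = np.ones((4, 4, 4), bool)
        curve = bf.differential_dvh(dose, mask, 0.1)
        assert (curve.volumes_mm3 > 0).sum() == 1
        assert curve.total_volume_mm3 == pytest.approx(64.0)

    def test_two_voxels_two_equal_bins(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0], vals[1, 0, 0] = 10.0, 20.0
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        curve = bf.differential_dvh(grid_of(vals), mask, 1.0)
        occupied = curve.volumes_mm3[curve.volumes_mm3 > 0]
        assert len(occupied) == 2
        assert np.allclose(occupied, 1.0)

    def test_conservation_exact_on_random_grids(self):
        """sum v(D) dD equals the structure volume exactly."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            dose = random_dose(rng)
            mask = rng.random(dose.dose.shape) > 0.5
            curve = bf.differential_dvh(dose, mask, 0.1)
            assert curve.total_volume_mm3 == mask.sum() * 1.0

    def test_cumulative_starts_at_100_and_decreases(self):
        rng = np.random.default_rng(1)
        curve = bf.differential_dvh(random_dose(rng), np.ones((12, 12, 8), bool), 0.5)
        _, cum = curve.cumulative_percent()
        assert cum[0] == pytest.approx(100.0)
        assert (np.diff(cum) <= 1e-9).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            bf.differential_dvh(grid_of(np.ones((2, 2, 2))), np.zeros((2, 2, 2), bool))


class TestDoseMoments:
    def test_uniform_dose_zero_std(self):
        dose = grid_of(np.full((4, 4, 4), 10.0))
        stats = bf.dose_mean_std(bf.differential_dvh(dose, np.ones((4, 4, 4), bool), 0.1))
        # the bin-centre convention shifts an on-edge value by half a bin
        assert stats.D_mean_Gy == pytest.approx(10.0, abs=0.0501)
        assert stats.D_std_Gy == pytest.approx(0.0, abs=1e-9)

    def test_two_point_distribution_closed_form(self):
        """Equal volumes at 10 and 20 Gy -> mean 15, std 5."""
        vals = np.zeros((4, 4, 4))
        vals[:2], vals[2:] = 10.0, 20.0
        stats = bf.dose_mean_std(
            bf.differential_dvh(grid_of(vals), np.ones((4, 4, 4), bool), 0.1)
        )
        assert stats.D_mean_Gy == pytest.approx(15.0, abs=0.0501)
        assert stats.D_std_Gy == pytest.approx(5.0, abs=0.0501)

    def test_moments_match_voxel_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            dose = random_dose(rng)
            mask = rng.random(dose.dose.shape) > 0.3
            dvh_stats = bf.dose_mean_std(bf.differential_dvh(dose, mask, 0.1))
            vox = bf.voxel_dose_stats(dose, mask)
            assert dvh_stats.D_mean_Gy == pytest.approx(vox.D_mean_Gy, abs=0.05)
            assert dvh_stats.D_std_Gy == pytest.approx(vox.D_std_Gy, abs=0.05)

    def test_convergence_with_bin_width(self):
        rng = np.random.default_rng(3)
        dose = random_dose(rng)
        mask = np.ones(dose.dose.shape, bool)
        vox = bf.voxel_dose_stats(dose, mask)
        errs = [
            abs(
                bf.dose_mean_std(bf.differential_dvh(dose, mask, bw)).D_mean_Gy
                - vox.D_mean_Gy
            )
            for bw in (2.0, 0.1)
        ]
        assert errs[1] < errs[0]


class TestConformityIndex:
    def test_perfect_conformity(self):
        vals = np.zeros((6, 6, 6))
        target = np.zeros((6, 6, 6), bool)
        target[2:4, 2:4, 2:4] = True
        vals[target] = 50.0
        res = bf.conformity_index(grid_of(vals), target, prescription_Gy=50.0)
        assert res.ci == pytest.approx(1.0)

    def test_half_conformity_by_voxel_counting(self):
        """Reference isodose twice the target, target fully covered -> 0.5."""
        vals = np.zeros((8, 8, 8))
        vals[0:4] = 50.0
        target = np.zeros((8, 8, 8), bool)
        target[0:2] = True
        res = bf.conformity_index(grid_of(vals), target, prescription_Gy=50.0)
        assert res.ci == pytest.approx(0.5)
        assert res.tv_ri_mm3 == pytest.approx(2 * 64.0)
        assert res.v_ri_mm3 == pytest.approx(4 * 64.0)

    def test_matches_counting_oracle_on_random_configs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            dose = random_dose(rng, scale=60.0)
            target = rng.random(dose.dose.shape) > 0.5
            level, rx = 0.9, 50.4
            ri = dose.dose.values >= level * rx
            if not ri.any():
                continue
            expected = (ri & target).sum() / ri.sum()
            res = bf.conformity_index(dose, target, rx, level)
            assert res.ci == pytest.approx(expected, abs=1e-12)

    def test_all_below_threshold_is_undefined_not_zero(self):
        vals = np.full((4, 4, 4), 10.0)
        with pytest.raises(bf.UndefinedConformityError):
            bf.conformity_index(grid_of(vals), np.ones((4, 4, 4), bool), 50.0)

    def test_invariant_under_joint_scaling(self):
        rng = np.random.default_rng(5)
        dose = random_dose(rng, scale=60.0)
        target = rng.random(dose.dose.shape) > 0.6
        a = bf.conformity_index(dose, target, 50.0)
        scaled = grid_of(dose.dose.values * 1.7)
        b = bf.conformity_index(scaled, target, 50.0 * 1.7)
        assert a.ci == pytest.approx(b.ci, abs=1e-12)


class TestNormalization:
    def test_scaling_ratio(self):
        vals = np.full((4, 4, 4), 45.0)
        mask = np.ones((4, 4, 4), bool)
        out = bf.normalize_to_equal_cw_mean(grid_of(vals), mask, 48.0)
        assert np.allclose(out.dose.values, 45.0 * 48.0 / 45.0)

    def test_identity_when_reference_equals_current(self):
        rng = np.random.default_rng(6)
        dose = random_dose(rng)
        mask = np.ones(dose.dose.shape, bool)
        current = float(dose.dose.values.mean())
        out = bf.normalize_to_equal_cw_mean(dose, mask, current)
        assert np.allclose(out.dose.values, dose.dose.values)

    def test_two_plans_agree_after_normalization(self):
        rng = np.random.default_rng(7)
        a, b = random_dose(rng), random_dose(rng)
        mask = rng.random(a.dose.shape) > 0.4
        na = bf.normalize_to_equal_cw_mean(a, mask, 48.0)
        nb = bf.normalize_to_equal_cw_mean(b, mask, 48.0)
        assert na.dose.values[mask].mean() == pytest.approx(
            nb.dose.values[mask].mean(), rel=1e-9
        )

    def test_zero_mean_rejected(self):
        dose = grid_of(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            bf.normalize_to_equal_cw_mean(dose, np.ones((4, 4, 4), bool), 48.0)
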