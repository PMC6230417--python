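import numpy as np
import pytest

from hepavol.errors import ContractError, HepavolError
from hepavol.io import BinaryMask, CTVolume
from hepavol.metrics import (
    combined_change,
    label_lesions,
    longest_axial_diameter,
    mean_density,
    percent_change,
    recist_category,
    recist_sum,
    response_record,
    total_volume,
)


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(data, float), spacing)


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(data, bool), spacing)


class TestLabelLesions:
    def test_empty_mask(self):
        vol = _vol(np.zeros((5, 5, 5)))
        ls = label_lesions(_mask(np.zeros((5, 5, 5))), vol)
        assert ls.lesion_count == 0
        assert total_volume(ls) == 0.0
        with pytest.raises(HepavolError):
            mean_density(ls)

    def test_three_cubes(self):
        m = np.zeros((12, 12, 12), dtype=bool)
        for o in (0, 4, 8):
            m[o : o + 3, 0:3, 0:3] = True
        vol = _vol(np.full((12, 12, 12), 80.0))
        ls = label_lesions(_mask(m), vol)
        assert ls.lesion_count == 3
        assert total_volume(ls) == pytest.approx(0.081)
        assert mean_density(ls) == pytest.approx(80.0)

    def test_connectivity_matters_for_diagonal_touch(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 1, 1] = m[2, 2, 2] = True
        vol = _vol(np.zeros((4, 4, 4)))
        assert label_lesions(_mask(m), vol, connectivity=26).lesion_count == 1
        assert label_lesions(_mask(m), vol, connectivity=6).lesion_count == 2

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ContractError):
            label_lesions(_mask(np.zeros((4, 4, 4))), _vol(np.zeros((5, 5, 5))))

    def test_density_is_voxel_weighted(self):
        """D is the mean over the union of tumor voxels, not of lesion means."""
        m = np.zeros((8, 8, 8), dtype=bool)
        m[1, 1:3, 1:3] = True        # 4 voxels
        m[5, 1:5, 1:5] = True        # 16 voxels
        data = np.zeros((8, 8, 8))
        data[1] = 100.0
        data[5] = 50.0
        ls = label_lesions(_mask(m), _vol(data))
        expected = (4 * 100 + 16 * 50) / 20
        assert mean_density(ls) == pytest.approx(expected)
        assert expected != pytest.approx(np.mean([100, 50]))

    def test_split_merge_invariance(self, rng):
        """V and D do not change when a mask is re-labeled as one lesion or many."""
        m = rng.random((10, 10, 10)) > 0.7
        vol = _vol(rng.normal(70, 20, (10, 10, 10)))
        ls26 = label_lesions(_mask(m), vol, connectivity=26)
        ls6 = label_lesions(_mask(m), vol, connectivity=6)
        assert total_volume(ls26) == pytest.approx(total_volume(ls6))
        assert mean_density(ls26) == pytest.approx(mean_density(ls6))


class TestDiameter:
    def test_single_voxel_zero(self):
        assert longest_axial_diameter(np.array([[2, 3, 4]]), (1, 1, 1)) == 0.0

    def test_row_of_11_voxels(self):
        vox = np.array([[0, 0, x] for x in range(11)])
        assert longest_axial_diameter(vox, (1.8, 1.0, 1.0)) == pytest.approx(1.0)

    def test_digitized_sphere(self):
        spacing = (1.0, 1.0, 1.0)
        zz, yy, xx = np.mgrid[:25, :25, :25]
        sphere = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 10.0**2
        d = longest_axial_diameter(np.argwhere(sphere), spacing)
        assert abs(d - 2.0) <= np.hypot(1.0, 1.0) / 10.0  # one in-plane diagonal

    def test_anisotropic_in_plane_spacing(self):
        vox = np.array([[0, 0, 0], [0, 3, 0], [0, 0, 4]])
        d = longest_axial_diameter(vox, (5.0, 2.0, 1.0))
        assert d == pytest.approx(np.hypot(6.0, 4.0) / 10.0)


class TestRecistSum:
    def _lesionset(self, diameters):
        from hepavol.metrics import Lesion, LesionSet

        lesions = [
            Lesion(i + 1, 10, 0.1, 70.0, d, (0.0, 0.0, float(i)))
            for i, d in enumerate(diameters)
        ]
        return LesionSet(lesions, 0.1 * len(lesions), 70.0, (1, 1, 1))

    def test_top_two_rule(self):
        s, labels = recist_sum(self._lesionset([3.1, 2.2, 1.5]))
        assert s == pytest.approx(5.3)
        assert len(labels) == 2

    def test_measurability_floor(self):
        assert recist_sum(self._lesionset([0.8])) is None

    def test_sub_centimeter_excluded_from_targets(self):
        s, _ = recist_sum(self._lesionset([2.0, 0.9, 0.8]))
        assert s == pytest.approx(2.0)


class TestChangeStatistics:
    def test_percent_change_worked_regression_case(self):
        # printed per-case volumes 57.4 -> 40.9 cm^3
        assert percent_change(57.4, 40.9) == pytest.approx(-28.75, abs=0.005)

    def test_percent_change_worked_progression_case(self):
        # printed per-case volumes 45.1 -> 77.6 cm^3
        assert percent_change(45.1, 77.6) == pytest.approx(72.06, abs=0.005)

    def test_percent_change_identity_and_domain(self):
        assert percent_change(12.3, 12.3) == 0.0
        with pytest.raises(ContractError):
            percent_change(0.0, 5.0)

    def test_combined_change_examples(self):
        assert combined_change(131.25, -4.7) == pytest.approx(126.55)
        assert combined_change(0, 0) == 0
        assert combined_change(-74.55, -27.84) == pytest.approx(-102.39)

    def test_baseline_reference_asymmetry(self):
        """Swapping pre/post does not negate the change; the exchanged value
        is 100*(pre/post - 1) — changes are baseline-referenced."""
        fwd = percent_change(50.0, 75.0)
        rev = percent_change(75.0, 50.0)
        assert rev != pytest.approx(-fwd)
        assert rev == pytest.approx(100 * (50 / 75 - 1))


class TestRecistCategory:
    def test_pr_threshold(self):
        assert recist_category(-35.0) == "PR"

    def test_pd_needs_absolute_increase(self):
        assert recist_category(25.0, absolute_increase_mm=3.0) == "SD"
        assert recist_category(25.0, absolute_increase_mm=6.0) == "PD"

    def test_cr(self):
        assert recist_category(-100.0, all_targets_gone=True) == "CR"

    def test_exhaustive_grid_against_rule_table(self):
        def oracle(ds, mm, gone):
            if gone:
                return "CR"
            if ds <= -30:
                return "PR"
            if ds >= 20 and mm >= 5:
                return "PD"
            return "SD"

        for ds in np.arange(-100, 101, 2.5):
            for mm in np.arange(0, 12, 0.5):
                for gone in (False, True):
                    assert recist_category(ds, mm, gone) == oracle(ds, mm, gone)


class TestResponseRecord:
    def test_phantom_truth_masks_give_consistent_record(self, easy_phantom_pair):
        pre, post, truth = easy_phantom_pair
        rec = response_record(
            label_lesions(truth.tumor_mask_pre, pre),
            label_lesions(truth.tumor_mask_post, post),
        )
        assert rec.combined_pct == pytest.approx(
            rec.delta_volume_pct + rec.delta_density_pct
        )
        assert rec.progression_group in ("progression", "nonprogression")
        assert (rec.progression_group == "progression") == (rec.recist_category == "PD")

    def test_configured_sphere_volume_recovered(self):
        from hepavol.phantom import PhantomConfig, make_phantom

        cfg = PhantomConfig(
            shape=(40, 56, 56), spacing=(1.5, 1.5, 1.5),
            liver_semiaxes_mm=(26, 36, 38), tumor_count=3,
            tumor_radius_range_mm=(9, 11), tumor_hu_sigma=0.0, seed=5,
        )
        pre, _, truth = make_phantom(cfg)
        ls = label_lesions(truth.tumor_mask_pre, pre)
        assert total_volume(ls) == pytest.approx(truth.analytic_v_pre_cm3, rel=0.05)
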