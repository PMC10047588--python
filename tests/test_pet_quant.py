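"""SUV computation, MTV/hypoxia threshold segmentation, TLG, TMR, SUVpeak."""

import numpy as np
import pytest

from hypoxmap.core import BinaryMask, ImageGrid, ScalarVolume
from hypoxmap.pet import (
    PetStudy,
    classify_hypoxic,
    compute_suv,
    muscle_reference,
    segment_hypoxic,
    segment_mtv,
    suv_peak,
    tlg,
    tmr,
)
from conftest import make_mask, make_volume


def _study(activity, dose=1e8, weight=7e4, tracer="FDG"):
    return PetStudy(make_volume(activity, units="Bq/mL"), dose, weight, tracer)


class TestComputeSuv:
    def test_normalization_identity(self):
        dose, weight = 2.5e8, 7.5e4
        act = np.full((4, 4, 4), dose / weight)
        suv = compute_suv(_study(act, dose, weight))
        assert np.allclose(suv.values, 1.0)
        assert suv.units == "SUV"

    def test_zero_activity(self):
        suv = compute_suv(_study(np.zeros((3, 3, 3))))
        assert np.all(suv.values == 0)

    def test_hot_voxel_suv_max(self):
        dose, weight = 1e8, 5e4
        act = np.zeros((4, 4, 4))
        act[1, 2, 3] = 2 * dose / weight
        suv = compute_suv(_study(act, dose, weight))
        assert suv.values.max() == pytest.approx(2.0)

    def test_invalid_dose_weight(self):
        with pytest.raises(ValueError):
            _study(np.ones((2, 2, 2)), dose=0.0)
        with pytest.raises(ValueError):
            _study(np.ones((2, 2, 2)), weight=-1.0)


def brute_force_threshold(values, roi, fraction):
    """Independent enumeration oracle for the closed-threshold rule."""
    vmax = max(values[i] for i in zip(*np.nonzero(roi)))
    return {
        idx
        for idx in zip(*np.nonzero(roi))
        if values[idx] >= fraction * vmax
    }


class TestSegmentMtv:
    def test_single_hot_voxel(self):
        vals = np.zeros((8, 8, 8))
        vals[4, 4, 4] = 10.0
        roi = make_mask(np.ones((8, 8, 8)))
        mtv = segment_mtv(make_volume(vals), roi)
        assert mtv.count == 1 and mtv.membership[4, 4, 4]

    def test_closed_threshold_rule(self):
        # values {10, 5, 4, 3.9}: threshold 4.0 keeps {10, 5, 4}
        vals = np.zeros((4, 4, 4))
        vals[0, 0, 0], vals[0, 0, 1], vals[0, 0, 2], vals[0, 0, 3] = 10, 5, 4, 3.9
        roi = np.zeros((4, 4, 4), bool)
        roi[0, 0, :] = True
        mtv = segment_mtv(make_volume(vals), make_mask(roi), fraction=0.40)
        assert set(zip(*np.nonzero(mtv.membership))) == {(0, 0, 0), (0, 0, 1), (0, 0, 2)}

    def test_agrees_with_enumeration_oracle_when_connected(self, rng):
        vals = rng.random((12, 12, 12)) * 2
        vals[4:8, 4:8, 4:8] += 8  # hot connected block
        roi = np.zeros_like(vals, dtype=bool)
        roi[2:10, 2:10, 2:10] = True
        mtv = segment_mtv(make_volume(vals), make_mask(roi), fraction=0.40)
        assert set(zip(*np.nonzero(mtv.membership))) == brute_force_threshold(
            vals, roi, 0.40
        )

    def test_disconnected_hot_blob_excluded(self):
        vals = np.zeros((16, 16, 16))
        vals[2:5, 2:5, 2:5] = 10.0  # blob A contains the max
        vals[3, 3, 3] = 12.0
        vals[10:13, 10:13, 10:13] = 9.0  # blob B above threshold, disconnected
        roi = make_mask(np.ones_like(vals, dtype=bool))
        mtv = segment_mtv(make_volume(vals), roi, fraction=0.40)
        assert mtv.membership[3, 3, 3]
        assert not mtv.membership[11, 11, 11]

    def test_monotone_in_fraction(self, rng):
        vals = rng.random((10, 10, 10)) * 5
        vals[5, 5, 5] = 10.0
        roi = make_mask(np.ones_like(vals, dtype=bool))
        vol = make_volume(vals)
        prev = segment_mtv(vol, roi, fraction=0.2)
        for f in (0.3, 0.5, 0.7, 0.9):
            cur = segment_mtv(vol, roi, fraction=f)
            assert np.all(cur.membership <= prev.membership)
            prev = cur

    def test_errors(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            segment_mtv(vol, make_mask(np.zeros((4, 4, 4))))
        with pytest.raises(ValueError):
            segment_mtv(vol, make_mask(np.ones((4, 4, 4))))


class TestTlg:
    def test_patient_level_product(self):
        # MTV 2.2 cm^3 with SUVmean 4.9 gives the printed TLG 10.78
        assert tlg(2.2, 4.9) == pytest.approx(10.78)

    @pytest.mark.parametrize("mtv,mean,expected", [(0.0, 3.3, 0.0), (15.3, 1.0, 15.3)])
    def test_edge_products(self, mtv, mean, expected):
        assert tlg(mtv, mean) == expected


class TestMuscleReferenceAndTmr:
    def test_muscle_mean(self):
        vals = np.zeros((4, 4, 4))
        vals[0, 0, :3] = [1.0, 2.0, 3.0]
        roi = np.zeros_like(vals, dtype=bool)
        roi[0, 0, :3] = True
        assert muscle_reference(make_volume(vals), make_mask(roi)) == pytest.approx(2.0)

    def test_single_voxel(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = 0.8
        roi = np.zeros_like(vals, dtype=bool)
        roi[0, 0, 0] = True
        assert muscle_reference(make_volume(vals), make_mask(roi)) == pytest.approx(0.8)

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            muscle_reference(make_volume(np.ones((2, 2, 2))), make_mask(np.zeros((2, 2, 2))))

    @pytest.mark.parametrize("mx,mean,expected", [(2.5, 2.0, 1.25), (2.0, 2.0, 1.0), (3.56, 1.0, 3.56)])
    def test_tmr(self, mx, mean, expected):
        assert tmr(mx, mean) == pytest.approx(expected)

    def test_classification_strict_cutoff(self):
        assert not classify_hypoxic(1.25)
        assert classify_hypoxic(1.25 + 1e-2)
        assert not classify_hypoxic(0.9)


class TestSegmentHypoxic:
    def test_containment_and_threshold(self):
        vals = np.zeros((6, 6, 6))
        vals[1, 1, 1] = 1.5  # inside tumor, above threshold
        vals[1, 1, 2] = 1.3  # inside tumor, below
        vals[4, 4, 4] = 1.5  # outside tumor
        tumor = np.zeros_like(vals, dtype=bool)
        tumor[1, 1, :3] = True
        hsv = segment_hypoxic(make_volume(vals), make_mask(tumor), 1.0, factor=1.4)
        assert set(zip(*np.nonzero(hsv.membership))) == {(1, 1, 1)}

    def test_may_be_empty(self):
        vals = np.full((4, 4, 4), 1.3)
        tumor = make_mask(np.ones_like(vals, dtype=bool))
        hsv = segment_hypoxic(make_volume(vals), tumor, 1.0, factor=1.4)
        assert hsv.count == 0

    def test_invalid_muscle_reference(self):
        tumor = make_mask(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            segment_hypoxic(make_volume(np.ones((3, 3, 3))), tumor, 0.0)

    def test_subset_of_tumor_always(self, rng):
        vals = rng.random((10, 10, 10)) * 3
        tumor = make_mask(rng.random((10, 10, 10)) > 0.5)
        hsv = segment_hypoxic(make_volume(vals), tumor, 1.0)
        assert not np.any(hsv.membership & ~tumor.membership)


class TestSuvPeak:
    def test_uniform(self):
        vol = make_volume(np.full((10, 10, 10), 5.0))
        roi = make_mask(np.ones((10, 10, 10)))
        assert suv_peak(vol, roi) == pytest.approx(5.0)

    def test_single_hot_voxel_sphere_mean(self):
        shape, spacing = (21, 21, 21), (2.0, 2.0, 2.0)
        vals = np.zeros(shape)
        vals[10, 10, 10] = 100.0
        vol = make_volume(vals, spacing)
        roi = make_mask(np.ones(shape, bool), spacing)
        # brute-force oracle: sphere voxel count at this spacing
        radius = (3 * 1000.0 / (4 * np.pi)) ** (1 / 3)
        offs = [
            (i, j, k)
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if np.sqrt((2 * i) ** 2 + (2 * j) ** 2 + (2 * k) ** 2) <= radius
        ]
        assert suv_peak(vol, roi, 1.0) == pytest.approx(100.0 / len(offs))

    def test_tiny_sphere_equals_suv_max(self):
        vals = np.zeros((8, 8, 8))
        vals[2, 2, 2] = 7.0
        vol = make_volume(vals, (3.0, 3.0, 3.0))
        roi = make_mask(np.ones((8, 8, 8)), (3.0, 3.0, 3.0))
        assert suv_peak(vol, roi, sphere_ml=0.01) == pytest.approx(7.0)

    def test_ordering_mean_peak_max(self, rng):
        vals = rng.random((16, 16, 16)) * 5
        vals[8, 8, 8] = 10.0
        vol = make_volume(vals, (2.0, 2.0, 2.0))
        roi = np.zeros_like(vals, dtype=bool)
        roi[4:12, 4:12, 4:12] = True
        roi_m = make_mask(roi, (2.0, 2.0, 2.0))
        peak = suv_peak(vol, roi_m)
        assert vals[roi].mean() <= peak <= vals[roi].max()
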