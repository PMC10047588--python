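"""Boolean mask algebra, similarity indices, and subvolume report extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypoxmap.core import BinaryMask, ImageGrid, ScalarVolume
from hypoxmap.phantom import build_phantom, cohort_config, simulate_pet
from hypoxmap.pet import compute_suv
from hypoxmap.subvolumes import (
    SubvolumeSet,
    build_subvolume_set,
    dice,
    exclude,
    extract_report,
    jaccard,
    overlap_fraction,
    union,
)
from conftest import make_mask


def mask_with_n(n, shape=(20, 20, 20), offset=0, spacing=(1.0, 1.0, 1.0)):
    m = np.zeros(shape, bool)
    m.flat[offset : offset + n] = True
    return make_mask(m, spacing)


class TestBooleanOps:
    def test_union_idempotent(self, rng):
        a = make_mask(rng.random((8, 8, 8)) > 0.5)
        assert np.array_equal(union(a, a).membership, a.membership)

    def test_union_disjoint_counts_add(self):
        a = mask_with_n(10)
        b = mask_with_n(20, offset=100)
        assert union(a, b).count == 30

    def test_union_volume_interval_patient4_like(self):
        # HsV-FDG 1.2 cm^3, HsV-MRI 1.76 cm^3, printed union 2.22 cm^3:
        # any reconstruction must land in [max, sum] = [1.76, 2.96] cm^3
        a = mask_with_n(1200)  # 1 mm^3 voxels -> 1.2 cm^3
        b = mask_with_n(1760, offset=740)  # overlap 460 -> union 2.5 cm^3
        v = union(a, b).volume_cm3
        assert 1.76 <= v <= 2.96
        # and the specific printed union implies overlap 0.74 cm^3
        b2 = mask_with_n(1760, offset=1200 - 740)
        assert union(a, b2).volume_cm3 == pytest.approx(2.22)

    def test_exclude_empty_hsv_returns_tv(self):
        tv = mask_with_n(50)
        hsv = mask_with_n(0)
        assert np.array_equal(exclude(tv, hsv).membership, tv.membership)

    def test_exclude_full_hsv_empty(self):
        tv = mask_with_n(50)
        assert exclude(tv, tv).count == 0

    def test_exclude_counting_oracle(self):
        tv = mask_with_n(100)
        hsv = mask_with_n(30, offset=70)  # 30 inside tv
        assert exclude(tv, hsv).count == 70

    def test_grid_mismatch_rejected(self):
        a = mask_with_n(10)
        b = mask_with_n(10, spacing=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            union(a, b)


class TestSimilarityIndices:
    def test_identical(self, rng):
        a = make_mask(rng.random((8, 8, 8)) > 0.4)
        assert dice(a, a) == 1.0
        assert jaccard(a, a) == 1.0
        assert overlap_fraction(a, a) == 1.0

    def test_disjoint(self):
        a = mask_with_n(100)
        b = mask_with_n(100, offset=200)
        assert dice(a, b) == 0.0
        assert jaccard(a, b) == 0.0
        assert overlap_fraction(a, b) == 0.0

    def test_hand_arithmetic(self):
        a = mask_with_n(100)
        b = mask_with_n(300)  # contains a, intersection 100
        assert dice(a, b) == pytest.approx(0.5)
        assert jaccard(a, b) == pytest.approx(1.0 / 3.0)
        assert overlap_fraction(a, b) == 1.0

    def test_overlap_fraction_partial(self):
        a = mask_with_n(100)
        b = mask_with_n(300, offset=30)  # intersection 70
        assert overlap_fraction(a, b) == pytest.approx(0.7)

    def test_both_empty_rejected(self):
        a = mask_with_n(0)
        with pytest.raises(ValueError):
            dice(a, a)
        with pytest.raises(ValueError):
            overlap_fraction(a, mask_with_n(5))

    def test_jaccard_dice_identity_seeded_pairs(self):
        # jaccard = dice / (2 - dice) over many random mask pairs
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = make_mask(rng.random((10, 10, 10)) > rng.uniform(0.3, 0.7))
            b = make_mask(rng.random((10, 10, 10)) > rng.uniform(0.3, 0.7))
            if a.count + b.count == 0:
                continue
            d = dice(a, b)
            assert jaccard(a, b) == pytest.approx(d / (2 - d), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), p=st.floats(0.2, 0.8), q=st.floats(0.2, 0.8))
    def test_symmetry_property(self, seed, p, q):
        rng = np.random.default_rng(seed)
        a = make_mask(rng.random((6, 6, 6)) > p)
        b = make_mask(rng.random((6, 6, 6)) > q)
        if a.count == 0 or b.count == 0:
            return
        assert dice(a, b) == dice(b, a)
        assert jaccard(a, b) == jaccard(b, a)
        assert overlap_fraction(a, b) == overlap_fraction(b, a)


class TestSubvolumeSetInvariants:
    def test_partition_enforced(self):
        tv = mask_with_n(100)
        hsv = mask_with_n(30)
        nsv = exclude(tv, hsv)
        sset = SubvolumeSet(tv, tv, tv, hsv, hsv, hsv, nsv, nsv, nsv)
        vols = sset.volumes_cm3()
        assert vols["hsv_fdg"] + vols["nsv_fdg"] == pytest.approx(vols["tv_fdg"])

    def test_bad_partition_rejected(self):
        tv = mask_with_n(100)
        hsv = mask_with_n(30)
        with pytest.raises(ValueError):
            SubvolumeSet(tv, tv, tv, hsv, hsv, hsv, tv, tv, tv)

    def test_hsv_outside_tv_rejected(self):
        tv = mask_with_n(50)
        hsv = mask_with_n(30, offset=40)  # extends past tv
        nsv = exclude(tv, hsv)
        with pytest.raises(ValueError):
            SubvolumeSet(tv, tv, tv, hsv, hsv, hsv, nsv, nsv, nsv)


@pytest.fixture(scope="module")
def phantom_pipeline():
    """Noise-free phantom -> SUV maps, truth masks, and subvolume set."""
    from scipy import ndimage

    cfg = cohort_config(seed=11, pet_noise_frac=0.0)
    truth = build_phantom(cfg)
    suv_fdg = compute_suv(simulate_pet(truth, "FDG", noise_sd=0.0))
    suv_fmiso = compute_suv(simulate_pet(truth, "FMISO", noise_sd=0.0))
    search = ndimage.binary_dilation(
        truth.masks("fdg")["tumor_fdg_avid"].membership, iterations=3
    )
    search_roi = BinaryMask(suv_fdg.grid, search)
    subvols = build_subvolume_set(
        suv_fdg,
        suv_fmiso,
        truth.masks("t2")["tumor_mri"],
        truth.masks("fmiso")["muscle"],
        search_roi,
        fdg_to_fmiso=truth.inter_session_transform("fdg", "fmiso"),
        mri_to_fmiso=truth.inter_session_transform("t2", "fmiso"),
    )
    return cfg, truth, subvols


class TestBuildSubvolumeSet:
    def test_partition_audit(self, phantom_pipeline):
        _, _, subvols = phantom_pipeline
        for fam in ("fdg", "mri", "union"):
            masks = subvols.masks()
            assert (
                masks[f"hsv_{fam}"].count + masks[f"nsv_{fam}"].count
                == masks[f"tv_{fam}"].count
            )

    def test_core_inside_both_tumors_gives_identical_hsv(self, phantom_pipeline):
        # default geometry: hypoxic core lies inside both tumor volumes, so
        # all three hypoxic subvolumes coincide voxel for voxel
        _, _, subvols = phantom_pipeline
        assert np.array_equal(subvols.hsv_fdg.membership, subvols.hsv_mri.membership)
        assert np.array_equal(subvols.hsv_fdg.membership, subvols.hsv_union.membership)

    def test_hsv_recovers_core_within_surface_layer(self, phantom_pipeline):
        from scipy import ndimage

        _, truth, subvols = phantom_pipeline
        core = truth.masks("fmiso")["hypoxic_core"].membership
        got = subvols.hsv_union.membership
        inner = ndimage.binary_erosion(core)
        outer = ndimage.binary_dilation(core)
        assert np.all(got >= inner)
        assert np.all(got <= outer)

    def test_no_core_means_all_hsv_empty(self):
        from scipy import ndimage

        cfg = cohort_config(seed=12, pet_noise_frac=0.0, core_radii_mm=(0.0, 0.0, 0.0))
        truth = build_phantom(cfg)
        suv_fdg = compute_suv(simulate_pet(truth, "FDG", noise_sd=0.0))
        suv_fmiso = compute_suv(simulate_pet(truth, "FMISO", noise_sd=0.0))
        search = ndimage.binary_dilation(
            truth.masks("fdg")["tumor_fdg_avid"].membership, iterations=3
        )
        subvols = build_subvolume_set(
            suv_fdg,
            suv_fmiso,
            truth.masks("t2")["tumor_mri"],
            truth.masks("fmiso")["muscle"],
            BinaryMask(suv_fdg.grid, search),
            fdg_to_fmiso=truth.inter_session_transform("fdg", "fmiso"),
            mri_to_fmiso=truth.inter_session_transform("t2", "fmiso"),
        )
        assert subvols.hsv_fdg.count == 0
        assert subvols.hsv_mri.count == 0
        assert subvols.hsv_union.count == 0
        assert np.array_equal(subvols.nsv_union.membership, subvols.tv_union.membership)

    def test_union_hsv_geq_components(self, phantom_pipeline):
        _, _, subvols = phantom_pipeline
        v = subvols.volumes_cm3()
        assert v["hsv_union"] >= max(v["hsv_fdg"], v["hsv_mri"]) - 1e-12
        assert v["hsv_union"] <= v["hsv_fdg"] + v["hsv_mri"] + 1e-12


class TestExtractReport:
    def test_uniform_map(self, phantom_pipeline):
        _, _, subvols = phantom_pipeline
        grid = subvols.tv_union.grid
        maps = {"x": ScalarVolume(grid, np.full(grid.shape, 7.0))}
        rep = extract_report(maps, subvols)
        for mask_name in rep.stats:
            st_ = rep.stats[mask_name]["x"]
            if st_.n_voxels:
                assert st_.mean == 7.0 and st_.max == 7.0

    def test_phantom_truth_means_same_grid(self, phantom_pipeline):
        # With masks aligned to the truth compartments on one grid, the means
        # are exactly the configured values: ADC 1.3e-3 in the hypoxic core,
        # 1.0e-3 in the normoxic tumor.
        cfg, truth, _ = phantom_pipeline
        m = truth.masks("dwi")
        tv = union(m["tumor_fdg_avid"], m["tumor_mri"])
        hsv = m["hypoxic_core"]
        nsv = exclude(tv, hsv)
        sset = SubvolumeSet(tv, tv, tv, hsv, hsv, hsv, nsv, nsv, nsv)
        adc_truth = truth.parameter_map("dwi", "adc")
        rep = extract_report({"adc": adc_truth}, sset)
        assert rep.stats["hsv_union"]["adc"].mean == pytest.approx(1.3e-3, rel=1e-12)
        assert rep.stats["nsv_union"]["adc"].mean == pytest.approx(1.0e-3, rel=1e-12)

    def test_phantom_pipeline_means_ordered(self, phantom_pipeline):
        # End-to-end (PET-grid masks propagated to the DWI grid) the hypoxic
        # mean is pulled toward the core value but dilution by a surface
        # layer of normoxic voxels is expected at the coarse PET resolution.
        cfg, truth, subvols = phantom_pipeline
        adc_truth = truth.parameter_map("dwi", "adc")
        transforms = {"adc": truth.inter_session_transform("fmiso", "dwi")}
        rep = extract_report({"adc": adc_truth}, subvols, transforms=transforms)
        hsv_mean = rep.stats["hsv_union"]["adc"].mean
        nsv_mean = rep.stats["nsv_union"]["adc"].mean
        assert 1.15e-3 < hsv_mean <= 1.3e-3 + 1e-12
        assert nsv_mean == pytest.approx(1.0e-3, rel=0.05)
        assert hsv_mean > nsv_mean

    def test_empty_mask_entries_absent(self):
        tv = mask_with_n(40)
        hsv = mask_with_n(0)
        nsv = exclude(tv, hsv)
        sset = SubvolumeSet(tv, tv, tv, hsv, hsv, hsv, nsv, nsv, nsv)
        maps = {"x": ScalarVolume(tv.grid, np.ones(tv.grid.shape))}
        rep = extract_report(maps, sset)
        assert rep.stats["hsv_union"]["x"].mean is None
        assert rep.stats["hsv_union"]["x"].n_voxels == 0
        assert rep.stats["nsv_union"]["x"].n_voxels == 40
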