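import numpy as np
import pytest

from bmupet import (
    BinaryMask,
    CutoffError,
    FocalConfig,
    classify_focal,
    compute_msau,
    compute_threshold,
    compute_tsau,
    extract_abnormal_region,
    remove_small_regions,
    tune_cutoff,
    watershed_basins,
)

from conftest import make_suv


class TestThreshold:
    def test_constant_marrow_gives_thr_equal_to_constant(self):
        suv = make_suv(np.full((4, 4, 4), 2.5))
        mask = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        assert compute_threshold(suv, mask) == pytest.approx(2.5)

    def test_population_sd_hand_arithmetic(self):
        # marrow SUVs {0, 2}: mean 1, population SD 1 -> THR = 3
        vals = np.zeros((2, 1, 1))
        vals[1] = 2.0
        suv = make_suv(vals)
        mask = BinaryMask(np.ones((2, 1, 1), bool), (1, 1, 1))
        assert compute_threshold(suv, mask) == pytest.approx(3.0)

    def test_empty_marrow_errors(self):
        suv = make_suv(np.ones((3, 3, 3)))
        mask = BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="threshold undefined"):
            compute_threshold(suv, mask)

    def test_gaussian_sampling_recovery(self):
        rng = np.random.default_rng(3)
        n = 22 ** 3
        vals = rng.normal(1.5, 0.2, (22, 22, 22)).clip(0)
        suv = make_suv(vals)
        mask = BinaryMask(np.ones((22, 22, 22), bool), (1, 1, 1))
        thr = compute_threshold(suv, mask)
        assert thr == pytest.approx(1.9, abs=3 * 0.2 / np.sqrt(n) * 3)


class TestMsauTsau:
    def test_msau_hand_arithmetic(self):
        vals = np.zeros((2, 1, 1))
        vals[0], vals[1] = 3.0, 5.0  # thr + 1, thr + 3 with thr = 2
        suv = make_suv(vals)
        mask = BinaryMask(np.ones((2, 1, 1), bool), (1, 1, 1))
        assert compute_msau(suv, 2.0, mask) == pytest.approx(5.0)

    def test_msau_empty_region_is_zero(self):
        suv = make_suv(np.ones((3, 3, 3)))
        mask = BinaryMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        assert compute_msau(suv, 0.5, mask) == 0.0

    def test_msau_matches_bruteforce_loop(self):
        rng = np.random.default_rng(11)
        vals = rng.gamma(2.0, 1.0, (6, 6, 6))
        suv = make_suv(vals)
        region = rng.random((6, 6, 6)) < 0.3
        mask = BinaryMask(region, (1, 1, 1))
        thr = 1.2
        acc = [
            (vals[i, j, k] - thr) ** 2
            for i, j, k in np.argwhere(region)
        ]
        assert compute_msau(suv, thr, mask) == pytest.approx(np.mean(acc), rel=1e-13)

    def test_tsau_is_product(self):
        assert compute_tsau(5.0, 2.0) == pytest.approx(10.0)
        assert compute_tsau(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            compute_tsau(-1.0, 2.0)

    def test_tsau_strictly_increases_with_abnormal_suv(self):
        rng = np.random.default_rng(5)
        vals = 2.0 + rng.random((5, 5, 5))
        region = np.zeros((5, 5, 5), bool)
        region[2, 2, 2] = region[2, 2, 3] = True
        mask = BinaryMask(region, (1, 1, 1))
        thr = 1.0
        t0 = compute_tsau(compute_msau(make_suv(vals), thr, mask), mask.volume_ml)
        vals2 = vals.copy()
        vals2[2, 2, 3] += 1.0
        t1 = compute_tsau(compute_msau(make_suv(vals2), thr, mask), mask.volume_ml)
        assert t1 > t0


class TestClassify:
    @pytest.mark.parametrize(
        "spine,other,expected",
        [
            (0.6, 0.0, True),    # spine above its 0.5 cut-off
            (0.0, 3.1, True),
            (0.5, 3.0, False),   # exactly at the cut-offs: strict comparison
            (0.0, 0.0, False),
        ],
    )
    def test_strict_cutoffs(self, spine, other, expected):
        assert classify_focal(spine, other) is expected


FOCUS_CENTER = (10, 8, 8)
NODE_CENTER = (22, 22, 22)


def spillover_scene():
    """A bone slab, a genuine in-bone focus and an out-of-bone hot node.

    The node's smooth skirt exceeds the threshold inside the bone; its
    intensity rises monotonically towards the node, so those voxels drain
    to a basin whose maximum lies outside the bone.  The two bumps are far
    apart, so every suprathreshold voxel is dominated by exactly one.
    """
    shape = (30, 30, 30)
    idx = np.indices(shape).astype(float)
    bone = (idx[0] >= 5) & (idx[0] <= 15)

    def bump(center, peak, sigma):
        d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        return peak * np.exp(-d2 / (2 * sigma ** 2))

    bump_focus = bump(FOCUS_CENTER, 5.0, 2.0)
    bump_node = bump(NODE_CENTER, 8.0, 4.0)
    vals = 1.0 + bump_focus + bump_node
    return make_suv(vals), BinaryMask(bone, (1, 1, 1)), bump_focus, bump_node


class TestAbnormalRegion:
    def test_no_voxel_above_threshold_gives_empty_mask(self):
        suv = make_suv(np.ones((4, 4, 4)))
        bone = BinaryMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        out = extract_abnormal_region(suv, bone, bone, thr=2.0)
        assert out.count == 0

    def test_candidates_above_threshold_strict(self):
        suv = make_suv(np.full((3, 3, 3), 2.0))
        bone = BinaryMask(np.ones((3, 3, 3), bool), (1, 1, 1))
        out = extract_abnormal_region(suv, bone, bone, thr=2.0, config=FocalConfig(min_region_ml=0))
        assert out.count == 0  # SUV == THR is not abnormal

    def test_spillover_basin_removed_in_bone_basin_kept(self):
        suv, bone, bump_focus, bump_node = spillover_scene()
        thr = 1.5
        cfg = FocalConfig(min_region_ml=0.0)
        out = extract_abnormal_region(suv, bone, bone, thr, cfg)
        candidates = bone.voxels & (suv.values > thr)
        focus_part = candidates & (bump_focus > bump_node)
        skirt = candidates & (bump_node > bump_focus)
        assert focus_part.any() and skirt.any(), "scene must produce both regions"
        # in-bone basin kept voxel-exact, out-of-bone basin fully removed
        np.testing.assert_array_equal(out.voxels, focus_part)

    def test_raising_threshold_never_enlarges_region(self):
        suv, bone, _, _ = spillover_scene()
        cfg = FocalConfig(min_region_ml=0.0)
        basins = watershed_basins(suv, cfg.connectivity)
        lo = extract_abnormal_region(suv, bone, bone, 1.5, cfg, basins)
        hi = extract_abnormal_region(suv, bone, bone, 2.0, cfg, basins)
        assert not (hi.voxels & ~lo.voxels).any()

    def test_size_filter_removes_small_components_and_is_idempotent(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:4, 2:4, 2:4] = True       # 8 voxels
        mask[10:15, 10:15, 10:15] = True  # 125 voxels
        spacing = (1.0, 1.0, 1.0)        # 1 voxel = 0.001 mL
        out = remove_small_regions(mask, spacing, min_region_ml=0.05)
        assert not out[2:4, 2:4, 2:4].any()
        assert out[10:15, 10:15, 10:15].all()
        np.testing.assert_array_equal(
            remove_small_regions(out, spacing, min_region_ml=0.05), out
        )


class TestScoreInvariants:
    def test_verdict_consistency_and_mask_contract(self, lesion_phantom, lesion_verdict):
        suv, labels, _ = lesion_phantom
        v = lesion_verdict
        cfg = FocalConfig()
        assert v.focal == (
            v.spine_score.tsau > cfg.cutoff_spine
            or v.other_score.tsau > cfg.cutoff_other
        )
        bone = labels.bone_mask().voxels
        for score in (v.spine_score, v.other_score):
            ab = score.abnormal_mask.voxels
            assert not (ab & ~bone).any()
            if ab.any():
                assert (suv.values[ab] > score.thr).all()
            assert score.tsau == pytest.approx(
                score.msau * score.abnormal_volume_ml, rel=1e-12
            )
            assert score.tsau >= 0


class TestTuneCutoff:
    def test_perfectly_separable_returns_midpoint(self):
        res = tune_cutoff([1, 2, 3, 4], [False, False, True, True],
                          ppv_target=1.0, npv_target=1.0)
        assert res.cutoff == pytest.approx(2.5)
        assert res.ppv == 1.0 and res.npv == 1.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        scores = np.round(rng.gamma(2.0, 1.5, 20), 3)
        labels = scores > 2.5
        labels[np.argmax(scores)] = False  # one mislabelled positive
        res = tune_cutoff(scores, labels, ppv_target=0.65, npv_target=0.5)

        # independent exhaustive scan over the same candidate family
        uniq = np.unique(scores)
        best = None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            pred = scores > c
            tp, fp = (pred & labels).sum(), (pred & ~labels).sum()
            tn, fn = (~pred & ~labels).sum(), (~pred & labels).sum()
            if tp + fp == 0 or tn + fn == 0:
                continue
            ppv, npv = tp / (tp + fp), tn / (tn + fn)
            if npv < 0.5:
                continue
            key = (abs(ppv - 0.65), -npv, c)
            if best is None or key < best[0]:
                best = (key, c, ppv, npv)
        assert res.cutoff == pytest.approx(best[1])
        assert res.ppv == pytest.approx(best[2])
        assert res.npv == pytest.approx(best[3])

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            tune_cutoff([1, 2, 3], [False, False, False])

    def test_unreachable_npv_reports_best_achievable(self):
        with pytest.raises(CutoffError) as exc:
            tune_cutoff([1, 2, 3, 4], [True, False, False, False],
                        ppv_target=0.65, npv_target=0.98)
        assert exc.value.best_npv == pytest.approx(2 / 3)
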