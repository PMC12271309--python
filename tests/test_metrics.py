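"""Accuracy metrics: worked examples, brute-force oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bodycomp import LabelVolume, classwise_metrics, dsc, hd95, iou, nsd, weighted_mean_dsc
from bodycomp.metrics import surface_mask


def brute_force_surface_distances(pred, ref, spacing):
    """All pairwise surface-voxel-centre distances, both directions (O(n^2))."""
    sp = np.asarray(spacing, dtype=float)
    p = np.argwhere(surface_mask(pred)) * sp
    r = np.argwhere(surface_mask(ref)) * sp
    d = np.sqrt(((p[:, None, :] - r[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1), d.min(axis=0)


def random_mask(seed, shape=(8, 9, 10), density=0.4):
    return np.random.default_rng(seed).random(shape) < density


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = random_mask(0)
        assert dsc(a, a) == 1.0
        assert iou(a, a) == 1.0
        b = np.zeros_like(a)
        b[0, 0, 0] = True
        c = np.zeros_like(a)
        c[1, 1, 1] = True
        assert dsc(b, c) == 0.0
        assert iou(b, c) == 0.0

    def test_half_overlap_hand_counted(self):
        a = np.zeros((4, 1, 4), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, :4] = True  # |A| = 4
        b[0, 0, 2:], b[1, 0, :2] = True, True  # |B| = 4, |A∩B| = 2
        assert dsc(a, b) == 0.5
        assert iou(a, b) == pytest.approx(1 / 3)  # via IOU = DSC/(2-DSC)

    def test_both_empty_convention(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        assert dsc(e, e) == 1.0 and iou(e, e) == 1.0

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dsc(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))

    @given(st.integers(0, 200))
    def test_iou_dsc_identity_on_random_masks(self, seed):
        a, b = random_mask(seed), random_mask(seed + 1000)
        d, j = dsc(a, b), iou(a, b)
        assert abs(j - d / (2.0 - d)) < 1e-12

    @given(st.integers(0, 50))
    def test_symmetry(self, seed):
        a, b = random_mask(seed), random_mask(seed + 500)
        assert dsc(a, b) == dsc(b, a)
        assert iou(a, b) == iou(b, a)


class TestBoundaryMetrics:
    def test_identical_masks(self):
        a = random_mask(3)
        a[0, 0, 0] = True
        assert hd95(a, a) == 0.0
        assert nsd(a, a, tau=0.5) == 1.0

    def test_shifted_strip_unit_distance(self):
        # disjoint parallel 1x1x40 strips one voxel apart: every surface
        # distance is exactly 1 mm
        a = np.zeros((4, 3, 44), dtype=bool)
        b = np.zeros_like(a)
        a[1, 1, 2:42] = True
        b[2, 1, 2:42] = True
        assert hd95(a, b, (1, 1, 1)) == pytest.approx(1.0)
        assert nsd(a, b, (1, 1, 1), tau=2.0) == 1.0

    def test_large_shift_low_nsd_matches_oracle(self):
        a = np.zeros((12, 3, 30), dtype=bool)
        b = np.zeros_like(a)
        a[1, 1, :] = True
        b[6, 1, :] = True  # 5-voxel shift
        d_pr, d_rp = brute_force_surface_distances(a, b, (1, 1, 1))
        expected = ((d_pr <= 2.0).sum() + (d_rp <= 2.0).sum()) / (d_pr.size + d_rp.size)
        got = nsd(a, b, (1, 1, 1), tau=2.0)
        assert got == pytest.approx(expected)
        assert got < 0.5

    def test_empty_mask_undefined(self):
        a = random_mask(4)
        a[0, 0, 0] = True
        empty = np.zeros_like(a)
        assert np.isnan(hd95(empty, a))
        assert np.isnan(nsd(empty, a))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_agreement_with_brute_force_oracle(self, seed):
        spacing = (1.46, 1.46, 4.0) if seed % 2 else (1.0, 1.0, 1.0)
        a = random_mask(seed, density=0.3)
        b = random_mask(seed + 77, density=0.3)
        d_pr, d_rp = brute_force_surface_distances(a, b, spacing)
        pooled = np.concatenate([d_pr, d_rp])
        assert hd95(a, b, spacing) == pytest.approx(np.percentile(pooled, 95), abs=1e-12)
        tau = 2.0
        expected_nsd = ((d_pr <= tau).sum() + (d_rp <= tau).sum()) / pooled.size
        assert nsd(a, b, spacing, tau) == pytest.approx(expected_nsd, abs=1e-12)

    def test_hd95_scales_with_isotropic_spacing_dsc_does_not(self):
        a, b = random_mask(9, density=0.3), random_mask(10, density=0.3)
        h1 = hd95(a, b, (1, 1, 1))
        h2 = hd95(a, b, (2, 2, 2))
        assert h2 == pytest.approx(2 * h1)
        assert dsc(a, b) == dsc(a, b)  # spacing plays no role in the overlap
        assert nsd(a, b, (2, 2, 2), tau=4.0) == pytest.approx(nsd(a, b, (1, 1, 1), tau=2.0))


class TestClasswise:
    def test_perfect_prediction(self, small_phantom):
        res = classwise_metrics(small_phantom, small_phantom)
        assert all(v == 1.0 for v in res.dsc.values())
        assert res.weighted_dsc == 1.0
        assert all(v == 0.0 for v in res.hd95.values())

    def test_matches_scalar_one_vs_rest(self, small_phantom, corrupted_raters):
        pred = corrupted_raters[2]
        res = classwise_metrics(pred, small_phantom)
        for lab in range(6):
            assert res.dsc[lab] == pytest.approx(
                dsc(pred.grid == lab, small_phantom.grid == lab)
            )

    def test_class_absent_in_both_flagged(self):
        grid = np.zeros((6, 6, 2), dtype=int)
        grid[2:4] = 2
        vol = LabelVolume(grid, (1, 1, 1))
        res = classwise_metrics(vol, vol)
        assert res.dsc[4] == 1.0
        assert res.flags[4] == "both-empty"


class TestWeightedMean:
    def test_constant_dsc_is_identity(self, small_phantom):
        per_class = {c: 0.7 for c in range(6)}
        assert weighted_mean_dsc(per_class, small_phantom) == pytest.approx(0.7)

    def test_hand_computed_weights(self):
        grid = np.zeros((10, 10, 1), dtype=int)
        grid.ravel()[:90] = 2  # 90 voxels SF
        grid.ravel()[90:100] = 3  # 10 voxels VF
        vol = LabelVolume(grid, (1, 1, 1))
        per_class = {0: 0.0, 1: 0.0, 2: 1.0, 3: 0.0, 4: 0.0, 5: 0.0}
        # background excluded; weights 0.9 / 0.1 over SF/VF
        assert weighted_mean_dsc(per_class, vol) == pytest.approx(0.9)

    def test_single_foreground_class(self):
        grid = np.zeros((4, 4, 1), dtype=int)
        grid[0] = 5
        vol = LabelVolume(grid, (1, 1, 1))
        per_class = {c: 0.0 for c in range(6)}
        per_class[5] = 0.42
        assert weighted_mean_dsc(per_class, vol) == pytest.approx(0.42)

    def test_all_background_reference_raises(self):
        vol = LabelVolume(np.zeros((3, 3, 3), dtype=int), (1, 1, 1))
        with pytest.raises(ValueError, match="background"):
            weighted_mean_dsc({c: 1.0 for c in range(6)}, vol)
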