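"""STAPLE EM: fixed points, closed-form E-step, recovery and cross-checks."""

import itertools

import numpy as np
import pytest

from bodycomp import RaterStack, dsc, reader_study, staple_binary, staple_multiclass
from bodycomp.consensus import compile_test_stack, e_step
from bodycomp.synthetic import CorruptionSpec, PhantomSpec, corrupt_segmentation, make_phantom


def bernoulli_rater(truth, p, q, rng):
    """Rater voting foreground w.p. p on truth, background w.p. q off truth."""
    return np.where(truth, rng.random(truth.shape) < p, rng.random(truth.shape) > q)


class TestEStep:
    def test_two_to_one_vote_closed_form(self):
        # 3 raters, one voxel, votes (1, 1, 0); p = q = 0.9, prior 0.5:
        # a = 0.5 * 0.9*0.9*0.1, b = 0.5 * 0.1*0.1*0.9  ->  W = 0.081/0.090 = 0.9
        Df = np.array([[1.0], [1.0], [0.0]])
        W, _ = e_step(Df, np.full(3, 0.9), np.full(3, 0.9), 0.5)
        assert W[0] == pytest.approx(0.9, abs=1e-12)


class TestBinaryStaple:
    def test_unanimity_fixed_point(self):
        rng = np.random.default_rng(0)
        mask = rng.random((20, 20, 5)) < 0.3
        W, perf = staple_binary([mask] * 4)
        assert np.array_equal(W >= 0.5, mask)
        assert np.all(perf.sensitivity > 0.999)
        assert np.all(perf.specificity > 0.999)

    def test_single_rater_returns_itself(self):
        rng = np.random.default_rng(1)
        mask = rng.random((15, 15, 4)) < 0.4
        W, _ = staple_binary([mask])
        assert np.array_equal(W >= 0.5, mask)

    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(2)
        truth = np.zeros((25, 25, 6), bool)
        truth[5:20, 5:20, 1:5] = True
        raters = [bernoulli_rater(truth, 0.9, 0.9, rng) for _ in range(5)]
        _, perf = staple_binary(raters)
        ll = perf.log_likelihood
        assert all(b >= a - 1e-7 * abs(a) for a, b in zip(ll, ll[1:]))

    def test_degenerate_stack_falls_back_to_majority(self):
        empty = np.zeros((5, 5, 2), bool)
        with pytest.warns(UserWarning, match="degenerate"):
            W, perf = staple_binary([empty, empty])
        assert not (W >= 0.5).any()
        assert np.isnan(perf.sensitivity).all()

    def test_matches_majority_vote_exhaustively(self):
        # raters with equal, symmetric performance (p = q) and prior 0.5:
        # the posterior weight exceeds 0.5 exactly where the majority votes
        # foreground, for every possible 3-rater stack over 4 voxels
        p = np.full(3, 0.9)
        for bits in itertools.product([0, 1], repeat=12):
            D = np.array(bits, dtype=float).reshape(3, 4)
            W, _ = e_step(D, p, p, 0.5)
            majority = D.sum(axis=0) >= 2
            assert np.array_equal(W >= 0.5, majority), bits

    def test_parameter_recovery_large_volume(self):
        rng = np.random.default_rng(7)
        truth = np.zeros((60, 60, 30), bool)  # 108k voxels
        truth[15:45, 15:45, 8:22] = True
        p_true = [0.95, 0.85, 0.90, 0.80, 0.92]
        q_true = [0.97, 0.90, 0.93, 0.88, 0.95]
        raters = [bernoulli_rater(truth, p, q, rng) for p, q in zip(p_true, q_true)]
        _, perf = staple_binary(raters)
        assert np.max(np.abs(perf.sensitivity - p_true)) < 0.03
        assert np.max(np.abs(perf.specificity - q_true)) < 0.03

    def test_agrees_with_simpleitk_reference(self):
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(0)
        truth = np.zeros((40, 40, 10), bool)
        truth[10:30, 10:30, 3:8] = True
        raters = [
            bernoulli_rater(truth, p, q, rng)
            for p, q in [(0.95, 0.97), (0.85, 0.9), (0.9, 0.93)]
        ]
        W, _ = staple_binary(raters)
        imgs = [
            sitk.GetImageFromArray(np.ascontiguousarray(r.transpose(2, 1, 0)).astype(np.uint8))
            for r in raters
        ]
        ref = sitk.GetArrayFromImage(sitk.STAPLE(imgs, 1.0)).transpose(2, 1, 0) >= 0.5
        assert ((W >= 0.5) == ref).mean() == 1.0


class TestMulticlass:
    def test_unanimous_stack_reproduced(self, small_phantom):
        stack = RaterStack([small_phantom] * 3)
        consensus, _ = staple_multiclass(stack)
        np.testing.assert_array_equal(consensus.grid, small_phantom.grid)

    def test_rater_permutation_invariance(self, small_phantom, corrupted_raters):
        c1, _ = staple_multiclass(RaterStack(corrupted_raters))
        c2, _ = staple_multiclass(RaterStack(corrupted_raters[::-1]))
        np.testing.assert_array_equal(c1.grid, c2.grid)

    def test_consensus_beats_best_single_rater(self, small_phantom):
        # per-class DSC vs truth: STAPLE of 9 raters >= best individual
        wins = 0
        trials = 0
        for seed in range(5):
            raters = [
                corrupt_segmentation(
                    small_phantom,
                    CorruptionSpec(displacement_mm=2.0, seed=1000 * seed + j),
                )
                for j in range(9)
            ]
            consensus, _ = staple_multiclass(RaterStack(raters))
            for lab in (2, 3, 4, 5):
                truth_mask = small_phantom.grid == lab
                best = max(dsc(r.grid == lab, truth_mask) for r in raters)
                cons = dsc(consensus.grid == lab, truth_mask)
                wins += cons >= best - 1e-9
                trials += 1
        assert wins == trials


class TestReaderStudy:
    def test_consensus_copy_ranks_first(self, corrupted_raters):
        stack = RaterStack(corrupted_raters)
        consensus, _ = staple_multiclass(stack)
        df = reader_study(stack, model_outputs=[consensus], model_ids=["MX"])
        top = df.iloc[0]
        assert top["id"] == "MX"
        assert top["weighted_dsc"] == pytest.approx(1.0)
        assert top["rank"] == 1

    def test_ranking_follows_corruption_level(self, small_phantom):
        good_order = 0
        n_seeds = 6
        levels = [0.5, 1.5, 3.0, 5.0]
        for seed in range(n_seeds):
            raters = [
                corrupt_segmentation(
                    small_phantom,
                    CorruptionSpec(displacement_mm=d, seed=500 * seed + j),
                )
                for j, d in enumerate(levels)
            ]
            df = reader_study(RaterStack(raters, [f"R{j}" for j in range(4)]))
            good_order += list(df["id"]) == ["R0", "R1", "R2", "R3"]
        assert good_order >= n_seeds - 1

    def test_stack_compilation_five_by_five(self):
        vols = [make_phantom(PhantomSpec(n_slices=25 + k)) for k in range(5)]
        stack = compile_test_stack(vols, slices_per_volume=5)
        assert stack.grid.shape[2] == 25
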