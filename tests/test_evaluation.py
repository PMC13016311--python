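"""Evaluation battery: Dice, ARI, harmonization, group maps, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fodparc import (
    DegenerateInputError,
    ShapeMismatchError,
    adjusted_rand_index,
    coefficient_of_variation,
    consistency_metrics,
    consistency_summary,
    dice,
    dice_confusion,
    group_maps,
    harmonize_labels,
    max_dice_match,
    wilcoxon_compare,
)


def pair_counting_ari(p, q):
    """Oracle: ARI from explicit enumeration of all voxel pairs."""
    p, q = np.asarray(p), np.asarray(q)
    n = p.size
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_p, same_q = p[i] == p[j], q[i] == q[j]
            ss += same_p and same_q
            sd += same_p and not same_q
            ds += not same_p and same_q
            dd += not same_p and not same_q
    a, b = ss + sd, ss + ds
    total = ss + sd + ds + dd
    expected = a * b / total
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


class TestDice:
    def test_identical_sets(self):
        a = np.zeros((4, 4, 4), bool)
        a[1:3, 1:3, 1:3] = True
        assert dice(a, a) == 1.0

    def test_disjoint_sets(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[:4] = True
        b[2:6] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_both_empty_is_zero(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestDiceConfusion:
    def test_identical_labelings_give_identity_pattern(self):
        vol = np.zeros((6, 6, 6), dtype=int)
        vol[:3] = 1
        vol[3:, :, :3] = 2
        vol[3:, :, 3:] = 3
        dm = dice_confusion(vol, vol)
        np.testing.assert_allclose(dm.values, np.eye(3))

    def test_cluster_spanning_two_nuclei(self):
        atlas = np.zeros((4, 4, 4), dtype=int)
        atlas[:2, 0, 0] = 1
        atlas[2:, 0, 0] = 2  # two nuclei of 2 voxels each
        parc = np.zeros((4, 4, 4), dtype=int)
        parc[:, 0, 0] = 1  # one cluster covering both
        dm = dice_confusion(parc, atlas)
        np.testing.assert_allclose(dm.values, [[2 / 3], [2 / 3]])

    def test_matches_per_pair_brute_force(self, rng):
        parc = rng.integers(0, 4, size=(5, 5, 5))
        atlas = rng.integers(0, 3, size=(5, 5, 5))
        dm = dice_confusion(parc, atlas)
        for i, al in enumerate(dm.atlas_labels):
            for j, cl in enumerate(dm.cluster_labels):
                assert dm.values[i, j] == pytest.approx(dice(atlas == al, parc == cl))


class TestMaxDiceMatch:
    def test_row_argmax(self):
        from fodparc.evaluation import DiceMatrix

        dm = DiceMatrix(np.array([[0.1, 0.7, 0.2]]), np.array([5]), np.array([1, 2, 3]))
        assert max_dice_match(dm) == {5: (2, 0.7)}

    def test_tie_breaks_to_lowest_cluster_id(self):
        from fodparc.evaluation import DiceMatrix

        dm = DiceMatrix(np.array([[0.5, 0.5]]), np.array([1]), np.array([1, 2]))
        assert max_dice_match(dm)[1] == (1, 0.5)

    def test_matches_enumeration(self, rng):
        from fodparc.evaluation import DiceMatrix

        vals = rng.random((3, 3))
        dm = DiceMatrix(vals, np.arange(1, 4), np.arange(1, 4))
        got = max_dice_match(dm)
        for i in range(3):
            best = max(range(3), key=lambda j: (vals[i, j], -j))
            assert got[i + 1] == (best + 1, pytest.approx(vals[i, best]))


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        p = np.array([1, 1, 2, 2, 3])
        assert adjusted_rand_index(p, p) == 1.0

    def test_label_permutation_invariance(self):
        p = np.array([1, 1, 2, 2, 3, 3])
        q = np.array([3, 3, 1, 1, 2, 2])
        assert adjusted_rand_index(p, q) == 1.0

    def test_hand_enumerated_pair_counting(self):
        p = np.array([1, 1, 2, 2])
        q = np.array([1, 2, 1, 2])
        assert adjusted_rand_index(p, q) == pytest.approx(pair_counting_ari(p, q))

    def test_matches_pair_counting_on_random_partitions(self, rng):
        for _ in range(5):
            p = rng.integers(0, 3, size=12)
            q = rng.integers(0, 4, size=12)
            assert adjusted_rand_index(p, q) == pytest.approx(pair_counting_ari(p, q))

    def test_independent_partitions_concentrate_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [
            adjusted_rand_index(rng.integers(0, 4, 1000), rng.integers(0, 4, 1000))
            for _ in range(100)
        ]
        assert abs(np.mean(vals)) < 0.05


class TestHarmonize:
    def _volume(self):
        vol = np.zeros((6, 6, 6), dtype=np.int16)
        vol[:3] = 1
        vol[3:, :3] = 2
        vol[3:, 3:] = 3
        return vol

    def test_permuted_labels_recover_reference(self):
        ref = self._volume()
        permuted = np.zeros_like(ref)
        for src, dst in [(1, 3), (2, 1), (3, 2)]:
            permuted[ref == src] = dst
        out = harmonize_labels([permuted], reference=ref)
        np.testing.assert_array_equal(out[0].labels, ref)

    def test_identity_assignment(self):
        ref = self._volume()
        out = harmonize_labels([ref.copy()], reference=ref)
        np.testing.assert_array_equal(out[0].labels, ref)

    def test_matches_exhaustive_permutation_search(self, rng):
        # oracle: best one-to-one relabeling over all 3! permutations,
        # scored by summed Dice against the reference
        ref = self._volume()
        subj = self._volume()
        noise = rng.random(ref.shape) < 0.2
        subj[noise] = rng.integers(1, 4, size=int(noise.sum()))
        subj[ref == 0] = 0
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations([1, 2, 3]):
            score = sum(dice(subj == src, ref == dst)
                        for src, dst in zip([1, 2, 3], perm))
            if score > best_score:
                best_score, best_perm = score, perm
        out = harmonize_labels([subj], reference=ref)[0].labels
        expected = np.zeros_like(subj)
        for src, dst in zip([1, 2, 3], best_perm):
            expected[subj == src] = dst
        np.testing.assert_array_equal(out, expected)

    def test_partition_is_unchanged(self, rng):
        ref = self._volume()
        subj = rng.integers(0, 4, size=ref.shape).astype(np.int16)
        subj[ref == 0] = 0
        if not np.any(subj > 0):
            subj[0, 0, 0] = 1
        out = harmonize_labels([subj], reference=ref)[0].labels
        sel = (subj > 0) | (out > 0)
        assert adjusted_rand_index(subj[sel], out[sel]) == 1.0


class TestGroupMaps:
    def test_single_subject_frequencies_are_binary(self):
        vol = np.zeros((4, 4, 4), dtype=int)
        vol[:2] = 1
        vol[2:] = 2
        gm = group_maps([vol])
        assert set(np.unique(gm.prob)) <= {0.0, 1.0}
        np.testing.assert_array_equal(gm.maxprob, vol)

    def test_full_agreement_survives_threshold(self):
        vol = np.zeros((4, 4, 4), dtype=int)
        vol[:2] = 1
        vol[2:] = 2
        gm = group_maps([vol, vol.copy()], threshold=0.5)
        np.testing.assert_array_equal(gm.thresholded, vol)

    def test_vote_counting_example(self):
        # four subjects label one voxel (1, 1, 2, 3)
        vols = []
        for lab in (1, 1, 2, 3):
            v = np.zeros((1, 1, 1), dtype=int)
            v[0, 0, 0] = lab
            vols.append(v)
        gm = group_maps(vols, threshold=0.5)
        np.testing.assert_allclose(gm.prob[0, 0, 0], [0.5, 0.25, 0.25])
        assert gm.maxprob[0, 0, 0] == 1
        assert gm.thresholded[0, 0, 0] == 1

    def test_frequency_mass_equals_coverage(self, rng):
        vols = [rng.integers(0, 4, size=(6, 6, 6)) for _ in range(10)]
        gm = group_maps(vols)
        total = gm.prob.sum(axis=-1)
        coverage = np.mean([v > 0 for v in vols], axis=0)
        np.testing.assert_allclose(total, coverage, atol=1e-12)
        assert total.max() <= 1.0 + 1e-12


class TestConsistency:
    def test_single_cluster_covers_mask(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        parc = np.where(mask, 1, 0)
        df = consistency_metrics(parc, mask, affine=np.eye(4))
        assert df.loc[1, "volume_ratio"] == pytest.approx(1.0)

    def test_cube_centroid_boundary_distance(self):
        # 3x3x3 cube, 1 mm voxels: the central voxel is 2 mm from the
        # nearest background voxel centre (hand-computed EDT)
        mask = np.zeros((3, 3, 3), bool)
        mask[:] = True
        parc = np.ones((3, 3, 3), dtype=int)
        df = consistency_metrics(parc, mask, affine=np.eye(4))
        assert df.loc[1, "centroid_boundary_distance_mm"] == pytest.approx(2.0)

    def test_equal_split_ratios(self):
        mask = np.ones((4, 4, 4), bool)
        parc = np.ones((4, 4, 4), dtype=int)
        parc[2:] = 2
        df = consistency_metrics(parc, mask, affine=np.eye(4))
        assert df["volume_ratio"].tolist() == pytest.approx([0.5, 0.5])

    def test_missing_cluster_reported_as_nan(self):
        mask = np.ones((3, 3, 3), bool)
        parc = np.ones((3, 3, 3), dtype=int)
        df = consistency_metrics(parc, mask, affine=np.eye(4), labels=[1, 2])
        assert np.isnan(df.loc[2, "volume_ratio"])

    def test_affine_scales_distance_to_mm(self):
        mask = np.ones((3, 3, 3), bool)
        parc = np.ones((3, 3, 3), dtype=int)
        df = consistency_metrics(parc, mask, affine=np.diag([1.25, 1.25, 1.25, 1.0]))
        assert df.loc[1, "centroid_boundary_distance_mm"] == pytest.approx(2.5)

    def test_summary_reports_cv(self):
        frames = []
        for ratio in (0.4, 0.5, 0.6):
            frames.append(
                pd.DataFrame(
                    {"label": [1], "volume_ratio": [ratio],
                     "centroid_boundary_distance_mm": [2.0]}
                ).set_index("label")
            )
        out = consistency_summary(frames)
        expected_cv = np.std([0.4, 0.5, 0.6], ddof=1) / 0.5
        assert out.loc[1, "volume_ratio_cv"] == pytest.approx(expected_cv)
        assert out.loc[1, "centroid_boundary_distance_mm_cv"] == pytest.approx(0.0)


class TestWilcoxon:
    def test_uniform_shift_gives_zero_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        stat, p = wilcoxon_compare(a, a + 1.0)
        assert stat == 0.0
        assert p < 0.05

    def test_identical_scores_undefined(self):
        a = np.arange(6, dtype=float)
        with pytest.raises(DegenerateInputError):
            wilcoxon_compare(a, a)

    def test_statistic_matches_manual_ranking(self):
        # oracle: midrank |differences|, sum ranks of each sign, statistic
        # is the smaller sum (here: |d| = 1,2,4,1,5,1.5 -> tied 1s get 1.5)
        a = np.array([10.0, 12.0, 9.0, 15.0, 11.0, 8.0])
        b = np.array([11.0, 10.0, 13.0, 14.0, 16.0, 9.5])
        d = b - a
        ranks = np.array([1.5, 4.0, 5.0, 1.5, 6.0, 3.0])
        w_pos = ranks[d > 0].sum()
        w_neg = ranks[d < 0].sum()
        stat, _ = wilcoxon_compare(a, b)
        assert stat == pytest.approx(min(w_pos, w_neg)) == 5.5


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_two_point_formula(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_matches_direct_recomputation(self, rng):
        v = rng.uniform(1, 5, size=20)
        assert coefficient_of_variation(v) == pytest.approx(np.std(v, ddof=1) / np.mean(v))

    def test_zero_mean_undefined(self):
        with pytest.raises(DegenerateInputError):
            coefficient_of_variation([-1.0, 1.0])
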