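"""Projection-quality metrics, precision/recall, ARI, motif KL divergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import modscape as m
from modscape.clustering import ClusterAssignment
from modscape.motifs import PWM

FOUR_POINTS = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0], [14.0, 0.0]])
FOUR_LABELS = np.array(["A", "A", "B", "B"])


class TestOutgroupIngroupScore:
    def test_hand_evaluated_example(self):
        """Ingroup dists {1,1,2,2}, outgroup {12,10,9,13} -> approx 0.4312."""
        report = m.outgroup_ingroup_score(FOUR_POINTS, FOUR_LABELS)
        assert report.score == pytest.approx(0.43122, abs=1e-4)

    @pytest.mark.parametrize("scale", [10.0, 0.01])
    def test_scale_invariance(self, scale):
        base = m.outgroup_ingroup_score(FOUR_POINTS, FOUR_LABELS).score
        scaled = m.outgroup_ingroup_score(FOUR_POINTS * scale, FOUR_LABELS).score
        assert scaled == pytest.approx(base, rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-3.14, 3.14), st.floats(-50, 50), st.floats(-50, 50))
    def test_similarity_transform_invariance(self, theta, dx, dy):
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = FOUR_POINTS @ rot.T + np.array([dx, dy])
        base = m.outgroup_ingroup_score(FOUR_POINTS, FOUR_LABELS).score
        assert m.outgroup_ingroup_score(moved, FOUR_LABELS).score == \
            pytest.approx(base, rel=1e-9)

    def test_single_point_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            m.outgroup_ingroup_score(FOUR_POINTS[:3],
                                     np.array(["A", "A", "B"]))

    def test_degenerate_geometry_rejected(self):
        coincident = np.array([[0, 0], [0, 0], [5, 5], [5, 5]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            m.outgroup_ingroup_score(coincident, FOUR_LABELS)


class TestBoundaryScore:
    def _blobs(self, gap, n=100, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 0.5, (n, 2)),
                         rng.normal(gap, 0.5, (n, 2))])
        return pts, np.array([0] * n + [1] * n)

    def test_separated_blobs_score_zero(self):
        pts, labels = self._blobs(gap=100)
        assert m.boundary_score(pts, labels, k=50).score == 0.0

    def test_shuffled_labels_score_near_one(self):
        pts, labels = self._blobs(gap=100)
        shuffled = np.random.default_rng(1).permutation(labels)
        assert m.boundary_score(pts, shuffled, k=50).score > 0.9

    def test_monotone_as_groups_separate(self):
        scores = []
        for gap in [0.5, 2.0, 8.0, 100.0]:
            pts, labels = self._blobs(gap=gap)
            scores.append(m.boundary_score(pts, labels, k=50).score)
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_n_not_larger_than_k_rejected(self):
        pts, labels = self._blobs(gap=1, n=20)
        with pytest.raises(ValueError, match="more than k"):
            m.boundary_score(pts, labels, k=50)


class TestPrecisionRecall:
    def test_perfect_partition(self):
        truth = np.array(["A"] * 5 + ["B"] * 3)
        assign = ClusterAssignment(np.array([0] * 5 + [1] * 3), "stub")
        table = m.precision_recall(assign, truth)
        assert (table["precision"] == 1.0).all()
        assert (table["recall"] == 1.0).all()

    def test_majority_counting(self):
        """Cluster of 10 with 9 class-A (A total 9): precision 0.9, recall 1."""
        truth = np.array(["A"] * 9 + ["B"])
        assign = ClusterAssignment(np.zeros(10, dtype=int), "stub")
        row = m.precision_recall(assign, truth).iloc[0]
        assert row["precision"] == pytest.approx(0.9)
        assert row["recall"] == pytest.approx(1.0)

    def test_all_noise_gives_zero_recall(self):
        truth = np.array(["A", "A", "B"])
        assign = ClusterAssignment(np.full(3, -1), "stub")
        table = m.per_class_precision_recall(assign, truth)
        assert (table["recall"] == 0.0).all()

    def test_truth_must_cover_records(self):
        assign = ClusterAssignment(np.array([0, 0, 1]), "stub")
        with pytest.raises(ValueError, match="cover"):
            m.precision_recall(assign, np.array(["A", "B"]))


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        assert m.adjusted_rand_index([0, 1, 1, 2], [0, 1, 1, 2]) == 1.0

    def test_contingency_example(self):
        assert m.adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 2]) == \
            pytest.approx(4 / 7)

    def test_singletons_vs_one_cluster(self):
        assert m.adjusted_rand_index([0, 0, 0, 0], [0, 1, 2, 3]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            m.adjusted_rand_index([0, 1], [0, 1, 2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=5, max_size=40),
           st.integers(0, 100))
    def test_matches_reference_and_is_symmetric(self, a, seed):
        """Cross-check the contingency-table formula against scikit-learn."""
        from sklearn.metrics import adjusted_rand_score

        b = list(np.random.default_rng(seed).integers(0, 3, size=len(a)))
        ours = m.adjusted_rand_index(a, b)
        assert ours == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)
        assert ours == pytest.approx(m.adjusted_rand_index(b, a), abs=1e-12)

    def test_invariant_to_label_renaming(self):
        a, b = [0, 0, 1, 2, 2], [1, 1, 0, 2, 2]
        renamed = [{0: 7, 1: 3, 2: 5}[x] for x in a]
        assert m.adjusted_rand_index(a, b) == \
            pytest.approx(m.adjusted_rand_index(renamed, b))


class TestMotifKLDivergence:
    def test_identical_pwms_give_zero(self):
        pwm = PWM.from_probs(np.tile([0.1, 0.2, 0.3, 0.4], (5, 1)))
        assert m.motif_kl_divergence(pwm, pwm) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_position(self):
        """p=(1,0,0,0) vs uniform, pseudocount 0.01 -> 2.4008 bits."""
        p = PWM.from_probs(np.array([[1.0, 0.0, 0.0, 0.0]]))
        q = PWM.from_probs(np.array([[0.25, 0.25, 0.25, 0.25]]))
        assert m.motif_kl_divergence(p, q, pseudocount=0.01) == \
            pytest.approx(2.4007974096, abs=1e-9)

    def test_length_mismatch_rejected(self):
        a = PWM.from_probs(np.full((5, 4), 0.25))
        b = PWM.from_probs(np.full((6, 4), 0.25))
        with pytest.raises(ValueError, match="lengths"):
            m.motif_kl_divergence(a, b)

    def test_zero_probability_without_pseudocount_rejected(self):
        p = PWM.from_probs(np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            m.motif_kl_divergence(p, p, pseudocount=0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_symmetric_and_nonnegative(self, s1, s2):
        rng1 = np.random.default_rng(s1)
        rng2 = np.random.default_rng(s2)
        a = PWM.from_probs(rng1.dirichlet(np.ones(4), size=4))
        b = PWM.from_probs(rng2.dirichlet(np.ones(4), size=4))
        d_ab = m.motif_kl_divergence(a, b)
        d_ba = m.motif_kl_divergence(b, a)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)
        assert d_ab >= 0.0
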