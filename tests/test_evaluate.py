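"""ROC/AUC, balanced-error threshold selection, binned AUC, summaries."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from phagesieve.ani import AniResult
from phagesieve.evaluate import auc_by_length, roc_auc, summarize_dataset


def pairwise_auc(scores, labels):
    """Brute-force Mann-Whitney estimator: P(pos > neg) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        s = roc_auc([9.0, 8.0, 1.0, 0.5], ["phage", "phage", "negative", "negative"])
        assert s.auc == 1.0

    def test_labels_independent_of_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_hand_listed_pairs_match_pairwise_estimator(self):
        scores = [5, 4, 4, 3.5, 3, 3, 3, 2, 1.5, 1, 1, 0]
        labels = [1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0]
        s = roc_auc(scores, labels)
        assert s.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert s.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_mann_whitney_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        scores = rng.integers(0, 8, size=n).astype(float)  # many ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        s = roc_auc(scores, labels)
        assert s.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert s.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(4)
        s = roc_auc(rng.normal(size=100), rng.random(100) < 0.4)
        assert s.fpr[0] == s.tpr[0] == 0.0
        assert s.fpr[-1] == s.tpr[-1] == 1.0
        assert np.all(np.diff(s.fpr) >= 0) and np.all(np.diff(s.tpr) >= 0)
        assert np.all(np.diff(s.thresholds) < 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], ["phage", "phage"])

    def test_pooled_evaluation_is_order_invariant(self):
        # pooling partitions == evaluating the concatenated score list
        rng = np.random.default_rng(9)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        perm = rng.permutation(200)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc(scores[perm], labels[perm]).auc, abs=1e-12
        )


class TestSelectThreshold:
    def test_hand_enumerated_operating_points(self):
        # pos {3, 2}, neg {1, 0}: crossing at the (tpr=1, fpr=0) point,
        # whose cutoff interval is [1, 2) -> midpoint 1.5
        s = roc_auc([3, 2, 1, 0], [1, 1, 0, 0])
        assert s.selected_threshold == pytest.approx(1.5)

    def test_perfect_separation_returns_gap_midpoint(self):
        s = roc_auc([10, 8, 2, 1], [1, 1, 0, 0])
        assert s.selected_threshold == pytest.approx(5.0)

    def test_symmetric_gaussians_converge_to_midpoint(self):
        rng = np.random.default_rng(17)
        pos = rng.normal(6.0, 1.0, 4000)
        neg = rng.normal(2.0, 1.0, 4000)
        s = roc_auc(np.r_[pos, neg], np.r_[np.ones(4000), np.zeros(4000)])
        assert s.selected_threshold == pytest.approx(4.0, abs=0.2)

    def test_class_swap_score_negation_symmetry(self):
        rng = np.random.default_rng(23)
        scores = np.r_[rng.normal(3, 1, 300), rng.normal(0, 1, 300)]
        labels = np.r_[np.ones(300), np.zeros(300)].astype(bool)
        t = roc_auc(scores, labels).selected_threshold
        t_swapped = roc_auc(-scores, ~labels).selected_threshold
        assert t == pytest.approx(-t_swapped, abs=1e-9)

    def test_balanced_error_residual_within_resolution(self):
        rng = np.random.default_rng(31)
        scores = np.r_[rng.normal(1.5, 1, 150), rng.normal(0, 1, 200)]
        labels = np.r_[np.ones(150), np.zeros(200)].astype(bool)
        s = roc_auc(scores, labels)
        t = s.selected_threshold
        tpr = (scores[labels] > t).mean()
        fpr = (scores[~labels] > t).mean()
        resolution = max(1 / 150, 1 / 200)
        assert abs(fpr - (1 - tpr)) <= resolution + 1e-12

    def test_all_ties_degenerate_returns_single_score(self):
        s = roc_auc([2.0, 2.0], [1, 0])
        assert s.selected_threshold == 2.0


class TestAucByLength:
    def test_one_bin_equals_pooled(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.5
        lengths = rng.integers(500, 5000, 100)
        table = auc_by_length(scores, labels, lengths, [0, 10_000])
        assert len(table) == 1
        assert table.loc[0, "auc"] == pytest.approx(roc_auc(scores, labels).auc)

    def test_edge_record_goes_to_right_hand_bin(self):
        table = auc_by_length(
            [1.0, 0.0, 1.0, 0.0],
            [1, 0, 1, 0],
            [999, 998, 1000, 1001],  # 1000 sits exactly on the edge
            [0, 1000, 2000],
        )
        assert table.loc[0, "n_pos"] + table.loc[0, "n_neg"] == 2
        assert table.loc[1, "n_pos"] + table.loc[1, "n_neg"] == 2

    def test_single_class_bin_is_nan_not_error(self):
        table = auc_by_length([1.0, 2.0, 0.5], [1, 1, 0], [100, 150, 1500],
                              [0, 1000, 2000])
        assert np.isnan(table.loc[0, "auc"])
        assert np.isnan(table.loc[1, "auc"])

    def test_noisier_short_fragments_lower_auc(self):
        """Per-bin AUC rises with length when score noise shrinks with
        length — the qualitative short-contig accuracy drop."""
        rng = np.random.default_rng(8)
        n = 600
        labels = np.r_[np.ones(n), np.zeros(n)].astype(bool)
        lengths = np.tile(np.r_[np.full(n // 2, 1000), np.full(n // 2, 20_000)], 2)
        noise_sd = np.where(lengths < 5000, 3.0, 0.4)
        scores = labels * 2.0 + rng.normal(0, 1, 2 * n) * noise_sd
        table = auc_by_length(scores, labels, lengths, [500, 5000, 50_000])
        assert table.loc[1, "auc"] > table.loc[0, "auc"]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            auc_by_length([1.0], [1], [100], [1000, 500])


def _result(qid, ani, cov, n_subj, length=1000):
    return AniResult(
        query_id=qid, query_length=length, pct_ani=ani, merged_coverage=cov,
        n_subjects=n_subj, n_alignments=n_subj, is_phage=ani > 1.7,
    )


class TestSummarizeDataset:
    def test_hand_computed_row(self):
        results = [
            _result("a", 60.0, 0.8, 2),
            _result("b", 40.0, 0.6, 4),
            _result("c", 1.0, 0.01, 1),
            _result("d", 0.0, 0.0, 0),
        ]
        labels = ["phage", "phage", "negative", "negative"]
        row = summarize_dataset(results, labels, threshold=1.7)
        assert row["mean_n_hits"] == pytest.approx((2 + 4 + 1 + 0) / 4)
        assert row["median_n_hits"] == pytest.approx(1.5)
        assert row["mean_pct_ani"] == pytest.approx((60 + 40 + 1 + 0) / 4)
        assert row["median_pct_ani"] == pytest.approx(20.5)
        assert row["mean_merged_coverage"] == pytest.approx(1.41 / 4)
        assert row["sensitivity"] == 1.0  # both positives above 1.7
        assert row["specificity"] == 1.0  # both negatives at or below 1.7

    def test_mean_median_of_two(self):
        row = summarize_dataset(
            [_result("a", 5.0, 0.1, 2), _result("b", 5.0, 0.1, 4)],
            ["phage", "phage"],
        )
        assert row["mean_n_hits"] == 3.0 and row["median_n_hits"] == 3.0
        assert row["specificity"] is None

    def test_sensitivity_counts_misses(self):
        row = summarize_dataset(
            [_result("a", 5.0, 0.1, 1), _result("b", 1.0, 0.01, 1)],
            ["phage", "phage"],
        )
        assert row["sensitivity"] == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_dataset([], [])
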