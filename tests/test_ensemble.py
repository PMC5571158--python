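"""Consensus schemes, thresholds, rank aggregation and ROC analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from premirscan import ensemble as en
from premirscan.simulate import FixtureSpec, make_separable_features
from premirscan.training import SplitSpec


class TestConsensusVote:
    @pytest.mark.parametrize("n_yes,label",
                             [(13, "miRNA"), (7, "miRNA"), (6, "negative"),
                              (0, "negative")])
    def test_majority_boundary(self, n_yes, label):
        votes = [1] * n_yes + [0] * (13 - n_yes)
        assert en.consensus_vote(votes) == label

    def test_missing_votes_rejected(self):
        with pytest.raises(ValueError, match="one vote per study"):
            en.consensus_vote([1] * 12)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            en.consensus_vote([0.5] + [0] * 12)

    def test_exhaustive_agreement_with_counting_rule(self):
        # brute force over all 2^13 vote vectors
        for bits in itertools.product((0, 1), repeat=13):
            expected = "miRNA" if sum(bits) >= 7 else "negative"
            assert en.consensus_vote(list(bits)) == expected


class TestAveragePredict:
    @pytest.mark.parametrize("scores,avg,label",
                             [([0.4], 0.4, "negative"),
                              ([0.6], 0.6, "miRNA"),
                              ([0.4, 0.6], 0.5, "miRNA")])  # equality -> miRNA
    def test_rule(self, scores, avg, label):
        a, lab = en.average_predict(scores)
        assert a == pytest.approx(avg) and lab == label

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            en.average_predict([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            en.average_predict([1.2])


class TestConsensusRule:
    @pytest.mark.parametrize("dt,nb,label",
                             [(0.95, 0.20, "miRNA"),  # miRNA clause precedence
                              (0.30, 0.30, "negative"),
                              (0.70, 0.70, "candidate"),
                              (0.89, 0.89, "candidate"),  # strict >
                              (0.5, 0.5, "candidate"),  # strict <
                              (0.90, 0.70, "miRNA"),
                              (0.70, 0.40, "negative")])
    def test_decision(self, dt, nb, label):
        assert en.consensus_rule(dt, nb).label == label

    def test_conflict_flagged(self):
        d = en.consensus_rule(0.95, 0.20)
        assert d.label == "miRNA" and d.rule_conflict
        assert not en.consensus_rule(0.95, 0.95).rule_conflict

    def test_totality_on_grid(self):
        # every point of [0,1]^2 at 0.01 resolution maps to exactly one label
        grid = np.round(np.arange(0, 1.0001, 0.01), 2)
        labels = {en.consensus_rule(a, b).label for a in grid for b in grid}
        assert labels == {"miRNA", "negative", "candidate"}

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            en.consensus_rule(1.1, 0.5)


@pytest.fixture(scope="module")
def score_clouds():
    # synthetic per-study score vectors: positives high, negatives low
    rng = np.random.default_rng(21)
    pos = np.clip(rng.normal(0.85, 0.08, size=(150, 13)), 0, 1)
    neg = np.clip(rng.normal(0.25, 0.08, size=(150, 13)), 0, 1)
    cols = [f"study_{i}" for i in range(13)]
    X = pd.DataFrame(np.vstack([pos, neg]), columns=cols)
    y = np.r_[np.ones(150), np.zeros(150)]
    return X, y


class TestConsensusModel:
    def test_separable_scores_learned(self, score_clouds):
        X, y = score_clouds
        meta = en.consensus_model_train(X, y, SplitSpec(iterations=5, seed=1))
        assert meta.best_metrics.accuracy >= 0.95
        preds = en.consensus_model_predict(meta, X)
        assert np.all((preds >= 0) & (preds <= 1))

    def test_deterministic(self, score_clouds):
        X, y = score_clouds
        a = en.consensus_model_train(X, y, SplitSpec(iterations=3, seed=1))
        b = en.consensus_model_train(X, y, SplitSpec(iterations=3, seed=1))
        assert a.best_iteration == b.best_iteration
        assert a.best_metrics == b.best_metrics

    def test_single_class_rejected(self, score_clouds):
        X, _ = score_clouds
        with pytest.raises(ValueError):
            en.consensus_model_train(X, np.ones(len(X)))


class TestDeriveThreshold:
    def test_lower_quartile(self):
        assert en.derive_threshold([0.8, 0.9, 1.0, 1.0]) == pytest.approx(0.875)

    def test_constant_scores(self):
        assert en.derive_threshold([0.7] * 10) == 0.7

    def test_too_few(self):
        with pytest.raises(ValueError):
            en.derive_threshold([0.9, 0.8, 0.7])

    def test_consistent_with_dataset_quantiles(self):
        from premirscan.datasets import quantile

        vals = list(np.random.default_rng(3).random(25))
        assert en.derive_threshold(vals) == quantile(vals, 0.25)


class TestTprTnr:
    @pytest.mark.parametrize("n_correct,expected",
                             [(96, 96.0), (0, 0.0), (100, 100.0)])
    def test_percentages(self, n_correct, expected):
        preds = ["miRNA"] * n_correct + ["negative"] * (100 - n_correct)
        truth = ["miRNA"] * 100
        assert en.tpr_tnr(preds, truth) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            en.tpr_tnr([], [])


class TestRankModels:
    def test_hand_ranked_two_by_two(self):
        mat = pd.DataFrame({"d1": [90.0, 80.0], "d2": [95.0, 85.0]},
                           index=["A", "B"])
        table = en.rank_models(mat)
        assert table.total_rank["A"] == 2 and table.total_rank["B"] == 4
        assert list(table.sorted().index) == ["A", "B"]

    def test_extreme_totals_32_by_21(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(10, 90, size=(32, 21))
        vals[0] = 99.0  # best everywhere
        vals[-1] = 1.0  # worst everywhere
        mat = pd.DataFrame(vals, index=[f"m{i}" for i in range(32)],
                           columns=[f"d{j}" for j in range(21)])
        table = en.rank_models(mat)
        assert table.total_rank["m0"] == 21
        assert table.total_rank["m31"] == 32 * 21

    def test_ties_get_average_rank_and_rank_sum_conserved(self):
        mat = pd.DataFrame({"d1": [90.0, 90.0, 50.0]}, index=list("ABC"))
        table = en.rank_models(mat)
        assert table.ranks.loc["A", "d1"] == 1.5
        assert table.ranks["d1"].sum() == 3 * 4 / 2

    def test_missing_cells_rejected(self):
        mat = pd.DataFrame({"d1": [90.0, np.nan]}, index=["A", "B"])
        with pytest.raises(ValueError):
            en.rank_models(mat)


class TestRoc:
    def test_perfect_and_antiperfect(self):
        y = [1, 1, 0, 0]
        assert en.roc_auc([0.9, 0.8, 0.2, 0.1], y) == 1.0
        assert en.roc_auc([0.1, 0.2, 0.8, 0.9], y) == 0.0

    def test_hand_derived_three_quarters(self):
        # pairs: (0.9+,0.8-) (0.9+,0.6-) (0.7+,0.8-) (0.7+,0.6-): 3 concordant
        assert en.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            en.roc_auc([0.5, 0.6], [1, 1])

    def test_matches_pair_concordance_and_sklearn(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.random(n)
            truth = rng.integers(0, 2, n)
            if len(set(truth)) < 2:
                continue
            # brute-force Mann-Whitney pair concordance
            pos = scores[truth == 1]
            neg = scores[truth == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = conc / (len(pos) * len(neg))
            assert en.roc_auc(scores, truth) == pytest.approx(expected, abs=1e-9)
            assert en.roc_auc(scores, truth) == pytest.approx(
                roc_auc_score(truth, scores), abs=1e-9)

    def test_curve_anchors(self):
        fpr, tpr, thr = en.roc_curve([0.9, 0.1], [1, 0])
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1
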