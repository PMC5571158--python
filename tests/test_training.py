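"""Balanced MCCV: split arithmetic, performance measures, the Model/Results
fitting surface, and model persistence."""

import numpy as np
import pandas as pd
import pytest

from premirscan.simulate import FixtureSpec, make_separable_features
from premirscan import training as tr


class TestSplitSpec:
    def test_defaults(self):
        spec = tr.SplitSpec()
        assert spec.train_fraction == 0.7 and spec.iterations == 1000

    @pytest.mark.parametrize("kw", [{"train_fraction": 0.0},
                                    {"train_fraction": 1.0},
                                    {"iterations": 0}])
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            tr.SplitSpec(**kw)


class TestMccvSplit:
    def test_seventy_thirty_arithmetic(self):
        tp, tn, sp, sn = tr.mccv_split(10, 20, tr.SplitSpec(seed=1), 0)
        assert len(tp) == 7 and len(tn) == 7
        assert len(sp) == 3 and len(sn) == 3

    def test_disjoint_and_balanced(self):
        spec = tr.SplitSpec(seed=1)
        for it in range(25):
            tp, tn, sp, sn = tr.mccv_split(100, 300, spec, it)
            assert not set(tp) & set(sp)
            assert not set(tn) & set(sn)
            assert len(tp) == len(tn) and len(sp) == len(sn)

    def test_deterministic_per_iteration(self):
        spec = tr.SplitSpec(seed=4)
        a = tr.mccv_split(50, 80, spec, 3)
        b = tr.mccv_split(50, 80, spec, 3)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        c = tr.mccv_split(50, 80, spec, 4)
        assert not all(np.array_equal(x, y) for x, y in zip(a, c))

    def test_insufficient_negatives(self):
        with pytest.raises(ValueError, match="insufficient"):
            tr.mccv_split(100, 50, tr.SplitSpec(), 0)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        p = tr.compute_metrics(50, 0, 50, 0)
        assert p.accuracy == 1.0 and p.cohens_kappa == 1.0
        assert p.youdens_index == 1.0 and p.f_measure == 1.0

    def test_degenerate_all_positive(self):
        p = tr.compute_metrics(50, 50, 0, 0)
        assert p.accuracy == 0.5
        assert p.cohens_kappa == 0.0
        assert p.youdens_index == 0.0

    def test_youden_from_rates(self):
        # sensitivity 0.8, specificity 0.7
        p = tr.compute_metrics(80, 30, 70, 20)
        assert p.sensitivity == pytest.approx(0.8)
        assert p.specificity == pytest.approx(0.7)
        assert p.youdens_index == pytest.approx(0.5)

    def test_recall_equals_sensitivity(self):
        p = tr.compute_metrics(30, 10, 40, 20)
        assert p.recall == p.sensitivity

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tr.compute_metrics(0, 0, 0, 0)


@pytest.fixture(scope="module")
def separable_fit():
    pos, neg = make_separable_features(
        FixtureSpec(seed=2, n_pos=120, n_neg=120, separation=4.0))
    model = tr.MCCV(pos, neg,
                    profiles={"A": list(pos.columns),
                              "A_copy": list(pos.columns),
                              "narrow": list(pos.columns)[:4]},
                    classifiers=("DT", "NB"),
                    spec=tr.SplitSpec(iterations=15, seed=9))
    return model, model.fit()


class TestMCCVFit:
    def test_distribution_length_per_pair(self, separable_fit):
        _, res = separable_fit
        for study in ("A", "A_copy", "narrow"):
            for kind in ("DT", "NB"):
                assert len(res.distribution(study, kind)) == 15

    def test_separable_data_high_accuracy(self, separable_fit):
        _, res = separable_fit
        assert res.best_model("A", "DT").best_metrics.accuracy >= 0.95
        assert res.best_model("A", "NB").best_metrics.accuracy >= 0.95

    def test_fair_comparison_identical_splits(self, separable_fit):
        # a profile with identical columns must see identical data, hence
        # produce identical confusion counts at every iteration
        _, res = separable_fit
        a = res.distribution("A", "NB").set_index("iteration")
        b = res.distribution("A_copy", "NB").set_index("iteration")
        for col in ("tp", "fp", "tn", "fn"):
            assert (a[col] == b[col]).all()

    def test_metric_consistency(self, separable_fit):
        _, res = separable_fit
        h = res.history
        recomputed = (h.tp + h.tn) / (h.tp + h.tn + h.fp + h.fn)
        assert np.allclose(recomputed, h.accuracy, atol=1e-12)

    def test_refit_reproducible(self, separable_fit):
        model, res = separable_fit
        res2 = model.fit()
        pd.testing.assert_frame_equal(res.history, res2.history)
        for key in res.best:
            assert res.best[key].best_iteration == res2.best[key].best_iteration

    def test_summary_shape(self, separable_fit):
        _, res = separable_fit
        s = res.summary()
        assert len(s) == 6  # 3 profiles x 2 kinds
        assert {"mean_accuracy", "best_iteration"} <= set(s.columns)


class TestPersistence:
    def test_round_trip_prediction_equality(self, separable_fit, tmp_path):
        _, res = separable_fit
        m = res.best_model("A", "DT")
        tr.save_model(m, tmp_path / "m.joblib")
        loaded = tr.load_model(tmp_path / "m.joblib")
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, len(m.feature_names))),
                         columns=list(m.feature_names))
        assert np.array_equal(m.predict_scores(X), loaded.predict_scores(X))
        assert loaded.best_metrics == m.best_metrics

    def test_corrupted_file(self, tmp_path):
        p = tmp_path / "bad.joblib"
        p.write_text("not a model")
        with pytest.raises(ValueError, match="unreadable"):
            tr.load_model(p)

    def test_schema_mismatch_names_features(self, separable_fit):
        _, res = separable_fit
        m = res.best_model("narrow", "NB")
        X = pd.DataFrame(np.zeros((2, 3)), columns=["f0", "f1", "zzz"])
        with pytest.raises(ValueError, match="schema mismatch"):
            m.predict_scores(X)

    def test_bundle_round_trip(self, separable_fit, tmp_path):
        _, res = separable_fit
        res.save_bundle(tmp_path / "bundle")
        bundle = tr.MCCVResults.load_bundle(tmp_path / "bundle")
        assert set(bundle) == set(res.best)
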