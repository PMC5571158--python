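"""Balanced Monte-Carlo cross-validated training of per-study classifiers.

The modelling surface follows the Model/Results idiom: build an
:class:`MCCV` object from positive and negative feature matrices (or from
hairpin data sets plus study profiles), call :meth:`MCCV.fit`, and receive
an :class:`MCCVResults` carrying the full per-iteration metric
distributions, the best model per (study, classifier) pair and a
``summary()`` table.

Sampling scheme: at every iteration, 70% of the positives (and an equal
number of negatives, drawn without replacement) form the training set; the
remaining 30% of positives plus an equal number of *fresh* negatives form
the test set.  Every study profile and classifier kind receives the same
split at a given iteration, so their scores are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

SCHEMA_VERSION = 1

CLASSIFIER_KINDS = ("DT", "NB", "SVM")


def _make_classifier(kind: str, seed: int):
    # library defaults throughout; hyperparameters are recorded verbatim in
    # model provenance rather than tuned
    if kind == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "NB":
        return GaussianNB()
    if kind == "SVM":
        return SVC(probability=True, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Monte-Carlo cross-validation parameters (70/30 split, balanced)."""

    train_fraction: float = 0.7
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class PerformanceRecord:
    """The eight performance measures plus the confusion counts they derive
    from.  Recall and sensitivity are both reported (they coincide for the
    positive class, as here)."""

    tp: int
    fp: int
    tn: int
    fn: int
    recall: float
    precision: float
    sensitivity: float
    specificity: float
    f_measure: float
    accuracy: float
    cohens_kappa: float
    youdens_index: float


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> PerformanceRecord:
    """Performance measures from confusion counts.

    Zero-denominator cases (e.g. precision with no predicted positives)
    are defined as 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def _div(a, b):
        return a / b if b else 0.0

    recall = _div(tp, tp + fn)
    precision = _div(tp, tp + fp)
    specificity = _div(tn, tn + fp)
    f_measure = _div(2 * precision * recall, precision + recall)
    accuracy = (tp + tn) / total
    # Cohen's kappa: observed vs chance agreement from the margins
    p_yes = ((tp + fp) / total) * ((tp + fn) / total)
    p_no = ((tn + fn) / total) * ((tn + fp) / total)
    pe = p_yes + p_no
    kappa = _div(accuracy - pe, 1 - pe) if pe != 1 else 1.0
    return PerformanceRecord(
        tp=tp, fp=fp, tn=tn, fn=fn,
        recall=recall, precision=precision,
        sensitivity=recall, specificity=specificity,
        f_measure=f_measure, accuracy=accuracy,
        cohens_kappa=kappa, youdens_index=recall + specificity - 1,
    )


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # counter-derived substream: iteration k reproducible in isolation
    return np.random.default_rng([seed, iteration])


def mccv_split(
    n_pos: int, n_neg: int, spec: SplitSpec, iteration: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index split for one iteration.

    Returns (train_pos, train_neg, test_pos, test_neg) as integer index
    arrays into the positive and negative pools.  Train takes
    ``floor(train_fraction * n_pos)`` positives and the same number of
    negatives; test takes the remaining positives and an equal number of
    fresh negatives (disjoint from the training negatives).
    """
    n_train_pos = int(np.floor(spec.train_fraction * n_pos))
    n_test_pos = n_pos - n_train_pos
    needed_neg = n_train_pos + n_test_pos
    if n_neg < needed_neg:
        raise ValueError(
            f"insufficient negatives: need {needed_neg}, have {n_neg}"
        )
    rng = _iteration_rng(spec.seed, iteration)
    pos_perm = rng.permutation(n_pos)
    neg_pick = rng.choice(n_neg, size=needed_neg, replace=False)
    return (
        np.sort(pos_perm[:n_train_pos]),
        np.sort(neg_pick[:n_train_pos]),
        np.sort(pos_perm[n_train_pos:]),
        np.sort(neg_pick[n_train_pos:]),
    )


# ---------------------------------------------------------------------------
# trained model container + persistence
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted classifier plus the schema and provenance needed to apply it
    safely to new feature matrices."""

    classifier_kind: str
    estimator: object
    feature_names: tuple[str, ...]
    study: str
    best_iteration: int
    best_metrics: PerformanceRecord
    provenance: dict = field(default_factory=dict)

    def _check_schema(self, X: pd.DataFrame) -> np.ndarray:
        cols = tuple(X.columns)
        if cols != self.feature_names:
            missing = set(self.feature_names) - set(cols)
            extra = set(cols) - set(self.feature_names)
            raise ValueError(
                "feature schema mismatch: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}, "
                f"expected order {list(self.feature_names)}"
            )
        return X.to_numpy(dtype=float)

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Positive-class scores in [0, 1]; schema checked (names + order)."""
        arr = self._check_schema(X)
        proba = self.estimator.predict_proba(arr)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]

    def predict_labels(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)


def save_model(model: TrainedModel, path) -> None:
    """Versioned envelope: JSON header (schema, metrics, provenance) plus the
    joblib-serialised estimator payload."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "classifier_kind": model.classifier_kind,
        "feature_names": list(model.feature_names),
        "study": model.study,
        "best_iteration": model.best_iteration,
        "best_metrics": asdict(model.best_metrics),
        "provenance": model.provenance,
    }
    joblib.dump({"header": payload, "estimator": model.estimator}, path)


def load_model(path) -> TrainedModel:
    try:
        blob = joblib.load(path)
        header = blob["header"]
        estimator = blob["estimator"]
    except Exception as exc:
        raise ValueError(f"unreadable model file {path}: {exc}") from exc
    if header.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {header.get('schema_version')} "
            f"!= supported {SCHEMA_VERSION}"
        )
    return TrainedModel(
        classifier_kind=header["classifier_kind"],
        estimator=estimator,
        feature_names=tuple(header["feature_names"]),
        study=header["study"],
        best_iteration=header["best_iteration"],
        best_metrics=PerformanceRecord(**header["best_metrics"]),
        provenance=header["provenance"],
    )


# ---------------------------------------------------------------------------
# the MCCV model object
# ---------------------------------------------------------------------------

class MCCV:
    """Balanced Monte-Carlo cross-validation over study profiles.

    Parameters
    ----------
    pos, neg : pandas.DataFrame
        Feature matrices (rows = hairpins, full registry columns) for the
        positive and negative pools.  Column sets must agree.
    profiles : mapping study -> ordered feature-name list, optional
        Column selections trained side by side on identical splits.  The
        default trains a single profile over all shared columns.
    classifiers : tuple of {'DT', 'NB', 'SVM'}
    spec : SplitSpec
    """

    def __init__(self, pos: pd.DataFrame, neg: pd.DataFrame,
                 profiles: dict[str, list[str]] | None = None,
                 classifiers: tuple[str, ...] = ("DT", "NB"),
                 spec: SplitSpec = SplitSpec()):
        if set(pos.columns) != set(neg.columns):
            raise ValueError("positive/negative feature columns differ")
        self.pos = pos
        self.neg = neg[pos.columns]
        if profiles is None:
            profiles = {"full": list(pos.columns)}
        for study, names in profiles.items():
            unknown = [n for n in names if n not in pos.columns]
            if unknown:
                raise ValueError(f"profile {study}: columns {unknown} absent")
        self.profiles = {s: list(n) for s, n in profiles.items()}
        for kind in classifiers:
            if kind not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier kind {kind!r}")
        self.classifiers = tuple(classifiers)
        self.spec = spec

    @classmethod
    def from_datasets(cls, pos_ds, neg_ds, profiles=None, backend="fallback",
                      classifiers=("DT", "NB"), spec=SplitSpec()):
        """Build from hairpin :class:`~premirscan.datasets.Dataset` objects,
        computing the full feature registry once and selecting per-profile
        columns from it."""
        from . import features as ft

        pos_X = ft.compute_matrix(pos_ds.records, backend=backend)
        neg_X = ft.compute_matrix(neg_ds.records, backend=backend)
        if profiles is None:
            profiles = {s: list(p.feature_names)
                        for s, p in ft.STUDY_PROFILES.items()}
        return cls(pos_X, neg_X, profiles, classifiers, spec)

    def fit(self, store_scores: bool = False) -> "MCCVResults":
        """Run the MCCV loop and return the results object.

        ``store_scores=True`` additionally retains per-iteration test scores
        of the best models (needed for ROC analysis without refitting).
        """
        spec = self.spec
        n_pos, n_neg = len(self.pos), len(self.neg)
        pos_arr = {s: self.pos[cols].to_numpy(float)
                   for s, cols in self.profiles.items()}
        neg_arr = {s: self.neg[cols].to_numpy(float)
                   for s, cols in self.profiles.items()}

        rows = []
        best: dict[tuple[str, str], TrainedModel] = {}
        failures: list[dict] = []
        for it in range(spec.iterations):
            tr_p, tr_n, te_p, te_n = mccv_split(n_pos, n_neg, spec, it)
            y_train = np.r_[np.ones(len(tr_p)), np.zeros(len(tr_n))]
            y_test = np.r_[np.ones(len(te_p)), np.zeros(len(te_n))]
            for study in self.profiles:
                X_train = np.vstack([pos_arr[study][tr_p], neg_arr[study][tr_n]])
                X_test = np.vstack([pos_arr[study][te_p], neg_arr[study][te_n]])
                for kind in self.classifiers:
                    clf = _make_classifier(kind, seed=spec.seed)
                    try:
                        clf.fit(X_train, y_train)
                        y_hat = clf.predict(X_test)
                    except Exception as exc:  # recorded, iteration skipped
                        failures.append({"iteration": it, "study": study,
                                         "kind": kind, "error": str(exc)})
                        continue
                    tp = int(np.sum((y_hat == 1) & (y_test == 1)))
                    fp = int(np.sum((y_hat == 1) & (y_test == 0)))
                    tn = int(np.sum((y_hat == 0) & (y_test == 0)))
                    fn = int(np.sum((y_hat == 0) & (y_test == 1)))
                    perf = compute_metrics(tp, fp, tn, fn)
                    rows.append({"iteration": it, "study": study, "kind": kind,
                                 **asdict(perf)})
                    key = (study, kind)
                    cur = best.get(key)
                    # best by accuracy; ties by F-measure, then earlier iteration
                    if cur is None or (
                        perf.accuracy, perf.f_measure, -it
                    ) > (
                        cur.best_metrics.accuracy, cur.best_metrics.f_measure,
                        -cur.best_iteration,
                    ):
                        best[key] = TrainedModel(
                            classifier_kind=kind, estimator=clf,
                            feature_names=tuple(self.profiles[study]),
                            study=study, best_iteration=it, best_metrics=perf,
                            provenance={
                                "spec": asdict(spec),
                                "n_pos": n_pos, "n_neg": n_neg,
                                "hyperparameters": clf.get_params(),
                            },
                        )
        history = pd.DataFrame(rows)
        return MCCVResults(self, history, best, failures)


class MCCVResults:
    """Results of :meth:`MCCV.fit`: per-iteration metric distributions,
    best models, failures and a summary table."""

    def __init__(self, model: MCCV, history: pd.DataFrame,
                 best: dict[tuple[str, str], TrainedModel], failures):
        self.model = model
        self.history = history
        self.best = best
        self.failures = failures

    def best_model(self, study: str, kind: str) -> TrainedModel:
        return self.best[(study, kind)]

    def distribution(self, study: str, kind: str) -> pd.DataFrame:
        h = self.history
        return h[(h["study"] == study) & (h["kind"] == kind)]

    def summary(self) -> pd.DataFrame:
        """Per (study, classifier): mean/max accuracy, mean F-measure and
        Youden's index over all iterations plus the best iteration index."""
        g = self.history.groupby(["study", "kind"])
        out = g.agg(
            mean_accuracy=("accuracy", "mean"),
            max_accuracy=("accuracy", "max"),
            mean_f_measure=("f_measure", "mean"),
            mean_youden=("youdens_index", "mean"),
            iterations=("iteration", "count"),
        ).reset_index()
        out["best_iteration"] = [
            self.best[(s, k)].best_iteration if (s, k) in self.best else -1
            for s, k in zip(out["study"], out["kind"])
        ]
        return out.sort_values(["study", "kind"]).reset_index(drop=True)

    def save_bundle(self, directory) -> None:
        """Persist every best model plus a bundle manifest."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = []
        for (study, kind), model in self.best.items():
            fname = f"{study}_{kind}.model.joblib"
            save_model(model, d / fname)
            manifest.append({"study": study, "kind": kind, "file": fname})
        (d / "bundle.json").write_text(json.dumps(
            {"schema_version": SCHEMA_VERSION, "models": manifest}, indent=1))

    @staticmethod
    def load_bundle(directory) -> dict[tuple[str, str], TrainedModel]:
        from pathlib import Path

        d = Path(directory)
        manifest = json.loads((d / "bundle.json").read_text())
        return {
            (m["study"], m["kind"]): load_model(d / m["file"])
            for m in manifest["models"]
        }
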