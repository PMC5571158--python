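"""Consensus prediction schemes, rank aggregation and ROC analysis.

Six ensemble schemes combine the per-study classifier scores:

* ``Consensus_DT`` / ``Consensus_NB`` — majority vote: *miRNA* when seven
  or more of the 13 study models of that kind vote positive.
* ``Average_DT`` / ``Average_NB`` — mean score; *negative* when the mean is
  below 0.5, *miRNA* otherwise (a mean of exactly 0.5 is *miRNA*).
* ``ConsensusRule`` — three-way rule on the two averages: *miRNA* when
  either average exceeds 0.89; otherwise *negative* when either average is
  below 0.5; everything left is a *candidate*.  When both clauses fire the
  miRNA clause wins and the decision carries a ``rule_conflict`` flag.
* ``ConsensusModel`` — a multi-layer-perceptron meta-classifier trained on
  the per-study score vectors with the same Monte-Carlo procedure used for
  the base classifiers, selected by accuracy then F-measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.neural_network import MLPClassifier

from .datasets import quantile
from .training import SplitSpec, TrainedModel, compute_metrics, mccv_split

MAJORITY_THRESHOLD = 7  # of the 13 study models
RULE_MIRNA_CUTOFF = 0.89  # strict >
RULE_NEGATIVE_CUTOFF = 0.5  # strict <

MIRNA, CANDIDATE, NEGATIVE = "miRNA", "candidate", "negative"


def consensus_vote(votes: dict[str, int] | list[int],
                   n_studies: int = 13,
                   threshold: int = MAJORITY_THRESHOLD) -> str:
    """Majority vote over binary per-study predictions of one classifier
    kind: *miRNA* iff at least ``threshold`` studies vote positive."""
    if isinstance(votes, dict):
        vals = list(votes.values())
    else:
        vals = list(votes)
    if len(vals) != n_studies:
        raise ValueError(
            f"expected one vote per study ({n_studies}), got {len(vals)}"
        )
    if any(v not in (0, 1) for v in vals):
        raise ValueError("votes must be binary 0/1")
    return MIRNA if sum(vals) >= threshold else NEGATIVE


def average_predict(scores) -> tuple[float, str]:
    """Mean of per-study scores of one kind; label per the 0.5 rule."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no scores supplied")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("scores must lie in [0, 1]")
    avg = float(arr.mean())
    return avg, (NEGATIVE if avg < 0.5 else MIRNA)


@dataclass(frozen=True)
class RuleDecision:
    label: str
    rule_conflict: bool = False


def consensus_rule(avg_dt: float, avg_nb: float) -> RuleDecision:
    """Three-way decision on the two average scores (see module docstring).

    Clause order resolves the one ambiguous corner (one average above the
    miRNA cutoff while the other is below the negative cutoff): the miRNA
    clause wins, and the decision is flagged as a rule conflict for audit.
    """
    for v, name in ((avg_dt, "avg_dt"), (avg_nb, "avg_nb")):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    mirna_fires = avg_dt > RULE_MIRNA_CUTOFF or avg_nb > RULE_MIRNA_CUTOFF
    negative_fires = avg_dt < RULE_NEGATIVE_CUTOFF or avg_nb < RULE_NEGATIVE_CUTOFF
    if mirna_fires:
        return RuleDecision(MIRNA, rule_conflict=negative_fires)
    if negative_fires:
        return RuleDecision(NEGATIVE)
    return RuleDecision(CANDIDATE)


# ---------------------------------------------------------------------------
# ConsensusModel: MLP meta-classifier over study score vectors
# ---------------------------------------------------------------------------

def consensus_model_train(
    scores: pd.DataFrame, labels: np.ndarray, spec: SplitSpec = SplitSpec(iterations=50)
) -> TrainedModel:
    """Train the meta-classifier on per-study score vectors.

    ``scores`` rows are hairpins, columns per-study model scores in [0, 1];
    ``labels`` is the binary truth.  Training repeats the balanced
    Monte-Carlo scheme of the base classifiers and keeps the model with the
    highest accuracy (ties broken by F-measure).  Architecture: one hidden
    layer as wide as the input, early stopping, seeded.
    """
    labels = np.asarray(labels, dtype=int)
    if len(set(labels)) < 2:
        raise ValueError("meta-training needs both classes in labels")
    pos_X = scores[labels == 1].to_numpy(float)
    neg_X = scores[labels == 0].to_numpy(float)
    width = scores.shape[1]
    best: TrainedModel | None = None
    for it in range(spec.iterations):
        tr_p, tr_n, te_p, te_n = mccv_split(len(pos_X), len(neg_X), spec, it)
        X_train = np.vstack([pos_X[tr_p], neg_X[tr_n]])
        y_train = np.r_[np.ones(len(tr_p)), np.zeros(len(tr_n))]
        X_test = np.vstack([pos_X[te_p], neg_X[te_n]])
        y_test = np.r_[np.ones(len(te_p)), np.zeros(len(te_n))]
        # learning rate and patience raised above the library defaults:
        # score vectors live in [0,1] and at a few hundred samples the
        # default step plateaus the validation score before the loss moves
        clf = MLPClassifier(
            hidden_layer_sizes=(width,), early_stopping=True,
            n_iter_no_change=50, learning_rate_init=0.05,
            random_state=spec.seed, max_iter=1000,
        )
        clf.fit(X_train, y_train)
        y_hat = clf.predict(X_test)
        perf = compute_metrics(
            tp=int(np.sum((y_hat == 1) & (y_test == 1))),
            fp=int(np.sum((y_hat == 1) & (y_test == 0))),
            tn=int(np.sum((y_hat == 0) & (y_test == 0))),
            fn=int(np.sum((y_hat == 0) & (y_test == 1))),
        )
        if best is None or (
            perf.accuracy, perf.f_measure, -it
        ) > (
            best.best_metrics.accuracy, best.best_metrics.f_measure,
            -best.best_iteration,
        ):
            best = TrainedModel(
                classifier_kind="MLP", estimator=clf,
                feature_names=tuple(scores.columns), study="ConsensusModel",
                best_iteration=it, best_metrics=perf,
                provenance={"spec": {"train_fraction": spec.train_fraction,
                                     "iterations": spec.iterations,
                                     "seed": spec.seed},
                            "architecture": f"1 hidden layer, width {width}"},
            )
    return best


def consensus_model_predict(meta: TrainedModel, scores: pd.DataFrame) -> np.ndarray:
    """Calibrated positive-class scores in [0, 1] from the meta-classifier."""
    return meta.predict_scores(scores)


# ---------------------------------------------------------------------------
# thresholds, rates, ranks, ROC
# ---------------------------------------------------------------------------

def derive_threshold(positive_control_scores) -> float:
    """Confidence threshold = lower quartile of the ensemble scores that a
    positive control set receives (linear-interpolation estimator shared
    with the data-set quantile code)."""
    arr = np.asarray(list(positive_control_scores), dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 control scores for a quartile")
    return quantile(arr, 0.25)


def tpr_tnr(predictions, truth) -> float:
    """Percent of hairpins classified correctly.

    Applied to an all-positive set this is the true positive rate, to an
    all-negative set the true negative rate (the convention used for
    single-label evaluation sets).
    """
    preds = list(predictions)
    tr = list(truth)
    if not preds or len(preds) != len(tr):
        raise ValueError("predictions/truth must be equal-length, non-empty")
    correct = sum(1 for p, t in zip(preds, tr) if p == t)
    return 100.0 * correct / len(preds)


@dataclass
class RankTable:
    correctness: pd.DataFrame  # model x dataset, percent correct
    ranks: pd.DataFrame  # per-dataset ranks (1 = best)
    total_rank: pd.Series  # row sums, ascending = better

    def sorted(self) -> pd.DataFrame:
        out = self.correctness.copy()
        out["total_rank"] = self.total_rank
        return out.sort_values("total_rank")


def rank_models(correctness: pd.DataFrame, ties: str = "average") -> RankTable:
    """Rank models per data set (1 = highest percent correct) and aggregate
    by summing ranks across data sets, treating every data set equally.

    With M models and D data sets, a model ranked best everywhere scores a
    total of D, and worst everywhere (no ties) M*D.  Ties share fractional
    (average) ranks by default; ``ties='min'`` is also accepted.
    """
    if correctness.isna().any().any():
        missing = correctness.columns[correctness.isna().any()].tolist()
        raise ValueError(f"correctness matrix has missing cells in {missing}")
    method = {"average": "average", "min": "min"}[ties]
    ranks = correctness.apply(
        lambda col: rankdata(-col.to_numpy(float), method=method), axis=0
    )
    total = ranks.sum(axis=1)
    return RankTable(correctness=correctness, ranks=ranks,
                     total_rank=total.astype(float))


def roc_curve(scores, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-sweep ROC: thresholds are the distinct scores (ties grouped),
    returning (fpr, tpr, thresholds) with the (0,0) and (1,1) anchors."""
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(truth), dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes in truth")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score group
    distinct = np.r_[np.where(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return fpr, tpr, thresholds


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve by the trapezoidal rule over the full
    threshold sweep (equals the Mann-Whitney pair-concordance statistic)."""
    fpr, tpr, _ = roc_curve(scores, truth)
    return float(np.trapezoid(tpr, fpr))
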