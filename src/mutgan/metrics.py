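"""Classification and explanation metrics, and dataset-splitting harnesses.

Conventions: macro-F1 is the unweighted mean of per-class F1 and a class
absent from both truth and prediction contributes 0; AUROC follows the
rank-statistic definition with half-credit for ties; cross-validated
aggregates weight each fold by its test-set size.  scikit-learn provides
the underlying computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn import metrics as skm
from sklearn.model_selection import KFold, LeaveOneGroupOut, StratifiedShuffleSplit

__all__ = [
    "macro_f1", "accuracy", "auroc", "explanation_f1", "make_splits",
    "weighted_average", "MetricReport", "aggregate_reports",
]


def _check_same_length(a, b):
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")


def macro_f1(y_true, y_pred, classes=None) -> float:
    """Unweighted mean of per-class F1 over ``classes`` (default: union)."""
    _check_same_length(y_true, y_pred)
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    return float(skm.f1_score(y_true, y_pred, labels=list(classes),
                              average="macro", zero_division=0))


def accuracy(y_true, y_pred) -> float:
    _check_same_length(y_true, y_pred)
    return float(skm.accuracy_score(list(y_true), list(y_pred)))


def auroc(y_true, scores, mode: str = "binary",
          positive_label=None) -> float:
    """Area under the ROC curve.

    Binary mode scores the ``positive_label`` (default: the larger label
    under sort order); macro one-vs-rest mode expects a score matrix with
    one column per sorted class.  Single-class truth raises.
    """
    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if mode == "binary":
        classes = np.unique(y_true.astype(str))
        if len(classes) != 2:
            raise ValueError(f"binary AUROC needs both classes present, "
                             f"got {list(classes)}")
        if positive_label is None:
            positive_label = classes[1]
        y = (y_true.astype(str) == str(positive_label)).astype(int)
        return float(skm.roc_auc_score(y, scores))
    if mode == "macro_ovr":
        classes = np.unique(y_true.astype(str))
        if scores.ndim != 2 or scores.shape[1] != len(classes):
            raise ValueError("macro_ovr needs an (n, n_classes) score matrix "
                             "with columns in sorted class order")
        return float(skm.roc_auc_score(y_true.astype(str), scores,
                                       multi_class="ovr", average="macro",
                                       labels=list(classes)))
    raise ValueError(f"unknown AUROC mode {mode!r}")


def explanation_f1(truth_masks, predicted_probs, lengths=None,
                   threshold: float = 0.5, per_sequence: bool = False) -> float:
    """Position-level macro-F1 of thresholded replacement probabilities.

    Positions are pooled across sequences (padding excluded); with
    ``per_sequence`` the macro-F1 is computed per sequence and averaged.
    """
    _check_same_length(truth_masks, predicted_probs)
    flat_t, flat_p, per_seq = [], [], []
    for i, (mask, probs) in enumerate(zip(truth_masks, predicted_probs)):
        mask = np.asarray(mask)
        probs = np.asarray(probs, dtype=float)
        if mask.shape != probs.shape:
            raise ValueError(f"sequence {i}: mask length {mask.size} != "
                             f"probability length {probs.size}")
        m = int(lengths[i]) if lengths is not None else mask.size
        t = mask[:m]
        p = (probs[:m] >= threshold).astype(int)
        if per_sequence:
            per_seq.append(skm.f1_score(t, p, labels=[0, 1], average="macro",
                                        zero_division=0))
        else:
            flat_t.append(t)
            flat_p.append(p)
    if per_sequence:
        return float(np.mean(per_seq)) if per_seq else 0.0
    t = np.concatenate(flat_t) if flat_t else np.zeros(0, dtype=int)
    p = np.concatenate(flat_p) if flat_p else np.zeros(0, dtype=int)
    return float(skm.f1_score(t, p, labels=[0, 1], average="macro",
                              zero_division=0))


def make_splits(labels, principle: str = "holdout", groups=None,
                test_size: float = 0.1, n_splits: int = 5,
                seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs under one of the evaluation principles.

    ``holdout``: one seeded stratified split (default 90/10);
    ``leave_one_group_out``: one fold per distinct group (needs ``groups``);
    ``kfold``: seeded shuffled K-fold.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    idx = np.arange(len(labels))
    if principle == "holdout":
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_size,
                                          random_state=seed)
        return [(tr, te) for tr, te in splitter.split(idx, labels)]
    if principle in ("leave_one_group_out", "logo"):
        if groups is None or any(g is None for g in groups):
            raise ValueError("leave-one-group-out needs a group key on "
                             "every record")
        splitter = LeaveOneGroupOut()
        return [(tr, te) for tr, te in
                splitter.split(idx, labels, groups=np.asarray(groups))]
    if principle == "kfold":
        splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(idx)]
    raise ValueError(f"unknown split principle {principle!r}")


def weighted_average(values, sizes) -> float:
    """Fold aggregate weighted by test-fold size."""
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    _check_same_length(values, sizes)
    return float((values * sizes).sum() / sizes.sum())


@dataclass
class MetricReport:
    """Bundle of evaluation results for one model on one test set."""

    macro_f1: float | None = None
    accuracy: float | None = None
    auroc: float | None = None
    per_class_f1: dict[str, float] = field(default_factory=dict)
    explanation_macro_f1: float | None = None
    n_test: int | None = None
    variance: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores=None,
                         auroc_mode: str = "binary",
                         positive_label=None) -> "MetricReport":
        classes = np.unique(np.asarray(y_true, dtype=object).astype(str))
        per_class = skm.f1_score(
            np.asarray(y_true, dtype=object).astype(str),
            np.asarray(y_pred, dtype=object).astype(str),
            labels=list(classes), average=None, zero_division=0)
        report = cls(
            macro_f1=macro_f1(y_true, y_pred),
            accuracy=accuracy(y_true, y_pred),
            per_class_f1={c: float(f) for c, f in zip(classes, per_class)},
            n_test=len(y_true))
        if scores is not None:
            report.auroc = auroc(y_true, scores, mode=auroc_mode,
                                 positive_label=positive_label)
        return report


def aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Size-weighted average across folds, with across-fold variance."""
    sizes = [r.n_test for r in reports]
    agg = MetricReport(n_test=int(np.sum(sizes)))
    for name in ("macro_f1", "accuracy", "auroc", "explanation_macro_f1"):
        vals = [getattr(r, name) for r in reports]
        if all(v is not None for v in vals):
            setattr(agg, name, weighted_average(vals, sizes))
            agg.variance[name] = float(np.var(vals))
    return agg
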