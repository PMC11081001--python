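"""Multiclass classification metrics and final-stage classification.

Computes the reported metric set — accuracy, macro precision/recall/F1,
Cohen's kappa and the multiclass (Gorodkin) Matthews correlation — directly
from a confusion matrix, plus classification of a selected feature subset
with standard off-the-shelf classifiers (KNN, RBF-SVM, one-hidden-layer
perceptron).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .pfa import SelectionMask
from .synthetic import LabeledFeatureMatrix


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.class_labels) != self.counts.shape[0]:
            raise ValueError("class_labels length must match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    kappa: float
    mcc: float
    degenerate: bool = False  # all mass on one true/predicted class


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Count matrix over the sorted union of observed (or given) labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_labels=list(labels))


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Metric set from a confusion matrix; 0/0 rates defined as 0.

    Kappa is the chance-corrected agreement (p_o - p_e) / (1 - p_e); MCC is
    the multiclass covariance form
    (c s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2)) with
    c = trace, s = total, t/p the true/predicted marginals. A matrix whose
    mass sits entirely in one row and one column has no chance-corrected
    information: kappa and MCC are reported as 0 with the degenerate flag.
    """
    c = np.asarray(cm.counts, dtype=float)
    s = c.sum()
    if s <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(c)
    true_marg = c.sum(axis=1)
    pred_marg = c.sum(axis=0)

    accuracy = float(diag.sum() / s)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_marg > 0, diag / pred_marg, 0.0)
        rec = np.where(true_marg > 0, diag / true_marg, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)

    p_o = accuracy
    p_e = float((true_marg * pred_marg).sum() / s**2)
    mcc_num = float(diag.sum() * s - (true_marg * pred_marg).sum())
    mcc_den = float(
        np.sqrt(s**2 - (pred_marg**2).sum()) * np.sqrt(s**2 - (true_marg**2).sum())
    )
    kappa_degenerate = bool(np.isclose(p_e, 1.0))
    mcc_degenerate = mcc_den == 0.0
    kappa = 0.0 if kappa_degenerate else (p_o - p_e) / (1.0 - p_e)
    mcc = 0.0 if mcc_degenerate else mcc_num / mcc_den
    degenerate = kappa_degenerate or mcc_degenerate

    return MetricsReport(
        accuracy=accuracy,
        precision_macro=float(prec.mean()),
        recall_macro=float(rec.mean()),
        f1_macro=float(f1.mean()),
        kappa=float(kappa),
        mcc=float(mcc),
        degenerate=bool(degenerate),
    )


def _make_classifier(name: str, params: dict | None, seed: int):
    params = dict(params or {})
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 5), **params)
    if name == "svm_rbf":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", random_state=seed, **params)
        )
    if name == "mlp":
        width = params.pop("hidden_width", 100)
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(width,),
                max_iter=params.pop("max_iter", 500),
                random_state=seed,
                **params,
            ),
        )
    raise ValueError(f"unknown classifier {name!r}")


def classify_selected(
    train: LabeledFeatureMatrix,
    test: LabeledFeatureMatrix,
    mask: SelectionMask,
    classifier: str = "knn",
    params: dict | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Fit on masked train columns, score masked test columns.

    The label set is fixed to the union of train and test labels so a class
    absent from the test split still occupies its confusion-matrix row.
    """
    if train.n_features != test.n_features:
        raise ValueError("train and test feature spaces differ")
    if mask.selected.size != train.n_features:
        raise ValueError("mask length must match feature count")
    clf = _make_classifier(classifier, params, seed)
    clf.fit(train.values[:, mask.selected], train.labels)
    y_pred = clf.predict(test.values[:, mask.selected])
    labels = sorted(set(train.labels.tolist()) | set(test.labels.tolist()))
    return report(confusion(test.labels, y_pred, labels=labels))
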