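"""Pre/post discriminability via ROC/AUC and the neural integration index.

Discriminability of an object pair from multivoxel patterns is quantified
by the area under the ROC curve of a binary logistic classifier, estimated
with leave-one-run-out cross-validation in the pre-training session. The
pre-training fold models are then tested, one per run, on the post-training
session. The *neural integration index* is the pre-training AUC minus the
post-training AUC: positive values mean the pair became harder to
discriminate (integration), negative values easier (differentiation).

AUC is computed here by the rank/concordance (Mann-Whitney) method with
midranks for ties, which equals the trapezoidal area under the empirical
ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .realtime_decoding import make_classifier
from .synthetic_data import AXES, PatternDataset


class UndefinedAucError(ValueError):
    pass


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray


@dataclass
class AxisAucResult:
    """Cross-validated AUC summary for one object pair (axis)."""

    axis: str
    fold_aucs: np.ndarray
    skipped_folds: list[int]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass
class IntegrationResult:
    """Per-axis pre/post AUCs and integration indices for one ROI."""

    roi: str
    auc_s1: dict[str, float]
    auc_s5: dict[str, float]

    def index(self, axis: str) -> float:
        return neural_integration_index(self.auc_s1[axis], self.auc_s5[axis])

    @property
    def contrast(self) -> float:
        return axis_contrast(self.index("trained"), self.index("untrained"))


def roc_auc(scores: "np.ndarray | list[float]", labels: "np.ndarray | list[int]") -> RocResult:
    """Rank-based AUC with midranks for ties, plus the empirical ROC curve.

    ``labels`` are binary (1 = positive). The AUC equals the probability
    that a random positive outscores a random negative, counting ties as
    one half, and equals the trapezoidal area under the (FPR, TPR) curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAucError("AUC undefined: both classes must be present")

    ranks = rankdata(scores)  # midranks for ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # empirical ROC at every distinct score threshold (predict positive if
    # score >= threshold), from the most liberal to the most conservative
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    distinct = np.r_[np.where(np.diff(sorted_scores))[0], sorted_labels.size - 1]
    tp = np.cumsum(sorted_labels)[distinct].astype(float)
    fp = (distinct + 1) - tp
    fn = n_pos - tp
    tn = n_neg - fp
    tpr = tp / n_pos
    fpr = fp / n_neg
    return RocResult(
        auc=float(auc),
        thresholds=sorted_scores[distinct],
        tpr=tpr,
        fpr=fpr,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def _pair_scores(model, patterns: np.ndarray, positive: str) -> np.ndarray:
    idx = list(model.classes_).index(positive)
    return model.predict_proba(patterns)[:, idx]


def session1_cv_auc(
    dataset_s1: PatternDataset,
    pair: tuple[str, str],
    l2_weight: float = 1.0,
    axis: str | None = None,
) -> tuple[AxisAucResult, list]:
    """Leave-one-run-out AUC for a pair in the pre-training session.

    Returns the per-fold AUCs and the fitted fold models (indexed by
    held-out run) for later testing on the post-training session. Folds
    whose held-out run lacks one of the two classes are skipped with a
    warning and recorded.
    """
    subset = dataset_s1.subset_pair(pair)
    run_ids = subset.run_ids
    if run_ids.size < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    positive = pair[0]
    fold_aucs, models, skipped = [], [], []
    for run in run_ids:
        test_mask = subset.runs == run
        train_x, train_y = subset.data[~test_mask], subset.labels[~test_mask]
        test_x, test_y = subset.data[test_mask], subset.labels[test_mask]
        clf = make_classifier(l2_weight)
        clf.fit(train_x, train_y)
        models.append(clf)
        bin_y = (test_y == positive).astype(int)
        if bin_y.sum() in (0, bin_y.size):
            warnings.warn(f"run {run}: single-class held-out fold skipped")
            skipped.append(int(run))
            continue
        fold_aucs.append(roc_auc(_pair_scores(clf, test_x, positive), bin_y).auc)
    name = axis or "+".join(pair)
    return AxisAucResult(axis=name, fold_aucs=np.asarray(fold_aucs), skipped_folds=skipped), models


def session5_auc(
    dataset_s5: PatternDataset,
    fold_models: list,
    pair: tuple[str, str],
    axis: str | None = None,
) -> AxisAucResult:
    """Test the pre-training fold models on the post-training runs.

    Model i scores run i (pairing by run index); the per-run AUCs are
    averaged. The model count must equal the post-training run count.
    """
    subset = dataset_s5.subset_pair(pair)
    run_ids = subset.run_ids
    if len(fold_models) != run_ids.size:
        raise ValueError(
            f"{len(fold_models)} models cannot be paired with {run_ids.size} runs"
        )
    positive = pair[0]
    aucs = []
    for model, run in zip(fold_models, run_ids):
        mask = subset.runs == run
        bin_y = (subset.labels[mask] == positive).astype(int)
        if bin_y.sum() in (0, bin_y.size):
            raise UndefinedAucError(f"run {run} contains a single class")
        aucs.append(roc_auc(_pair_scores(model, subset.data[mask], positive), bin_y).auc)
    name = axis or "+".join(pair)
    return AxisAucResult(axis=name, fold_aucs=np.asarray(aucs), skipped_folds=[])


def neural_integration_index(auc_s1: float, auc_s5: float) -> float:
    """Pre minus post AUC; positive = integration (discriminability lost)."""
    for v in (auc_s1, auc_s5):
        if not 0.0 <= v <= 1.0:
            raise ValueError("AUCs must lie in [0, 1]")
    return auc_s1 - auc_s5


def axis_contrast(trained_index: float, untrained_index: float) -> float:
    """Trained-axis integration relative to the untrained baseline."""
    return trained_index - untrained_index


def integration_for_roi(
    dataset_s1: PatternDataset,
    dataset_s5: PatternDataset,
    roi: str = "roi",
    l2_weight: float = 1.0,
) -> IntegrationResult:
    """Run the full pre/post AUC analysis for both axes on one ROI."""
    auc_s1, auc_s5 = {}, {}
    for axis, pair in AXES.items():
        res_s1, models = session1_cv_auc(dataset_s1, pair, l2_weight=l2_weight, axis=axis)
        res_s5 = session5_auc(dataset_s5, models, pair, axis=axis)
        auc_s1[axis] = res_s1.mean_auc
        auc_s5[axis] = res_s5.mean_auc
    return IntegrationResult(roi=roi, auc_s1=auc_s1, auc_s5=auc_s5)
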