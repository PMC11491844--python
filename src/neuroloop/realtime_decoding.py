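"""Causal normalization, trial extraction, pairwise classifiers and evidence.

The real-time system normalizes each voxel's timecourse causally (using only
prior TRs of the current run), extracts one pattern per trial at the
hemodynamically lagged TR, and scores it with a bank of six pairwise
logistic-regression classifiers (all unordered pairs of the four objects).
Classifier *evidence* for an object is the mean probability assigned to it
by the two classifiers pitting it against the control objects; coactivation
of the presented and competitor objects is the product of their evidences.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .synthetic_data import OBJECTS, PatternDataset


class ExtractionError(IndexError):
    pass


class TrainingError(ValueError):
    pass


def running_zscore(series: np.ndarray) -> np.ndarray:
    """Strictly causal per-voxel z-scoring of a TR x voxel timeseries.

    The value at TR t is standardized by the mean and sample (n-1) standard
    deviation of TRs 0..t-1 only. TRs with fewer than two prior samples, and
    voxels whose prior variance is zero, emit 0.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n_trs = series.shape[0]
    out = np.zeros_like(series)
    csum = np.cumsum(series, axis=0)
    csum2 = np.cumsum(series**2, axis=0)
    for t in range(2, n_trs):
        n = t
        mean = csum[t - 1] / n
        var = (csum2[t - 1] - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (series[t] - mean) / sd
        out[t] = np.where(sd > 0, z, 0.0)
    return out


def full_run_zscore(series: np.ndarray) -> np.ndarray:
    """Offline per-voxel z-scoring over the full run timecourse.

    Zero-variance voxels emit 0 (matching the causal variant's guard).
    """
    series = np.asarray(series, dtype=float)
    mean = series.mean(axis=0)
    sd = series.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (series - mean) / sd
    return np.where(sd > 0, z, 0.0)


def extract_trial_pattern(
    series: np.ndarray, onset_tr: int, lag_trs: int = 2
) -> np.ndarray:
    """The single-TR voxel vector ``lag_trs`` after the trial onset."""
    series = np.asarray(series)
    t = onset_tr + lag_trs
    if not 0 <= t < series.shape[0]:
        raise ExtractionError(
            f"lagged TR {t} outside run of {series.shape[0]} TRs (onset {onset_tr})"
        )
    return series[t]


@dataclass
class PairwiseModelBank:
    """Six binary logistic models, one per unordered object pair."""

    models: dict[frozenset, LogisticRegression]
    l2_weight: float = 1.0

    def model_for(self, a: str, b: str) -> LogisticRegression:
        key = frozenset((a, b))
        if key not in self.models:
            raise KeyError(f"no model for pair {sorted(key)}")
        return self.models[key]

    def prob_of(self, pattern: np.ndarray, target: str, other: str) -> float:
        """Probability that ``pattern`` is ``target`` under the (target, other) model."""
        model = self.model_for(target, other)
        pattern = np.asarray(pattern, dtype=float).reshape(1, -1)
        proba = model.predict_proba(pattern)[0]
        idx = list(model.classes_).index(target)
        return float(proba[idx])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "l2_weight": self.l2_weight,
            "models": [
                {
                    "pair": sorted(key),
                    "classes": list(m.classes_),
                    "coef": m.coef_.tolist(),
                    "intercept": m.intercept_.tolist(),
                }
                for key, m in self.models.items()
            ],
        }
        Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class EvidenceScore:
    """Mean probability for ``target`` from its two against-control models."""

    target: str
    value: float
    constituents: tuple[float, float]


def make_classifier(l2_weight: float = 1.0, weight_is_c: bool = False) -> LogisticRegression:
    """L2-regularized logistic regression with a fixed, deterministic solver.

    ``l2_weight`` is by default the weight on the squared-norm penalty term,
    i.e. sklearn's C = 1 / l2_weight. Some conventions quote the inverse
    strength directly; pass ``weight_is_c=True`` to treat the value as C.
    The two readings coincide at the protocol's setting of 1.
    """
    c = l2_weight if weight_is_c else 1.0 / l2_weight
    # L2 is sklearn's default penalty; C is the inverse regularization strength
    return LogisticRegression(C=c, solver="lbfgs", max_iter=2000)


def train_pairwise_classifiers(
    patterns: np.ndarray,
    labels: np.ndarray,
    l2_weight: float = 1.0,
    weight_is_c: bool = False,
) -> PairwiseModelBank:
    """Train one binary model per unordered pair of the four objects.

    Each model sees only that pair's trials. Raises if any object has fewer
    than two examples.
    """
    patterns = np.asarray(patterns, dtype=float)
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    missing = set(OBJECTS) - present
    if missing:
        raise TrainingError(f"missing training examples for objects: {sorted(missing)}")
    for obj in OBJECTS:
        if int(np.sum(labels == obj)) < 2:
            raise TrainingError(f"need >= 2 examples of {obj}")
    models: dict[frozenset, LogisticRegression] = {}
    for a, b in itertools.combinations(OBJECTS, 2):
        mask = np.isin(labels, (a, b))
        clf = make_classifier(l2_weight, weight_is_c)
        clf.fit(patterns[mask], labels[mask])
        models[frozenset((a, b))] = clf
    return PairwiseModelBank(models=models, l2_weight=l2_weight)


def train_bank_from_dataset(dataset: PatternDataset, **kwargs) -> PairwiseModelBank:
    return train_pairwise_classifiers(dataset.data, dataset.labels, **kwargs)


def object_evidence(
    pattern: np.ndarray,
    bank: PairwiseModelBank,
    target: str,
    controls: tuple[str, str],
) -> EvidenceScore:
    """Evidence for ``target``: mean of its two against-control probabilities."""
    if target in controls:
        raise ValueError("target must not be one of the controls")
    p1 = bank.prob_of(pattern, target, controls[0])
    p2 = bank.prob_of(pattern, target, controls[1])
    return EvidenceScore(target=target, value=(p1 + p2) / 2.0, constituents=(p1, p2))


def coactivation_index(presented_ev: float, competitor_ev: float) -> float:
    """Coactivation of presented and competitor: the product of their evidences."""
    for v in (presented_ev, competitor_ev):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"evidence {v} outside [0, 1]")
    return presented_ev * competitor_ev
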