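"""Data-driven feedback-ROI construction.

Voxels are grouped into disjoint parcels (the synthetic analogue of atlas
parcels). Each parcel is scored by leave-one-run-out four-way decoding
accuracy; a *mega ROI* is then refined by greedy backward elimination: at
each subset size every single-parcel removal is evaluated by cross-validated
accuracy, the best removal is kept, and the best-scoring subset over all
sizes becomes the feedback ROI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .realtime_decoding import make_classifier
from .synthetic_data import PatternDataset


class CvError(ValueError):
    pass


@dataclass
class Parcellation:
    """Disjoint parcel_id -> voxel-index-set mapping."""

    parcels: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pid, idx in self.parcels.items():
            idx = np.asarray(idx, dtype=int)
            self.parcels[pid] = idx
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"parcel {pid} overlaps earlier parcels at voxels {sorted(overlap)[:5]}")
            seen.update(idx.tolist())

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)

    def voxels_of(self, parcel_ids) -> np.ndarray:
        idx = np.concatenate([self.parcels[p] for p in parcel_ids])
        return np.sort(idx)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({str(p): idx.tolist() for p, idx in self.parcels.items()})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Parcellation":
        raw = json.loads(Path(path).read_text())
        return cls({int(p): np.asarray(idx, dtype=int) for p, idx in raw.items()})

    @classmethod
    def contiguous(cls, n_voxels: int, n_parcels: int) -> "Parcellation":
        """Even split of the voxel range into contiguous parcels."""
        bounds = np.linspace(0, n_voxels, n_parcels + 1).astype(int)
        return cls({p: np.arange(bounds[p], bounds[p + 1]) for p in range(n_parcels)})


@dataclass
class MegaRoi:
    included_parcels: list[int]
    voxels: np.ndarray
    score: float
    #: (subset size, removed parcel id or None, best score at that size)
    trajectory: list[tuple[int, "int | None", float]] = field(default_factory=list)


def four_way_cv_accuracy(
    dataset: PatternDataset, voxel_idx: np.ndarray, l2_weight: float = 1.0
) -> float:
    """Leave-one-run-out four-way classification accuracy on a voxel subset.

    The four-way decision composes the binary machinery as one-vs-rest
    logistic models with an argmax over class probabilities (sklearn's
    multinomial logistic would serve equally; one-vs-rest is kept for
    parity with the pairwise feedback models).
    """
    run_ids = dataset.run_ids
    if run_ids.size < 2:
        raise CvError("leave-one-run-out needs at least 2 runs")
    data = dataset.data[:, voxel_idx]
    correct = total = 0
    for run in run_ids:
        test = dataset.runs == run
        clf = make_classifier(l2_weight)
        clf.fit(data[~test], dataset.labels[~test])
        pred = clf.predict(data[test])
        correct += int(np.sum(pred == dataset.labels[test]))
        total += int(np.sum(test))
    return correct / total


def score_parcels(
    dataset: PatternDataset, parcellation: Parcellation, l2_weight: float = 1.0
) -> list[tuple[int, float]]:
    """Per-parcel cross-validated accuracy, ranked descending.

    Ties are broken by lower parcel id first, making the ranking (and
    everything downstream of it) deterministic.
    """
    scores = []
    for pid in sorted(parcellation.parcels):
        idx = parcellation.parcels[pid]
        if idx.size == 0:
            raise ValueError(f"parcel {pid} is empty")
        scores.append((pid, four_way_cv_accuracy(dataset, idx, l2_weight)))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


def top_n_curve(
    dataset: PatternDataset,
    parcellation: Parcellation,
    ranked: list[tuple[int, float]] | None = None,
    l2_weight: float = 1.0,
) -> list[tuple[int, float]]:
    """Pooled accuracy of the top-N parcels for every N, per the ranking."""
    if ranked is None:
        ranked = score_parcels(dataset, parcellation, l2_weight)
    curve = []
    for n in range(1, len(ranked) + 1):
        ids = [pid for pid, _ in ranked[:n]]
        curve.append((n, four_way_cv_accuracy(dataset, parcellation.voxels_of(ids), l2_weight)))
    return curve


def greedy_backward_eliminate(
    dataset: PatternDataset,
    parcellation: Parcellation,
    starting_parcels: list[int] | None = None,
    l2_weight: float = 1.0,
) -> MegaRoi:
    """Greedy backward parcel elimination under leave-one-run-out accuracy.

    From the starting set, each step removes the parcel whose removal gives
    the highest cross-validated accuracy (ties: remove the lowest id),
    recording the best score at each subset size down to one parcel. The
    returned ROI is the best-scoring subset over all visited sizes, with its
    score re-evaluated on the final subset.
    """
    current = sorted(parcellation.parcels if starting_parcels is None else starting_parcels)
    if not current:
        raise ValueError("starting parcel set must be non-empty")
    trajectory: list[tuple[int, "int | None", float]] = []
    full_score = four_way_cv_accuracy(dataset, parcellation.voxels_of(current), l2_weight)
    trajectory.append((len(current), None, full_score))
    best_subset, best_score = list(current), full_score

    while len(current) > 1:
        step_best: tuple[float, int] | None = None  # (score, parcel to remove)
        for pid in current:
            remaining = [p for p in current if p != pid]
            score = four_way_cv_accuracy(dataset, parcellation.voxels_of(remaining), l2_weight)
            if step_best is None or score > step_best[0] or (
                score == step_best[0] and pid < step_best[1]
            ):
                step_best = (score, pid)
        score, removed = step_best
        current = [p for p in current if p != removed]
        trajectory.append((len(current), removed, score))
        if score > best_score:
            best_subset, best_score = list(current), score

    final_score = four_way_cv_accuracy(dataset, parcellation.voxels_of(best_subset), l2_weight)
    return MegaRoi(
        included_parcels=best_subset,
        voxels=parcellation.voxels_of(best_subset),
        score=final_score,
        trajectory=trajectory,
    )


def write_trajectory(roi: MegaRoi, path: str | Path) -> None:
    lines = ["size\tremoved_parcel\tscore"]
    for size, removed, score in roi.trajectory:
        lines.append(f"{size}\t{'' if removed is None else removed}\t{score:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
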