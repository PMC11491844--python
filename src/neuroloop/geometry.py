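"""Vector-geometric decomposition of representational change.

For each object pair (axis), the pre-training mean patterns define two
orthogonal directions in voxel space: the *shared* direction is the sum of
the two unit-normalized object vectors, the *unique* direction their
difference. Projections of the un-normalized session means onto these
directions, compared post minus pre, separate an increase in shared
features from a loss of unique features.

Each object's unique projection is taken along its own signed sense of the
unique direction (the first object along +u, the second along -u), so that
"expression of unique features" is positive for both objects and a
symmetric shrink of both objects' unique components registers as a negative
change rather than cancelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import AXES, OBJECTS, PatternDataset


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class AxisGeometry:
    axis: str
    shared: np.ndarray  # unit vector
    unique: np.ndarray  # unit vector, oriented first-object-positive


@dataclass
class ProjectionChange:
    """Post-minus-pre projection changes, per axis and direction.

    ``d_shared[axis]`` / ``d_unique[axis]`` sum the change over the axis's
    two objects. The trained-minus-untrained differences are the quantities
    interpreted as relative shared gain / unique loss.
    """

    d_shared: dict[str, float]
    d_unique: dict[str, float]

    @property
    def shared_contrast(self) -> float:
        return self.d_shared["trained"] - self.d_shared["untrained"]

    @property
    def unique_contrast(self) -> float:
        return self.d_unique["trained"] - self.d_unique["untrained"]


def mean_center_run(series: np.ndarray) -> np.ndarray:
    """Remove each voxel's mean over the run timecourse."""
    series = np.asarray(series, dtype=float)
    return series - series.mean(axis=0, keepdims=True)


def mean_center_dataset(dataset: PatternDataset) -> PatternDataset:
    """Mean-center each voxel's trial series within each run."""
    data = dataset.data.copy()
    for run in dataset.run_ids:
        mask = dataset.runs == run
        data[mask] = mean_center_run(data[mask])
    return PatternDataset(data, dataset.labels.copy(), dataset.runs.copy(), dataset.session, dataset.seed)


def object_mean_vectors(dataset: PatternDataset) -> dict[str, np.ndarray]:
    """Per-object mean pattern across all trials and runs, after per-run centering."""
    centered = mean_center_dataset(dataset)
    means = {}
    for obj in OBJECTS:
        mask = centered.labels == obj
        if not mask.any():
            raise ValueError(f"no trials for object {obj}")
        means[obj] = centered.data[mask].mean(axis=0)
    return means


def shared_unique_directions(v_a: np.ndarray, v_b: np.ndarray, axis: str = "axis") -> AxisGeometry:
    """Orthogonal shared/unique unit directions from a pair of mean patterns.

    Both inputs are unit-normalized first; shared = normalize(a_hat + b_hat),
    unique = normalize(a_hat - b_hat). For unit inputs these are orthogonal
    by the identity (a+b).(a-b) = |a|^2 - |b|^2 = 0.
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    na, nb = np.linalg.norm(v_a), np.linalg.norm(v_b)
    if na == 0 or nb == 0:
        raise DegenerateGeometryError("zero-length mean pattern")
    a_hat, b_hat = v_a / na, v_b / nb
    diff = a_hat - b_hat
    if np.linalg.norm(diff) < 1e-12:
        raise DegenerateGeometryError("identical mean patterns: unique direction undefined")
    shared = (a_hat + b_hat) / np.linalg.norm(a_hat + b_hat)
    unique = diff / np.linalg.norm(diff)
    return AxisGeometry(axis=axis, shared=shared, unique=unique)


def _axis_projections(
    means: dict[str, np.ndarray], geom: AxisGeometry, pair: tuple[str, str]
) -> tuple[float, float]:
    """(sum of shared projections, sum of signed unique projections)."""
    a, b = pair
    p_shared = float(means[a] @ geom.shared + means[b] @ geom.shared)
    # first object along +u, second along -u: both positive when each object
    # expresses its own unique features
    p_unique = float(means[a] @ geom.unique - means[b] @ geom.unique)
    return p_shared, p_unique


def projection_change(
    means_s1: dict[str, np.ndarray],
    means_s5: dict[str, np.ndarray],
    geometries: dict[str, AxisGeometry] | None = None,
) -> ProjectionChange:
    """Post-minus-pre shared/unique projection changes for both axes.

    Directions default to those derived from the pre-training means of the
    same axis (as they must be: the shared features are estimated from the
    initial representations themselves).
    """
    if geometries is None:
        geometries = {
            axis: shared_unique_directions(means_s1[pair[0]], means_s1[pair[1]], axis=axis)
            for axis, pair in AXES.items()
        }
    d_shared, d_unique = {}, {}
    for axis, pair in AXES.items():
        geom = geometries[axis]
        s1_sh, s1_un = _axis_projections(means_s1, geom, pair)
        s5_sh, s5_un = _axis_projections(means_s5, geom, pair)
        d_shared[axis] = s5_sh - s1_sh
        d_unique[axis] = s5_un - s1_un
    return ProjectionChange(d_shared=d_shared, d_unique=d_unique)


def geometric_integration_index(change: ProjectionChange) -> float:
    """Overall integration: shared gain plus unique loss, trained vs untrained.

    index = (trained-minus-untrained increase in the shared projection)
          + (trained-minus-untrained decrease in the unique projection).
    Positive = integration. A pure unique-feature loss contributes through
    the second term only; a pure shared gain through the first only.
    """
    return change.shared_contrast - change.unique_contrast


def geometry_for_datasets(
    dataset_s1: PatternDataset, dataset_s5: PatternDataset
) -> tuple[ProjectionChange, float]:
    """End-to-end geometric analysis from two sessions' pattern datasets."""
    means_s1 = object_mean_vectors(dataset_s1)
    means_s5 = object_mean_vectors(dataset_s5)
    change = projection_change(means_s1, means_s5)
    return change, geometric_integration_index(change)
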