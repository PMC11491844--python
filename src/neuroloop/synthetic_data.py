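"""Synthetic multivoxel data generation with known ground truth.

This module fabricates every input the downstream analyses consume:

* object *templates* in voxel space, built from orthonormal shared and
  unique components so that representational integration can be implanted
  exactly (shrink the unique components of the trained pair, optionally
  amplify their shared component);
* recognition-run trial *schedules* (balanced per quarter, no back-to-back
  repetitions of an object);
* trial-locked activity *patterns* (template + i.i.d. Gaussian voxel noise);
* per-TR classifier-evidence streams from a simulated participant whose
  competitor evidence grows across feedback sessions;
* forced-choice categorical-perception responses on a 13-step morph
  continuum governed by a logistic model.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

OBJECTS = ("presented", "competitor", "control1", "control2")
TRAINED_PAIR = ("presented", "competitor")
UNTRAINED_PAIR = ("control1", "control2")
AXES = {"trained": TRAINED_PAIR, "untrained": UNTRAINED_PAIR}

#: morph percentages sampled by the categorical perception task
MORPH_STEPS = (18, 26, 34, 38, 42, 46, 50, 54, 58, 62, 66, 74, 82)

#: TRs between the object onset and the pattern read-out (2 s TRs, 4 s lag)
HEMODYNAMIC_LAG_TRS = 2


class ScheduleError(RuntimeError):
    """Raised when a trial schedule satisfying the constraints cannot be built."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Design parameters of one simulated participant's recognition data.

    The defaults mirror the multi-session protocol: 4 objects, 8 recognition
    runs per pre/post session, 48 trials per run (12 per object, 3 per
    quarter). ``noise_sd`` is the per-voxel trial noise in template units;
    the default of 0.75 with unit component scales puts pairwise decoding
    in a decodable-but-imperfect regime (cross-validated AUC roughly
    0.7-0.9).
    """

    n_voxels: int = 200
    n_runs_per_session: int = 8
    trials_per_run: int = 48
    n_objects: int = 4
    noise_sd: float = 0.75
    shared_scale: float = 1.0
    unique_scale: float = 1.0
    unique_shrink: float = 0.5
    shared_gain: float = 1.0
    seed: int = 0
    lag_trs: int = HEMODYNAMIC_LAG_TRS

    def __post_init__(self) -> None:
        if self.n_objects != 4:
            raise ValueError("the protocol uses exactly 4 objects")
        if self.n_voxels < 6:
            raise ValueError(
                "n_voxels must be >= 6 to hold 2 shared + 4 unique orthogonal components"
            )
        if self.trials_per_run % self.n_objects:
            raise ValueError("trials_per_run must be divisible by n_objects")
        if not 0.0 <= self.unique_shrink <= 1.0:
            raise ValueError("unique_shrink must lie in [0, 1]")
        if self.shared_gain < 1.0:
            raise ValueError("shared_gain must be >= 1")
        if self.noise_sd < 0 or self.shared_scale < 0 or self.unique_scale < 0:
            raise ValueError("scales and noise_sd must be nonnegative")


@dataclass(frozen=True)
class ObjectTemplateSet:
    """Ground-truth voxel templates built from orthonormal components.

    ``shared`` maps axis name -> unit component shared by that axis's pair;
    ``unique`` maps object name -> that object's unit component. Each
    template is ``shared_scale * shared[axis] + unique_scale * unique[obj]``
    with per-axis effective scales so that integration can be implanted on
    the trained pair only.
    """

    shared: dict[str, np.ndarray]
    unique: dict[str, np.ndarray]
    shared_scales: dict[str, float]
    unique_scales: dict[str, float]

    def axis_of(self, obj: str) -> str:
        return "trained" if obj in TRAINED_PAIR else "untrained"

    def template(self, obj: str) -> np.ndarray:
        axis = self.axis_of(obj)
        return (
            self.shared_scales[axis] * self.shared[axis]
            + self.unique_scales[obj] * self.unique[obj]
        )

    @property
    def templates(self) -> dict[str, np.ndarray]:
        return {obj: self.template(obj) for obj in OBJECTS}

    def component_matrix(self) -> np.ndarray:
        """All six components stacked as rows (2 shared then 4 unique)."""
        rows = [self.shared[a] for a in ("trained", "untrained")]
        rows += [self.unique[o] for o in OBJECTS]
        return np.vstack(rows)


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered recognition trials: (trial_index, object_label, onset_TR)."""

    objects: tuple[str, ...]
    onsets: tuple[int, ...]
    quarters: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.objects)


@dataclass(frozen=True)
class AgentProfile:
    """A feedback-controllable simulated participant.

    Competitor evidence at session ``s`` (1-based) is drawn per TR from a
    clipped Gaussian with mean ``baseline + gain * (s - 1)``; presented
    evidence is stationary around ``presented_mean``. All evidence lives on
    the classifier-probability scale [0, 1].
    """

    baseline: float = 0.45
    gain: float = 0.10
    noise_sd: float = 0.15
    presented_mean: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline <= 1.0 and 0.0 <= self.presented_mean <= 1.0):
            raise ValueError("evidence means must lie in [0, 1]")
        if self.gain < 0 or self.noise_sd < 0:
            raise ValueError("gain and noise_sd must be nonnegative")


@dataclass
class PatternDataset:
    """Trial x voxel activity with object labels and run/session indices."""

    data: np.ndarray  # (n_trials, n_voxels)
    labels: np.ndarray  # (n_trials,) object names
    runs: np.ndarray  # (n_trials,) 0-based run index
    session: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.runs = np.asarray(self.runs, dtype=int)
        if not (len(self.data) == len(self.labels) == len(self.runs)):
            raise ValueError("data, labels and runs must have equal length")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def run_ids(self) -> np.ndarray:
        return np.unique(self.runs)

    def subset_pair(self, pair: Sequence[str]) -> "PatternDataset":
        mask = np.isin(self.labels, list(pair))
        return PatternDataset(
            self.data[mask], self.labels[mask], self.runs[mask], self.session, self.seed
        )

    def select_voxels(self, idx: Sequence[int]) -> "PatternDataset":
        idx = np.asarray(idx, dtype=int)
        return PatternDataset(
            self.data[:, idx], self.labels.copy(), self.runs.copy(), self.session, self.seed
        )


@dataclass
class BehaviouralDataset:
    """Forced-choice responses per (axis, session): morph x -> binary choice."""

    frame: pd.DataFrame  # columns: axis, session, morph, response

    def slice(self, axis: str, session: int) -> pd.DataFrame:
        f = self.frame
        return f[(f["axis"] == axis) & (f["session"] == session)]


# ---------------------------------------------------------------------------
# templates


def make_templates(config: SyntheticConfig) -> ObjectTemplateSet:
    """Build the six orthonormal components and assemble object templates.

    Components are seeded standard-normal vectors orthonormalized by
    QR decomposition (equivalent to Gram-Schmidt up to per-vector signs,
    which are fixed so the decomposition is deterministic).
    """
    rng = np.random.default_rng(config.seed)
    raw = rng.standard_normal((config.n_voxels, 6))
    q, r = np.linalg.qr(raw)
    # fix the sign convention so the result matches classical Gram-Schmidt
    q = q * np.sign(np.diag(r))
    comps = q.T  # 6 orthonormal voxel-length vectors
    shared = {"trained": comps[0], "untrained": comps[1]}
    unique = {obj: comps[2 + i] for i, obj in enumerate(OBJECTS)}
    return ObjectTemplateSet(
        shared=shared,
        unique=unique,
        shared_scales={"trained": config.shared_scale, "untrained": config.shared_scale},
        unique_scales={obj: config.unique_scale for obj in OBJECTS},
    )


def implant_integration(
    templates: ObjectTemplateSet, unique_shrink: float, shared_gain: float = 1.0
) -> ObjectTemplateSet:
    """Return post-training templates with the trained pair integrated.

    The trained pair's unique components are multiplied by ``unique_shrink``
    (0 = fully collinear pair) and its shared component by ``shared_gain``;
    the untrained pair is untouched. This is the ground-truth analogue of
    losing object-unique neural features while preserving shared ones.
    """
    if not 0.0 <= unique_shrink <= 1.0:
        raise ValueError("unique_shrink must lie in [0, 1]")
    if shared_gain < 1.0:
        raise ValueError("shared_gain must be >= 1")
    unique_scales = dict(templates.unique_scales)
    for obj in TRAINED_PAIR:
        unique_scales[obj] = unique_scales[obj] * unique_shrink
    shared_scales = dict(templates.shared_scales)
    shared_scales["trained"] = shared_scales["trained"] * shared_gain
    return replace(templates, shared_scales=shared_scales, unique_scales=unique_scales)


# ---------------------------------------------------------------------------
# schedules


def make_recognition_schedule(
    config: SyntheticConfig, seed: int, trial_spacing_trs: int = 3, max_attempts: int = 10_000
) -> TrialSchedule:
    """Balanced recognition-run schedule with no back-to-back repetitions.

    Trials are split into four quarters; each quarter contains each object
    equally often (3 times under the default 48-trial design). Quarters are
    shuffled independently and re-drawn until no two consecutive trials
    (including across quarter boundaries) share an object.
    """
    n_obj = config.n_objects
    if config.trials_per_run % (4 * n_obj):
        raise ScheduleError("trials_per_run must be divisible by 4 * n_objects")
    per_quarter = config.trials_per_run // 4
    reps = per_quarter // n_obj
    if n_obj < 2:
        raise ScheduleError("need at least 2 objects to avoid back-to-back repeats")
    rng = np.random.default_rng(seed)
    quarter_pool = np.repeat(np.arange(n_obj), reps)

    order: list[int] = []
    for _ in range(4):
        for attempt in range(max_attempts):
            cand = rng.permutation(quarter_pool)
            if np.any(cand[1:] == cand[:-1]):
                continue
            if order and cand[0] == order[-1]:
                continue
            order.extend(int(c) for c in cand)
            break
        else:
            raise ScheduleError("could not satisfy the no-repeat constraint")

    objects = tuple(OBJECTS[i] for i in order)
    onsets = tuple(i * trial_spacing_trs for i in range(config.trials_per_run))
    quarters = tuple(i // per_quarter for i in range(config.trials_per_run))
    return TrialSchedule(objects=objects, onsets=onsets, quarters=quarters)


# ---------------------------------------------------------------------------
# pattern simulation


def simulate_recognition_session(
    templates: ObjectTemplateSet,
    schedules: Sequence[TrialSchedule],
    noise_sd: float,
    seed: int,
    session: int = 1,
) -> PatternDataset:
    """One trial pattern per scheduled trial: template + Gaussian voxel noise."""
    rng = np.random.default_rng(seed)
    tpl = templates.templates
    n_voxels = next(iter(tpl.values())).shape[0]
    rows, labels, runs = [], [], []
    for run_idx, sched in enumerate(schedules):
        for obj in sched.objects:
            rows.append(tpl[obj] + rng.normal(0.0, noise_sd, size=n_voxels))
            labels.append(obj)
            runs.append(run_idx)
    return PatternDataset(
        data=np.vstack(rows),
        labels=np.array(labels),
        runs=np.array(runs),
        session=session,
        seed=seed,
    )


def simulate_run_timeseries(
    templates: ObjectTemplateSet,
    schedule: TrialSchedule,
    noise_sd: float,
    seed: int,
    n_trs: int = 145,
    lag_trs: int = HEMODYNAMIC_LAG_TRS,
) -> np.ndarray:
    """TR x voxel run timeseries with each trial's template placed at its
    lagged TR (onset + lag) on top of baseline noise.

    This is the raw-timecourse view of a recognition run, for exercising the
    causal normalization and trial-extraction path end to end.
    """
    rng = np.random.default_rng(seed)
    tpl = templates.templates
    n_voxels = next(iter(tpl.values())).shape[0]
    series = rng.normal(0.0, noise_sd, size=(n_trs, n_voxels))
    for obj, onset in zip(schedule.objects, schedule.onsets):
        t = onset + lag_trs
        if t >= n_trs:
            raise ScheduleError(f"trial at onset {onset} falls outside the {n_trs}-TR run")
        series[t] += tpl[obj]
    return series


# ---------------------------------------------------------------------------
# agent evidence


def simulate_agent_evidence(
    profile: AgentProfile,
    n_sessions: int = 3,
    runs_per_session: int = 10,
    trials_per_run: int = 16,
    trs_per_trial: int = 5,
) -> np.ndarray:
    """Per-TR (competitor, presented) evidence for every feedback trial.

    Returns an array of shape
    ``(n_sessions, runs_per_session, trials_per_run, trs_per_trial, 2)``
    where the last axis is (competitor, presented). Values are clipped to
    [0, 1], the scale of classifier probability outputs.
    """
    rng = np.random.default_rng(profile.seed)
    shape = (n_sessions, runs_per_session, trials_per_run, trs_per_trial)
    comp_mean = profile.baseline + profile.gain * np.arange(n_sessions)
    comp = rng.normal(comp_mean[:, None, None, None], profile.noise_sd, size=shape)
    pres = rng.normal(profile.presented_mean, profile.noise_sd, size=shape)
    out = np.stack([comp, pres], axis=-1)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# behaviour


def logistic_response_probability(x: np.ndarray, mu: float, slope: float) -> np.ndarray:
    """P(choose object B) under the categorical-perception logistic model.

    ``slope`` is the steepness beta = 1/s of p(x) = 1 / (1 + exp(-(x - mu)/s)).
    """
    z = np.clip(slope * (np.asarray(x, dtype=float) - mu), -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_behaviour(
    mu: float,
    slope: float,
    reps_per_step: int = 12,
    seed: int = 0,
    axis: str = "trained",
    session: int = 1,
) -> BehaviouralDataset:
    """Bernoulli forced-choice responses at the 13 printed morph steps."""
    if not 0.0 <= mu <= 100.0:
        raise ValueError("mu must lie on the 0-100 morph scale")
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    rng = np.random.default_rng(seed)
    records = []
    for x in MORPH_STEPS:
        p = float(logistic_response_probability(x, mu, slope))
        resp = rng.random(reps_per_step) < p
        for r in resp:
            records.append({"axis": axis, "session": session, "morph": x, "response": int(r)})
    return BehaviouralDataset(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# serialization


def write_pattern_dataset(dataset: PatternDataset, path: str | Path) -> None:
    """Write a dataset as TSV (trial x voxel) plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(dataset.data).to_csv(path, sep="\t", header=False, index=False)
    meta = {
        "labels": dataset.labels.tolist(),
        "runs": dataset.runs.tolist(),
        "session": dataset.session,
        "seed": dataset.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_pattern_dataset(path: str | Path) -> PatternDataset:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    return PatternDataset(
        data=data,
        labels=np.array(meta["labels"]),
        runs=np.array(meta["runs"]),
        session=int(meta["session"]),
        seed=meta.get("seed"),
    )


def write_behavioural_dataset(dataset: BehaviouralDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, sep="\t", index=False)


def read_behavioural_dataset(path: str | Path) -> BehaviouralDataset:
    frame = pd.read_csv(path, sep="\t")
    required = {"axis", "session", "morph", "response"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"behavioural file {path} is missing columns: {sorted(missing)}")
    return BehaviouralDataset(frame)


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SyntheticConfig:
    return SyntheticConfig(**d)
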