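"""The closed-loop neurofeedback protocol.

Each feedback trial spans 5 TRs. On every TR, the running average of the
competitor-evidence values collected so far in the trial is compared with an
adaptive threshold (strictly greater-than). The displayed wobble level is
held at the maximum (13) for a 3-TR hemodynamic lead-in and thereafter maps
the accumulated above-threshold count to a level: 0 -> 13, 1 -> 9, 2 -> 5,
3-5 -> 1. Each level corresponds to a fixed morph interval of the 1-100
continuum. After the trial the final count determines a monetary bonus and
a valenced emoji. The threshold follows a criterion-based up/down staircase
so that the required evidence tracks the participant's ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LEAD_IN_TRS = 3
TRS_PER_TRIAL = 5

#: wobble level -> (ascending interval, mirrored descending interval)
MORPH_RANGES = {
    13: ((1, 40), (100, 60)),
    9: ((1, 28), (100, 72)),
    5: ((1, 16), (100, 84)),
    1: ((1, 4), (100, 96)),
}

#: final above-threshold count -> (bonus cents, emoji)
REWARDS = {
    0: (0, "unhappy"),
    1: (0, "neutral"),
    2: (5, "smiling"),
    3: (5, "smiling"),
    4: (10, "laughing"),
    5: (10, "laughing"),
}

COUNT_TO_LEVEL = {0: 13, 1: 9, 2: 5, 3: 1, 4: 1, 5: 1}


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StaircaseState:
    """Adaptive evidence threshold with its update history.

    The threshold rises by ``step_up`` when recent trials average at least
    ``raise_criterion`` above-threshold TRs, falls by ``step_down`` when they
    average at most ``lower_criterion``, and is clamped to [0, 1].
    """

    threshold: float = 0.5
    step_up: float = 0.05
    step_down: float = 0.05
    raise_criterion: float = 3.0
    lower_criterion: float = 1.0
    history: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class TrialOutcome:
    evidences: tuple[float, ...]
    running_avgs: tuple[float, ...]
    above_flags: tuple[bool, ...]
    count: int
    levels: tuple[int, ...]
    final_level: int
    cents: int
    emoji: str
    threshold: float


@dataclass
class RunResult:
    trials: list[TrialOutcome]
    threshold_before: float
    threshold_after: float

    @property
    def mean_count(self) -> float:
        return float(np.mean([t.count for t in self.trials]))

    @property
    def total_cents(self) -> int:
        return int(sum(t.cents for t in self.trials))


def classify_tr(evidence_running_avg: float, threshold: float) -> bool:
    """True iff the running-average evidence strictly exceeds the threshold."""
    if not (0.0 <= evidence_running_avg <= 1.0 and 0.0 <= threshold <= 1.0):
        raise ValueError("evidence and threshold must lie in [0, 1]")
    return evidence_running_avg > threshold


def wobble_level(count_above: int, tr_index: int) -> int:
    """Displayed wobble level given the accumulated count and 1-based TR index.

    The first three TRs are a hemodynamic lead-in pinned at the maximum
    level; from TR 4 the count-to-level mapping applies.
    """
    if count_above not in range(6):
        raise ValueError("count_above must be in 0..5")
    if tr_index not in range(1, TRS_PER_TRIAL + 1):
        raise ValueError("tr_index must be in 1..5")
    if tr_index <= LEAD_IN_TRS:
        return 13
    return COUNT_TO_LEVEL[count_above]


def morph_range(level: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Ascending and mirrored morph intervals rendered at a wobble level."""
    try:
        return MORPH_RANGES[level]
    except KeyError:
        raise KeyError(f"unknown wobble level {level}; valid: {sorted(MORPH_RANGES)}")


def trial_reward(count_above: int) -> tuple[int, str]:
    """Monetary bonus (cents) and emoji for a final above-threshold count."""
    try:
        return REWARDS[count_above]
    except KeyError:
        raise ValueError(f"count_above must be in 0..5, got {count_above}")


def staircase_update(state: StaircaseState, recent_counts: "list[int] | np.ndarray") -> StaircaseState:
    """One criterion-based up/down step from the recent trials' counts."""
    recent_counts = np.asarray(recent_counts, dtype=float)
    if recent_counts.size == 0:
        raise ValueError("need at least one trial outcome")
    mean_count = float(recent_counts.mean())
    threshold = state.threshold
    if mean_count >= state.raise_criterion:
        threshold += state.step_up
    elif mean_count <= state.lower_criterion:
        threshold -= state.step_down
    threshold = float(np.clip(threshold, 0.0, 1.0))
    history = state.history + ((len(state.history), threshold),)
    return replace(state, threshold=threshold, history=history)


def run_trial(evidences: "np.ndarray | list[float]", threshold: float) -> TrialOutcome:
    """Play one 5-TR feedback trial against a fixed threshold."""
    evidences = np.asarray(evidences, dtype=float)
    if evidences.shape[0] != TRS_PER_TRIAL:
        raise SimulationError(f"a trial needs {TRS_PER_TRIAL} evidence values")
    avgs, flags, levels = [], [], []
    count = 0
    for i, _ in enumerate(evidences, start=1):
        avg = float(evidences[:i].mean())
        above = classify_tr(avg, threshold)
        count += int(above)
        avgs.append(avg)
        flags.append(above)
        levels.append(wobble_level(count, i))
    cents, emoji = trial_reward(count)
    return TrialOutcome(
        evidences=tuple(float(e) for e in evidences),
        running_avgs=tuple(avgs),
        above_flags=tuple(flags),
        count=count,
        levels=tuple(levels),
        final_level=levels[-1],
        cents=cents,
        emoji=emoji,
        threshold=threshold,
    )


def simulate_feedback_run(
    evidence_stream: np.ndarray,
    state: StaircaseState,
    trials_per_run: int | None = None,
) -> tuple[RunResult, StaircaseState]:
    """Play one feedback run and apply one staircase update at its end.

    ``evidence_stream`` has shape (trials, 5) of competitor evidence. The
    threshold is held fixed within the run and updated once from the run's
    mean above-threshold count.
    """
    evidence_stream = np.asarray(evidence_stream, dtype=float)
    if trials_per_run is None:
        trials_per_run = evidence_stream.shape[0]
    if evidence_stream.shape[0] < trials_per_run:
        raise SimulationError("evidence stream exhausted before the run completed")
    before = state.threshold
    trials = [run_trial(evidence_stream[i], state.threshold) for i in range(trials_per_run)]
    state = staircase_update(state, [t.count for t in trials])
    return RunResult(trials=trials, threshold_before=before, threshold_after=state.threshold), state


def simulate_feedback_sessions(
    evidence: np.ndarray, state: StaircaseState
) -> tuple[list[list[RunResult]], StaircaseState, np.ndarray]:
    """Play all feedback sessions of an agent's competitor-evidence array.

    ``evidence`` has shape (sessions, runs, trials, 5). Returns the per-run
    results, the final staircase state, and the per-session mean threshold
    (the average of each run's operating threshold within the session).
    """
    evidence = np.asarray(evidence, dtype=float)
    results: list[list[RunResult]] = []
    session_thresholds = []
    for s in range(evidence.shape[0]):
        session_runs = []
        thresholds = []
        for r in range(evidence.shape[1]):
            run_result, state = simulate_feedback_run(evidence[s, r], state)
            session_runs.append(run_result)
            thresholds.append(run_result.threshold_before)
        results.append(session_runs)
        session_thresholds.append(float(np.mean(thresholds)))
    return results, state, np.asarray(session_thresholds)


def session_threshold_trend(per_session_thresholds: "np.ndarray | list[float]") -> float:
    """OLS slope of the (mean) threshold against 1-based session index."""
    y = np.asarray(per_session_thresholds, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 sessions for a trend")
    x = np.arange(1, y.size + 1, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def session_coactivation_means(evidence: np.ndarray) -> np.ndarray:
    """Mean presented x competitor coactivation per session.

    ``evidence`` has shape (sessions, runs, trials, 5, 2) with the last axis
    (competitor, presented), as produced by the synthetic agent.
    """
    evidence = np.asarray(evidence, dtype=float)
    comp = evidence[..., 0]
    pres = evidence[..., 1]
    prod = comp * pres
    return prod.reshape(prod.shape[0], -1).mean(axis=1)
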