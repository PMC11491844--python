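"""Experiment orchestration, configuration and serialization.

``run_experiment`` simulates a cohort of participants through the full
five-session protocol — pre-training recognition runs, three closed-loop
feedback sessions, post-training recognition runs and the two
categorical-perception tests — then runs every analysis (threshold and
coactivation trends, pre/post AUC integration, geometric decomposition,
psychometric slopes, group bootstrap, brain-behaviour correlation).

Participants differ in a latent *learning strength* in [0, 1] that scales
all three implanted effects (unique-feature shrinkage, feedback-evidence
gain, psychometric slope reduction) so that neural and behavioural
integration covary across participants, as a real cohort's would.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import feedback_loop, geometry, group_stats, psychometrics, representational_change
from .feedback_loop import StaircaseState
from .synthetic_data import (
    AgentProfile,
    BehaviouralDataset,
    PatternDataset,
    SyntheticConfig,
    implant_integration,
    make_recognition_schedule,
    make_templates,
    read_behavioural_dataset,
    read_pattern_dataset,
    simulate_agent_evidence,
    simulate_behaviour,
    simulate_recognition_session,
    write_behavioural_dataset,
    write_pattern_dataset,
)

logger = logging.getLogger("neuroloop")

MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to simulate and analyse one cohort."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    agent: AgentProfile = field(default_factory=AgentProfile)
    staircase: StaircaseState = field(default_factory=StaircaseState)
    n_participants: int = 20
    n_feedback_sessions: int = 3
    feedback_runs_per_session: int = 10
    feedback_trials_per_run: int = 16
    #: pre-training psychometric steepness (beta = 1/s) on both axes
    slope_s1: float = 0.2
    #: post-training trained-axis steepness at full learning strength
    slope_s5_trained: float = 0.12
    behaviour_reps_per_step: int = 12
    #: draw per-participant learning strengths from U(lo, hi); a degenerate
    #: (1, 1) range gives every participant the full implanted effect
    learning_strength_range: tuple[float, float] = (0.2, 1.0)
    n_bootstrap: int = 1000
    master_seed: int = 0


def null_config(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """A cohort with no implanted effects anywhere (for calibration)."""
    synth = SyntheticConfig(unique_shrink=1.0, shared_gain=1.0, **overrides)
    agent = AgentProfile(gain=0.0)
    base = ExperimentConfig()
    return ExperimentConfig(
        synthetic=synth,
        agent=agent,
        slope_s5_trained=base.slope_s1,
        master_seed=master_seed,
    )


@dataclass
class ParticipantReport:
    participant: int
    seed: int
    learning_strength: float
    session_thresholds: np.ndarray
    threshold_trend: float
    session_coactivation: np.ndarray
    coactivation_trend: float
    integration: representational_change.IntegrationResult
    projection_change: geometry.ProjectionChange
    geometric_index: float
    behavioural: psychometrics.BehaviouralIntegration


@dataclass
class GroupReport:
    participants: list[ParticipantReport]
    stats: dict[str, group_stats.BootstrapResult]
    brain_behaviour_r: float
    config: ExperimentConfig

    def participant_table(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "participant": p.participant,
                    "seed": p.seed,
                    "learning_strength": p.learning_strength,
                    "threshold_trend": p.threshold_trend,
                    "coactivation_trend": p.coactivation_trend,
                    "auc_s1_trained": p.integration.auc_s1["trained"],
                    "auc_s5_trained": p.integration.auc_s5["trained"],
                    "auc_s1_untrained": p.integration.auc_s1["untrained"],
                    "auc_s5_untrained": p.integration.auc_s5["untrained"],
                    "neural_index_trained": p.integration.index("trained"),
                    "neural_index_untrained": p.integration.index("untrained"),
                    "neural_contrast": p.integration.contrast,
                    "d_shared_contrast": p.projection_change.shared_contrast,
                    "d_unique_contrast": p.projection_change.unique_contrast,
                    "geometric_index": p.geometric_index,
                    "behavioural_index_trained": p.behavioural.index("trained"),
                    "behavioural_index_untrained": p.behavioural.index("untrained"),
                    "behavioural_contrast": p.behavioural.contrast,
                }
            )
        return pd.DataFrame(rows)


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-participant seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % MAX_SEED for s in ss.generate_state(n, dtype=np.uint32)]


def simulate_participant_sessions(
    config: ExperimentConfig, seed: int, learning_strength: float = 1.0
) -> tuple[PatternDataset, PatternDataset]:
    """Pre- and post-training recognition datasets for one participant.

    The implanted unique shrink interpolates between 1 (no change) and the
    configured value according to the participant's learning strength.
    """
    synth = replace(config.synthetic, seed=seed)
    rng = np.random.default_rng(seed)
    templates_s1 = make_templates(synth)
    shrink = 1.0 - learning_strength * (1.0 - synth.unique_shrink)
    gain = 1.0 + learning_strength * (synth.shared_gain - 1.0)
    templates_s5 = implant_integration(templates_s1, unique_shrink=shrink, shared_gain=gain)

    def session(templates, session_idx):
        sched_seeds = rng.integers(0, MAX_SEED, size=synth.n_runs_per_session)
        schedules = [make_recognition_schedule(synth, int(s)) for s in sched_seeds]
        return simulate_recognition_session(
            templates,
            schedules,
            synth.noise_sd,
            seed=int(rng.integers(0, MAX_SEED)),
            session=session_idx,
        )

    return session(templates_s1, 1), session(templates_s5, 5)


def simulate_participant_behaviour(
    config: ExperimentConfig, seed: int, learning_strength: float = 1.0
) -> BehaviouralDataset:
    """Categorical-perception responses for both axes and sessions."""
    rng = np.random.default_rng(seed)
    slope_trained_s5 = config.slope_s1 - learning_strength * (
        config.slope_s1 - config.slope_s5_trained
    )
    frames = []
    for axis in ("trained", "untrained"):
        for session, slope in ((1, config.slope_s1), (5, config.slope_s1)):
            if axis == "trained" and session == 5:
                slope = slope_trained_s5
            ds = simulate_behaviour(
                mu=50.0,
                slope=slope,
                reps_per_step=config.behaviour_reps_per_step,
                seed=int(rng.integers(0, MAX_SEED)),
                axis=axis,
                session=session,
            )
            frames.append(ds.frame)
    return BehaviouralDataset(pd.concat(frames, ignore_index=True))


def run_participant(
    config: ExperimentConfig, participant: int, seed: int, learning_strength: float
) -> ParticipantReport:
    """Simulate and analyse one participant end to end."""
    logger.info("participant %d seed %d strength %.3f", participant, seed, learning_strength)
    dataset_s1, dataset_s5 = simulate_participant_sessions(config, seed, learning_strength)

    integration = representational_change.integration_for_roi(
        dataset_s1, dataset_s5, roi="whole_roi"
    )
    change, geo_index = geometry.geometry_for_datasets(dataset_s1, dataset_s5)

    behaviour = simulate_participant_behaviour(config, seed + 1, learning_strength)
    behavioural, _ = psychometrics.analyse_behaviour(behaviour)

    agent = replace(
        config.agent, seed=seed + 2, gain=config.agent.gain * learning_strength
    )
    evidence = simulate_agent_evidence(
        agent,
        n_sessions=config.n_feedback_sessions,
        runs_per_session=config.feedback_runs_per_session,
        trials_per_run=config.feedback_trials_per_run,
    )
    _, _, session_thresholds = feedback_loop.simulate_feedback_sessions(
        evidence[..., 0], config.staircase
    )
    threshold_trend = feedback_loop.session_threshold_trend(session_thresholds)
    coactivation = feedback_loop.session_coactivation_means(evidence)
    coactivation_trend = feedback_loop.session_threshold_trend(coactivation)

    return ParticipantReport(
        participant=participant,
        seed=seed,
        learning_strength=learning_strength,
        session_thresholds=session_thresholds,
        threshold_trend=threshold_trend,
        session_coactivation=coactivation,
        coactivation_trend=coactivation_trend,
        integration=integration,
        projection_change=change,
        geometric_index=geo_index,
        behavioural=behavioural,
    )


def run_experiment(config: ExperimentConfig, out_dir: "str | Path | None" = None) -> GroupReport:
    """Simulate the whole cohort and compute every group statistic."""
    seeds = child_seeds(config.master_seed, config.n_participants + 1)
    strength_rng = np.random.default_rng(seeds[-1])
    lo, hi = config.learning_strength_range
    strengths = strength_rng.uniform(lo, hi, size=config.n_participants)

    participants = [
        run_participant(config, i, seeds[i], float(strengths[i]))
        for i in range(config.n_participants)
    ]

    table = GroupReport(participants, {}, np.nan, config).participant_table()
    stats: dict[str, group_stats.BootstrapResult] = {}
    stat_columns = [
        "threshold_trend",
        "coactivation_trend",
        "neural_index_trained",
        "neural_index_untrained",
        "neural_contrast",
        "d_shared_contrast",
        "d_unique_contrast",
        "geometric_index",
        "behavioural_index_trained",
        "behavioural_index_untrained",
        "behavioural_contrast",
    ]
    boot_seed = seeds[-1] ^ 0x5EED
    for i, col in enumerate(stat_columns):
        stats[col] = group_stats.bootstrap_mean(
            table[col].to_numpy(), n_iter=config.n_bootstrap, seed=(boot_seed + i) % MAX_SEED
        )
    r = group_stats.pearson(
        table["neural_index_trained"].to_numpy(),
        table["behavioural_index_trained"].to_numpy(),
    )
    report = GroupReport(participants=participants, stats=stats, brain_behaviour_r=r, config=config)
    if out_dir is not None:
        write_group_report(report, out_dir)
    return report


# ---------------------------------------------------------------------------
# serialization


def config_to_yaml(config: ExperimentConfig, path: "str | Path | None" = None) -> str:
    d = dataclasses.asdict(config)
    d["staircase"].pop("history", None)
    text = yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source: str | Path) -> ExperimentConfig:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    d = yaml.safe_load(text)
    d["synthetic"] = SyntheticConfig(**d.get("synthetic", {}))
    d["agent"] = AgentProfile(**d.get("agent", {}))
    d["staircase"] = StaircaseState(**d.get("staircase", {}))
    if "learning_strength_range" in d:
        d["learning_strength_range"] = tuple(d["learning_strength_range"])
    return ExperimentConfig(**d)


def write_group_report(report: GroupReport, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.participant_table().to_csv(out_dir / "participants.tsv", sep="\t", index=False)
    stats_payload = {
        name: {
            "observed_mean": res.observed_mean,
            "ci_lower": res.ci_lower,
            "ci_upper": res.ci_upper,
            "p_sign": res.p_sign,
            "n_iterations": res.n_iterations,
            "seed": res.seed,
        }
        for name, res in report.stats.items()
    }
    stats_payload["brain_behaviour_r"] = report.brain_behaviour_r
    (out_dir / "group_stats.json").write_text(json.dumps(stats_payload, indent=2))
    config_to_yaml(report.config, out_dir / "config.yaml")


# thin re-exports so the orchestration module is the one-stop IO surface
write_dataset = write_pattern_dataset
read_dataset = read_pattern_dataset
write_behaviour = write_behavioural_dataset
read_behaviour = read_behavioural_dataset
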