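"""Simulate a small example cohort and write its raw data to disk.

Generates pre- and post-training recognition patterns (8 runs x 48 trials,
200 voxels) and categorical-perception responses for five participants
under the default effect configuration (trained-pair unique features shrink
to 50% at full learning strength), then writes TSV + JSON files under
results/cohort/.
"""

from pathlib import Path

from neuroloop.pipeline_io import (
    ExperimentConfig,
    child_seeds,
    simulate_participant_behaviour,
    simulate_participant_sessions,
)
from neuroloop.synthetic_data import write_behavioural_dataset, write_pattern_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
N_PARTICIPANTS = 5

cfg = ExperimentConfig(master_seed=0)
seeds = child_seeds(cfg.master_seed, N_PARTICIPANTS)
for i, seed in enumerate(seeds):
    pdir = OUT / f"participant_{i:02d}"
    pdir.mkdir(parents=True, exist_ok=True)
    ds1, ds5 = simulate_participant_sessions(cfg, seed)
    write_pattern_dataset(ds1, pdir / "session_1_patterns.tsv")
    write_pattern_dataset(ds5, pdir / "session_5_patterns.tsv")
    behav = simulate_participant_behaviour(cfg, seed + 1)
    write_behavioural_dataset(behav, pdir / "behaviour.tsv")
    print(
        f"participant {i}: seed {seed}, "
        f"{ds1.n_trials}+{ds5.n_trials} recognition trials, "
        f"{len(behav.frame)} behavioural trials"
    )
print(f"wrote {N_PARTICIPANTS} participants to {OUT}")
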