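"""Categorical-perception analysis: psychometric slopes before and after.

Forced-choice responses along the 13-step morph continuum are fitted with
the logistic model; the post-training fit fixes the point of subjective
equality at its pre-training estimate and refits the slope. The
behavioural integration index (pre slope minus post slope) should be
positive for the trained axis only.
Writes results/behaviour.tsv.
"""

from pathlib import Path

import pandas as pd

from neuroloop.pipeline_io import ExperimentConfig, child_seeds, simulate_participant_behaviour
from neuroloop.psychometrics import analyse_behaviour

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)
N = 20

cfg = ExperimentConfig(master_seed=0)
rows = []
for i, seed in enumerate(child_seeds(cfg.master_seed, N)):
    behav = simulate_participant_behaviour(cfg, seed + 1, learning_strength=1.0)
    integration, models = analyse_behaviour(behav)
    rows.append(
        {
            "participant": i,
            "mu_trained": models[("trained", 1)].mu,
            "slope_s1_trained": integration.slope_s1["trained"],
            "slope_s5_trained": integration.slope_s5["trained"],
            "index_trained": integration.index("trained"),
            "index_untrained": integration.index("untrained"),
            "contrast": integration.contrast,
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "behaviour.tsv", sep="\t", index=False)

print(table.round(3).to_string(index=False))
print(
    f"\nmean trained index {table['index_trained'].mean():+.3f} (expect > 0), "
    f"mean untrained index {table['index_untrained'].mean():+.3f} (expect ~0)"
)
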