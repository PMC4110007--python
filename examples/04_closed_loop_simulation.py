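"""Run the trained networks as a closed-loop reach generator.

The first submovement fires at t = 0; afterwards the initiation network
is queried every 10 ms on features of the simulated state, and each
0.5-crossing adds a corrective submovement. A reach succeeds after one
second of dwell inside the 1.27 cm target sphere. Takes a few minutes;
the 150-reach corpus is modest, so expect somewhat weaker numbers than a
full-scale study.
"""

import numpy as np

from submovekit import DecompositionConfig, GeneratorConfig, TrainingConfig, generate_corpus
from submovekit.closed_loop import AnnPolicy, SimulationConfig, evaluate_closed_loop
from submovekit.decompose import decompose_dataset
from submovekit.features import build_training_tables
from submovekit.io import preprocess_dataset
from submovekit.nets import train_nets

gen = GeneratorConfig(n_reaches=150, seed=5)
dataset, _ = generate_corpus(gen)
dataset = preprocess_dataset(dataset)
decomps = decompose_dataset(
    dataset, DecompositionConfig(n_range=tuple(range(1, 7)), n_restarts=2, seed=0)
)  # a few minutes of nonlinear least squares
tables = build_training_tables(dataset, decomps)
nets = train_nets(*tables, TrainingConfig(seed=0))

result = evaluate_closed_loop(AnnPolicy(nets), dataset, SimulationConfig())
s = result["summary"]
print(f"simulated {s['n_trials']} reaches to the corpus targets")
print(f"target acquisition rate: {s['target_acquisition_rate']:.1f}%")
print(f"end distance to target center: {s['end_distance_mean']:.2f} "
      f"+/- {s['end_distance_sd']:.2f} cm (target radius 1.27 cm)")
print(f"simulated vs recorded trajectory: VAF {s['trajectory_vaf']:.2f}%, "
      f"RMSE {s['trajectory_rmse']:.2f} cm")
print(f"mean submovements per simulated reach: {s['mean_n_submovements']:.2f}")

one = result["per_trial"][0]
print(f"first reach: {'hit' if one.success else 'miss'}, "
      f"{one.n_submovements} submovements, onsets "
      f"{np.round([sub.t0 for sub in one.submovements], 2)} s")
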