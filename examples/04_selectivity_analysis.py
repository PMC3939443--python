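"""Classify neurons as turn-, trajectory- or conjunctively selective.

Synthetic neurons with known tuning are spiked over a tracked session;
the analysis then recovers their classes blind: a two-factor ANOVA
(direction x turn location) for turn selectivity, a t-test on central-arm
rates (R1- vs R2-origin trials) for trajectory selectivity, and signed
d-primes on both axes for the conjunctive-coding scatter.
"""

import numpy as np

from tmaze.maze import default_maze
from tmaze.mql import standard_queries
from tmaze.selectivity import classify_neurons, conjunctive_scatter
from tmaze.synthetic import NeuronSpec, SessionSpec, generate_spikes, generate_tracking

rng = np.random.default_rng(11)
track, truth = generate_tracking(SessionSpec(n_choice_trials=24, dropout_fraction=0.0), rng=rng)
neurons = [
    NeuronSpec(0, 5.0, turn_gain=4.0, preferred_turn="left"),
    NeuronSpec(1, 5.0, trajectory_gain=3.0, preferred_origin="R1"),
    NeuronSpec(2, 5.0, turn_gain=4.0, trajectory_gain=3.0,
               preferred_turn="right", preferred_origin="R2"),
    NeuronSpec(3, 5.0),  # untuned
]
spikes = generate_spikes(truth, neurons, rng=rng)

lib = standard_queries(default_maze())
summary = classify_neurons(spikes, lib.turn_table(track), lib.choice_trial_table(track))
print(summary.round(4).to_string(index=False))
print()
print("conjunctive-coding table (selective neurons only):")
print(conjunctive_scatter(summary).round(3).to_string(index=False))
print()
print("Neuron 0 is called 'turn' (direction ANOVA p << 0.05, |turn d'| large), "
      "neuron 1 'trajectory', neuron 2 'conjunctive' (both), and the untuned "
      "neuron 3 is excluded from the d-prime table.")
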