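"""Prospective ramping of turn-selective neurons before the choice turn.

Interval lines partition the approach to the T-junction into windows a-j
(h is the choice turn itself).  Ramping neurons raise their rate with
progress toward the choice on trials in their preferred direction, with
attenuated gains on error trials.  The analysis averages rates per
interval across neurons in four conditions and tests the choice-turn
window with a two-factor ANOVA (preference x outcome).
"""

import numpy as np

from tmaze.maze import default_maze
from tmaze.mql import standard_queries
from tmaze.selectivity import classify_neurons, interval_rate_table, ramping_profile
from tmaze.synthetic import NeuronSpec, SessionSpec, generate_spikes, generate_tracking

rng = np.random.default_rng(7000)
track, truth = generate_tracking(
    SessionSpec(n_choice_trials=40, dropout_fraction=0.0), rng=rng
)
neurons = [
    NeuronSpec(i, 4.0, turn_gain=3.0, ramp_gain=6.0,
               preferred_turn="left" if i % 2 else "right",
               error_gain_factor=0.4)
    for i in range(16)
]
spikes = generate_spikes(truth, neurons, rng=rng)

lib = standard_queries(default_maze())
trial_table = lib.choice_trial_table(track)
cls = classify_neurons(spikes, lib.turn_table(track), trial_table).set_index("neuron")
selective = cls[cls["turn_selective"]]
print(f"turn-selective neurons: {len(selective)} / {len(neurons)}")

preferred = {i: selective.loc[i, "preferred_turn"] for i in selective.index}
profile = ramping_profile(interval_rate_table(spikes, trial_table, preferred))
print("\nmean firing rate (spikes/s) per interval and condition:")
print(profile.curves.round(2).to_string())
print(f"\nchoice-turn ANOVA: preference p = {profile.p_preference:.2e}, "
      f"interaction (outcome x preference) p = {profile.p_interaction:.2e}")
print("\nThe preferred-correct curve ramps up from interval a to h and "
      "collapses after the turn; on error trials the preferred/unpreferred "
      "split at h shrinks, which the interaction term picks up.")
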