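"""Select maze trajectories from tracking data with ordered query lines.

A query is a sequence of axis-aligned lines a trajectory must cross in
order, plus avoid lines that disqualify a candidate if crossed in between.
Here we generate a synthetic tracked session and use the standard library
of queries to pull out choice trials and individual turn traversals, with
crossing timestamps interpolated below the 30 Hz sample spacing.
"""

import numpy as np

from tmaze.maze import default_maze
from tmaze.mql import run_query, standard_queries
from tmaze.synthetic import SessionSpec, generate_tracking

track, truth = generate_tracking(SessionSpec(n_choice_trials=12, seed=5))
print(f"tracking: {len(track)} samples at 30 Hz, "
      f"{(~track.valid).sum()} flagged invalid (simulated signal loss)")

lib = standard_queries(default_maze())

matches = run_query(track, lib.choice_query("R2", "correct"))
print(f"\ncorrect choice trials from R2: {len(matches)} matches")
m = matches[0]
print("first match crossing times (s):",
      np.round(m.crossing_times, 2))

turns = lib.turn_table(track)
print(f"\nturn traversals found: {len(turns)} "
      f"(ground truth scripted {len(truth.turns)})")
print(turns.groupby(["turn_id", "direction"]).size().unstack(fill_value=0))
print("\nEach traversal contributes one firing-rate observation to the "
      "8-turns x 2-directions selectivity analysis.")
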