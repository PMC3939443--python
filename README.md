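# tmaze

Accumulator-model simulation and spike-train analysis of spatial
decision-making on the end-to-end T-maze.

On this task a rat starts at one of two reward points (R1 top-left, R2
bottom-left), is guided by a barrier into the central arm, and at the choice
T-junction must repeat the direction of that guided turn to reach the
rewarded arm (R1 → left → R3, R2 → right → R4); barrier-guided return runs
bring it back without any decision. `tmaze` packages three things built
around this task:

1. **A leaky competing accumulator (LCA) agent** that solves the task in a
   virtual 2D maze. Four output units *O*₁..*O*₄ (straight, turn-around,
   right, left) and two working-memory units *M*₁, *M*₂ are leaky
   integrators

   d*A* = (ΣExt − *k·A* − *w*·ΣInh) d*t* + *c* d*W*,

   with leak *k*, mutual inhibition *w*, and Wiener noise scaled by *c*,
   integrated by the Euler method (d*t* = 0.1, negative values reset to 0).
   One-hot sensory inputs *I*₁..*I*₅ (corridor, dead end, right bend,
   T-junction, left bend) drive the outputs; right/left bends also charge
   *M*₁/*M*₂, which bias the corresponding outputs at the T-junction. An
   action executes when its output unit exceeds threshold (max wins;
   excitations frozen during the action). When *k* = *w* and *c* = 0 the
   memory difference obeys d(*M*₁−*M*₂) = (*I*₃−*I*₅) d*t* — guided-turn
   memory is retained without decay, and the agent is perfect.

2. **A trajectory query engine**: ordered axis-aligned *query lines* (plus
   disqualifying *avoid lines*) select sub-trajectories from (t, x, y,
   valid) tracking data, exporting interpolated crossing timestamps and
   honoring tracking-validity flags. A standard library provides the
   choice-trial queries with interval lines a–j around the choice turn, and
   16 turn queries (8 maze turns × 2 travel directions).

3. **Selectivity statistics**: per-window firing rates; turn selectivity
   (two-factor ANOVA, direction × turn location, p < 0.05); trajectory
   selectivity (t-test on central-arm rates, R1- vs R2-origin trials);
   discriminability d′ = (μₐ−μᵦ)/σ with σ from the pooled mean-centred
   samples; prospective-ramping profiles over intervals a–j with a
   preference × outcome ANOVA at the choice turn; correct-vs-error duration
   comparison (medians + Wilcoxon rank sum); and the conjunctive-coding
   d′ scatter. A synthetic-data generator produces tracked sessions and
   inhomogeneous-Poisson spike trains with known turn/trajectory/ramping
   tuning so every analysis is testable end to end.

## Worked example

```python
from tmaze import ModelParams, run_session

params = ModelParams(c=0.0, k=0.2, w=0.2, threshold=1.0, dt=0.1)
session = run_session(params, duration=1000.0, seed=1)
print(f"choice trials: {len(session.choice_trials)}, accuracy: {session.accuracy}")
print(session.trials_frame().query("trial_kind == 'choice'").head(4).to_string(index=False))
```

prints

```
choice trials: 8, accuracy: 1.0
trial_kind origin guided_turn choice_turn correct  t_start  t_end
    choice     R2       right       right    True     57.1   84.6
    choice     R1        left        left    True    178.1  205.6
    choice     R2       right       right    True    299.1  326.6
    choice     R1        left        left    True    420.1  447.6
```

Without noise every trial is correct: each choice turn repeats the trial's
guided turn. Raising the noise scale `c`, or the working-memory leak
(`ModelParams(k_wm=...)`) at small positive noise, degrades accuracy toward
chance — see `examples/02_parameter_sweeps.py`. The `examples/` directory
has one short script per capability (simulation, sweeps, trajectory
queries, selectivity classification, prospective ramping), and the `tmaze`
command line exposes `simulate`, `sweep`, `generate` and `analyze`.

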