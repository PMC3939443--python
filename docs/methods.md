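# Methods

## The decision model

The agent is a population-level leaky-competing-accumulator network wired
for the end-to-end T-maze. Six integrators evolve by Euler–Maruyama steps
of

    dO1 = (I1                - k·O1 - w·(O2+O3+O4)) dt + c dW
    dO2 = (I2                - k·O2 - w·(O1+O3+O4)) dt + c dW
    dO3 = (I3 + I4 + M1      - k·O3 - w·(O1+O2+O4)) dt + c dW
    dO4 = (I4 + I5 + M2      - k·O4 - w·(O1+O2+O3)) dt + c dW
    dM1 = (I3                - k_wm·M1 - w·M2)      dt + c dW
    dM2 = (I5                - k_wm·M2 - w·M1)      dt + c dW

with one-hot sensory inputs set from the agent's pose: I1 corridor, I2 dead
end, I3 right bend, I4 T-junction, I5 left bend. The connections encode the
task's optimal policy: bends drive the matching turn output and charge the
matching memory unit; at the T-junction I4 drives both turn outputs equally
and the memories break the tie. Each dW is an independent Gaussian
increment of standard deviation sqrt(dt) per unit per step (the
conventional independent-noise reading; correlated noise is not modelled).
Negative excitations are reset to 0 after the full update including noise.

Defaults: w = 0.2, k = 0.2, c = 1e-4, dt = 0.1, threshold 1, movement speed
2 length units/s. `k_wm` (the leak of the memory units) defaults to k and
can be raised separately to degrade retention while leaving the motor
pathway intact; this separation is deliberate — see the leak sweep below.

**Memory conservation and its boundary.** Subtracting the M equations
gives d(M1−M2) = (I3−I5) dt when k_wm = w and c = 0: the stored
guided-turn direction does not decay. The identity holds exactly in the
linear regime; if one memory unit is driven to the non-negativity clip
while the other is positive, the difference is no longer conserved. In
task dynamics both memories stay positive (bends recharge them every few
seconds), and the conservation tests exercise the driven, clip-free
regime.

## Simulation loop

Each tick of length dt does exactly one of two things. If some output unit
exceeds threshold among the *legal* actions, that action executes with all
integrator excitations frozen — a straight move covers speed·dt. Otherwise
one Euler step runs while the agent pauses. Action repetition therefore
interleaves with integration, so whether a unit stays above threshold
between executions depends on the leak (the only reading under which
repetition is leak-dependent). Legality filters candidates before the
threshold/max rule: turns are possible only at corners or junctions with an
open exit, straight only with open track ahead, turn-around anywhere. Ties
at exactly equal excitation (a measure-zero event) go to the
lowest-numbered unit.

The decision threshold is crossed quickly in corridors, so the agent cruises
at full speed there and pauses at bends while the blocked straight output
decays and the turn output charges — these pauses are where memory is
written, and their duration self-limits (a well-charged memory makes its
turn output cross threshold sooner, shortening further exposure).

## Geometry

Only the maze's topology and relative lengths matter; the canonical
geometry is fixed as nine axis-aligned segments in an H arrangement:
a 10-unit central arm (y = 0, x ∈ [−5, 5]), 6-unit crossbars at x = ±5,
and four 3-unit reward arms ending at R1 (−8, 3), R2 (−8, −3), R3 (8, 3),
R4 (8, −3). The T-junction at (5, 0) is the choice point; (−5, 0) is the
guided junction. This yields exactly eight turn locations (four corners and
two branches at each junction); a full alternating trial cycle traverses
every turn once in each direction, giving a balanced 8 × 2 design for the
selectivity analyses. The canonical geometry ships as
`tmaze/data/default_maze.json`.

Barriers are modelled as blocked junction exits. During a choice phase the
non-origin west arm is blocked (forcing the guided turn); during a guided
phase the straight continuation at the east junction and one west arm are
blocked, steering the agent to the next start box. The guided target
alternates R1/R2 by default — the schedule the recorded sessions imply,
since they contain trials from both origins — with `repeat` and `random`
policies available. Sessions start mid-central-arm facing west with all
integrators at zero.

## Parameter sweeps

Accuracy is the fraction of correct choice trials; sessions with no
completed choice trial report NaN and are excluded from sweep aggregates
rather than counted as failures.

* **Noise sweep**: c ∈ {1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.3} at k = w = 0.2.
  Accuracy declines from 1.0 toward chance as noise swamps the memory
  difference at the choice point.
* **Leak sweep**: k_wm ∈ {0.2, 0.35, 0.5, 0.75, 1.0} at fixed c = 0.02.
  A positive noise level is structurally necessary here: with c = 0 the
  output-layer remnant of the guided turn (O3/O4 decay only at k = 0.2
  along the central arm) still deterministically selects the correct turn
  even when the memories have fully leaked, so leak-induced errors only
  surface once noise can overturn that small remnant. Sweeping the global
  k instead is not viable — above k ≈ 0.25 no output reaches threshold
  under inhibition and the agent stalls.

Both trends are asserted as Spearman rank correlations over per-session
(value, accuracy) pairs, 30 replicate sessions of 1000 time units per grid
point (the deterministic noise-free check uses a single session; the
original protocol's 300 replicates are reduced to keep the default runs in
minutes — the trend statistics are already decisive at 30).

## Trajectory queries

A query line is horizontal or vertical with a fixed level and a span on the
other axis. Crossings are detected between consecutive samples straddling
the level with the interpolated intersection inside the span; the timestamp
interpolates linearly (sub-sample resolution), and validity is the
conjunction of the two samples' flags. A sample landing exactly on a line
counts as a crossing completed at that sample, sided by the preceding
sample, and is not double-counted.

Matching is greedy, earliest-start and non-overlapping: a candidate starts
at the earliest uncommitted crossing of line 1 and completes with the first
subsequent crossing of each remaining line in order; an avoid-line crossing
strictly inside the candidate's window disqualifies it and the scan resumes
at the next line-1 crossing. This gives one match per behavioural pass,
which is the trial semantics the analyses need, and is verified against a
brute-force chain enumerator on random trajectories.

The standard library places the central-arm lines one eighth into the arm
at both ends (x = ±3.75), delimiting the central three-quarters; the
choice turn runs from the final eighth of the central arm to the same
distance (1.25 units) into the chosen crossbar. The approach to the choice
turn is partitioned into intervals a–j: seven equal windows across the
central three-quarters (a–g), the choice turn itself (h), and two
post-turn windows (i, j). Every turn query consists of an entry and an
exit line 1.25 units from the corner, flanked by avoid lines at 2.5 units
(and on any third junction branch) so that reward-point dwells or later
passes can never be stitched into one traversal. Validity gating is
applied at the required crossings only; signal loss elsewhere in the maze
does not discard a match.

## Selectivity statistics

Firing rates use half-open windows [t0, t1), so interval boundaries a–j
never double-count a spike. Turn selectivity is a two-factor ANOVA
(direction × turn location, Type II sums of squares for robustness to
unbalanced traversal counts, interaction included; the model falls back to
additive if a design is saturated) with the direction main effect tested at
α = 0.05 and no minimum firing-rate requirement; the preferred direction is
the higher grand mean. Trajectory selectivity is a two-sample t-test on
central-arm rates of R1- vs R2-origin choice trials. Degenerate inputs
(zero variance everywhere) are flagged and reported as not selective
rather than erroring.

d′ = (μa − μb)/σ, where σ is the standard deviation (ddof = 1) of the two
mean-centred samples concatenated — the convention pinned by the package's
reference example (a = {2,4}, b = {1,3} → σ = sqrt(4/3)); a `ddof=2`
option removes one degree of freedom per centred group instead. σ = 0 with
unequal means raises rather than returning infinity. d′ values are stored
signed; magnitude plots are the caller's choice.

Ramping profiles average within-neuron mean rates per interval across
turn-selective neurons in four conditions (preferred/unpreferred ×
correct/error, where "preferred" compares the trial's choice direction
with the neuron's preferred turn), then test the choice-turn interval h
with a preference × outcome ANOVA including the interaction. The
correct-vs-error duration comparison reports group medians and the
two-sided Wilcoxon rank-sum p. The conjunctive table includes only neurons
passing at least one selectivity test.

## Synthetic data generator

The generator scripts sessions with the structure of the recorded ones:
93 choice trials with error rate 16/93 ≈ 0.17 by default, alternating
origins with guided returns, 30 Hz tracking, Gaussian positional jitter
(sd 0.05 units), and signal loss in contiguous geometric bursts (mean 10
samples, 2% of samples by default) to exercise validity gating the way
camera occlusions do. Running speed is 4 units/s with 1 s reward dwells
and 0.3 s corner pauses; the pause at the T-junction is 0.45 s on correct
and 1.45 s on error trials, so choice-turn durations land near the
reference medians (~1.07 s vs ~2.07 s). Neurons spike as inhomogeneous
Poisson processes via exact thinning at a ceiling of baseline plus all
positive gains; rate gains are locked to turn windows of a preferred
direction, central-arm windows of a preferred origin, and a
distance-fraction ramp toward the choice turn on preferred-direction
trials, with an optional attenuation factor on error trials.

What it does not emulate: refractoriness, bursting and theta modulation;
speed modulation of rates; variable running speeds or off-path excursions;
electrode drift or sorting errors. Passing tests therefore show the
statistics are correct and calibrated for Poisson-like firing with
condition-locked rates, not that real mPFC/dCA1 data would meet
parametric assumptions equally well.

## Problem sizes and numerical choices

Default test/acceptance scales: 1000-time-unit sessions; 30 replicates per
sweep point; 24-trial sessions for the calibration battery (≥ 8 traversals
per turn × direction cell), 1000 null + 100 tuned neurons for
false-positive/power estimates; 40-trial sessions with 16 ramping neurons
for the prospective-activity analysis. Conservation and d′ identities are
asserted to 1e-12; the type-I band is [0.03, 0.08] at α = 0.05 over 1000
nulls; recovery power ≥ 90% at +4 spikes/s over a 5 spikes/s baseline.
Floating-point geometry uses exact node clipping (a straight move lands
exactly on a junction), so node tests need no tolerances beyond 1e-9.

## Known limitations

* Task learning is out of scope: connections are fixed at the learned
  optimum; reward delivery has no feedback into the dynamics.
* The agent's effective corridor speed is one length unit per two ticks
  (move ticks interleave with integration ticks), so absolute trial
  durations are a model property, not a fit to rat running speeds.
* Non-alternating barrier policies remain accurate in simulation (the
  self-limiting bend pauses keep the memories balanced), but they produce
  one-sided trial mixes; the default alternating schedule matches the
  balanced origins of the recorded sessions and is what the selectivity
  analyses assume for their 8 × 2 design.
* Query libraries assume the canonical H-geometry; other mazes need their
  own line placements (per-line overrides are available on the standard
  library's constructor parameters).
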