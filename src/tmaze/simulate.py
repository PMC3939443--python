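"""Closed-loop T-maze sessions: environment <-> accumulator model.

Each simulation tick of length ``dt`` does exactly one of two things: if some
output unit is above the decision threshold (among the physically legal
actions), the winning action executes while all integrator excitations stay
frozen — a straight move covers ``speed * dt`` length units; otherwise one
Euler step of the integrator equations runs while the virtual rat pauses in
place.  Repetition of an action therefore interleaves with integration, so
whether a unit keeps its excitation above threshold between executions
depends on the leak.

Trials are segmented at reward-point arrivals.  A choice trial runs from
departure at R1/R2 to arrival at R3/R4 and is correct when the choice turn
matches the trial's initial guided turn (R1 -> left -> R3, R2 -> right ->
R4).  Guided trials (R3/R4 back to R1/R2, enforced by barriers) never count
toward accuracy.  Barriers are modelled as blocked junction exits; the
guided-trial target side alternates between R1 and R2 by default, mirroring
the experimenter moving barriers between trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .lca import IntegratorState, ModelParams, integrate_step, select_action
from .maze import AgentPose, MazeGeometry, classify_location, default_maze, legal_actions
from .mql import TrackingSeries

__all__ = ["TrialRecord", "SessionResult", "run_session", "sweep", "export_virtual_tracking"]

_NOISE_CHUNK = 4096


@dataclass(frozen=True)
class TrialRecord:
    trial_kind: str  # "choice" | "guided"
    origin: str  # reward point the trial departs from
    guided_turn: Optional[str]  # direction of the barrier-enforced turn
    choice_turn: Optional[str]  # direction chosen at the T-junction (choice trials)
    correct: Optional[bool]
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.trial_kind == "choice" and self.correct != (self.choice_turn == self.guided_turn):
            raise ValueError("choice trial correctness inconsistent with turns")


@dataclass
class SessionResult:
    trials: list[TrialRecord]
    params: ModelParams
    seed: Optional[int]
    duration: float
    trace_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    trace_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    trace_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    trace_state: Optional[np.ndarray] = None  # ticks x 6 (O1..O4, M1, M2)

    @property
    def choice_trials(self) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.trial_kind == "choice"]

    @property
    def accuracy(self) -> float:
        """Fraction of correct choice trials; NaN if no choice trial completed."""
        ct = self.choice_trials
        if not ct:
            return float("nan")
        return sum(tr.correct for tr in ct) / len(ct)

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame([tr.__dict__ for tr in self.trials])


def _guided_barriers(maze: MazeGeometry, from_arm: Optional[str], target: str) -> frozenset:
    wj, ej = maze.guided_junction, maze.choice_junction
    blocked = {(wj, "N" if target == "R2" else "S")}
    if from_arm == "R4":
        blocked.add((ej, "N"))
    elif from_arm == "R3":
        blocked.add((ej, "S"))
    return frozenset(blocked)


def _choice_barriers(maze: MazeGeometry, origin: str) -> frozenset:
    wj = maze.guided_junction
    return frozenset({(wj, "N" if origin == "R2" else "S")})


def _next_target(policy: str, origin: str, rng: np.random.Generator) -> str:
    if policy == "alternate":
        return "R1" if origin == "R2" else "R2"
    if policy == "repeat":
        return origin
    if policy == "random":
        return str(rng.choice(["R1", "R2"]))
    raise ValueError(f"unknown barrier policy {policy!r}")


def run_session(
    params: ModelParams,
    duration: float = 1000.0,
    seed: Optional[int] = None,
    maze: Optional[MazeGeometry] = None,
    barrier_policy: str = "alternate",
    initial_target: str = "R2",
    record_trace: bool = True,
    record_state: bool = False,
) -> SessionResult:
    """Run one closed-loop session of ``duration`` time units.

    The agent starts at the centre of the central arm facing west (toward
    the guided junction) with all integrators at zero, in a guided phase
    whose barrier directs it to ``initial_target``.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    maze = maze or default_maze()
    rng = np.random.default_rng(seed)
    dt = params.dt

    pose = AgentPose(
        (maze.guided_junction[0] + maze.choice_junction[0]) / 2.0,
        maze.guided_junction[1],
        "W",
        maze.segment_of((maze.guided_junction[0] + maze.choice_junction[0]) / 2.0, maze.guided_junction[1]),
    )
    state = IntegratorState()

    phase = "guided"
    target = initial_target
    blocked = _guided_barriers(maze, None, target)
    origin: Optional[str] = None
    guided_from: Optional[str] = None
    guided_start = 0.0
    choice_start: Optional[float] = None
    dwelling: Optional[str] = None
    trials: list[TrialRecord] = []

    ts, xs, ys = [0.0], [pose.x], [pose.y]
    states = [state.as_array()] if record_state else None

    noise_buf: Optional[np.ndarray] = None
    noise_i = 0
    use_noise = params.c > 0.0

    t = 0.0
    n_ticks = int(round(duration / dt))
    tick = 0

    def log() -> None:
        if record_trace:
            ts.append(t)
            xs.append(pose.x)
            ys.append(pose.y)
            if states is not None:
                states.append(state.as_array())

    while tick < n_ticks:
        # --- one integration tick (rat pauses) ---
        scene = classify_location(pose, maze, blocked)
        if use_noise:
            if noise_buf is None or noise_i + 6 > noise_buf.size:
                noise_buf = rng.standard_normal(_NOISE_CHUNK * 6)
                noise_i = 0
            draws = noise_buf[noise_i : noise_i + 6]
            noise_i += 6
            state = integrate_step(state, scene, params, noise=draws)
        else:
            state = integrate_step(state, scene, params)
        t += dt
        tick += 1
        log()
        if tick >= n_ticks:
            break

        # --- optionally one action tick (integrators frozen) ---
        legal = legal_actions(pose, maze, blocked)
        action = select_action(state, params.threshold, legal)
        if action is None:
            continue
        prev_pos = pose.position
        pose = advance_pose = _advance(pose, action, maze, params, blocked)
        t += dt
        tick += 1
        log()

        if pose.position == prev_pos and action == "straight":
            continue

        # choice-trial departure: first movement off the origin reward point
        if phase == "choice" and choice_start is None and pose.position != maze.reward_points[origin]:
            choice_start = t - dt

        label = maze.reward_label_at(pose.x, pose.y)
        if label is None:
            dwelling = None
            continue
        if label == dwelling:
            continue
        dwelling = label

        if phase == "choice" and label in ("R3", "R4"):
            guided_turn = "left" if origin == "R1" else "right"
            choice_turn = "left" if label == "R3" else "right"
            trials.append(
                TrialRecord(
                    "choice",
                    origin,
                    guided_turn,
                    choice_turn,
                    guided_turn == choice_turn,
                    choice_start if choice_start is not None else t,
                    t,
                )
            )
            phase = "guided"
            prev_origin = origin
            origin = None
            choice_start = None
            target = _next_target(barrier_policy, prev_origin, rng)
            guided_from = label
            guided_start = t
            blocked = _guided_barriers(maze, label, target)
        elif phase == "choice" and label in ("R1", "R2"):
            # wandered back to the start side: trial restarts on next departure
            choice_start = None
        elif phase == "guided" and label in ("R1", "R2"):
            guided_turn = "left" if label == "R2" else "right"
            trials.append(
                TrialRecord("guided", guided_from or label, guided_turn, None, None, guided_start, t)
            )
            phase = "choice"
            origin = label
            choice_start = None
            blocked = _choice_barriers(maze, origin)

    result = SessionResult(
        trials=trials,
        params=params,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        duration=duration,
        trace_t=np.asarray(ts),
        trace_x=np.asarray(xs),
        trace_y=np.asarray(ys),
        trace_state=np.asarray(states) if states is not None else None,
    )
    if not result.choice_trials and duration > 0:
        warnings.warn("session completed zero choice trials; accuracy is NaN", stacklevel=2)
    return result


def _advance(pose, action, maze, params: ModelParams, blocked):
    from .maze import advance

    return advance(pose, action, maze, speed=params.speed, duration=params.dt, blocked=blocked)


def sweep(
    param_name: str,
    values,
    replicates: int = 30,
    duration: float = 1000.0,
    seed: Optional[int] = None,
    base_params: Optional[ModelParams] = None,
    maze: Optional[MazeGeometry] = None,
    barrier_policy: str = "alternate",
) -> pd.DataFrame:
    """Mean/sd of session accuracy over a parameter grid.

    ``param_name`` is ``"c"`` (noise scale, all integrators) or ``"k"`` (leak
    of the working-memory integrators only, per the reference protocol for
    the leak sweep).  Each (value, replicate) runs an independently seeded
    session; rows report the across-replicate mean and standard deviation of
    accuracy, ignoring sessions with no completed choice trial.
    """
    if param_name not in ("c", "k"):
        raise ValueError("param_name must be 'c' or 'k'")
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = base_params or ModelParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(values) * replicates)
    rows = []
    idx = 0
    for v in values:
        if param_name == "c":
            p = ModelParams(
                w=base.w, k=base.k, c=v, dt=base.dt, threshold=base.threshold,
                speed=base.speed, k_wm=base.k_wm,
            )
        else:
            p = ModelParams(
                w=base.w, k=base.k, c=base.c, dt=base.dt, threshold=base.threshold,
                speed=base.speed, k_wm=v,
            )
        accs = []
        n_trials = 0
        for _ in range(replicates):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_session(
                    p, duration, seed=children[idx], maze=maze,
                    barrier_policy=barrier_policy, record_trace=False,
                )
            idx += 1
            if res.choice_trials:
                accs.append(res.accuracy)
                n_trials += len(res.choice_trials)
        rows.append(
            {
                "param": param_name,
                "value": v,
                "mean_accuracy": float(np.mean(accs)) if accs else float("nan"),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "n_sessions": len(accs),
                "n_choice_trials": n_trials,
            }
        )
    return pd.DataFrame(rows)


def export_virtual_tracking(session: SessionResult, rate_hz: float = 30.0) -> TrackingSeries:
    """Resample a session's pose trace to a fixed-rate tracking series.

    All samples are flagged valid (the virtual camera never loses signal).
    """
    if session.trace_t.size == 0:
        raise ValueError("session has no trace; rerun with record_trace=True")
    t0, t1 = float(session.trace_t[0]), float(session.trace_t[-1])
    n = max(1, int(math.floor((t1 - t0) * rate_hz)) + 1)
    tg = t0 + np.arange(n) / rate_hz
    x = np.interp(tg, session.trace_t, session.trace_x)
    y = np.interp(tg, session.trace_t, session.trace_y)
    return TrackingSeries(t=tg, x=x, y=y, valid=np.ones(n, dtype=bool))
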