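"""Synthetic tracking and spike data with known ground truth.

The generator scripts an end-to-end T-maze session — alternating-origin
choice trials with Bernoulli errors, barrier-guided returns, reward-point
dwells and corner pauses — as a piecewise-linear trajectory over the
canonical maze, samples it at the camera rate with Gaussian positional
jitter, and flags contiguous bursts of samples invalid to emulate tracking
signal loss.  Spike trains are drawn from an inhomogeneous Poisson process
(exact thinning) whose rate is a baseline plus optional condition-locked
gains: extra rate during turns of a preferred direction, extra rate on the
central arm for a preferred trial origin, and a linear ramp toward the
choice turn on trials whose choice matches the preferred direction.

Every generated feature is returned as ground truth (trial table, turn
traversal windows, interval windows, ramp progress), so the query engine
and the selectivity statistics can be validated end to end with no
recorded data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maze import CENTRAL_HALF, CROSS_HALF, MazeGeometry, default_maze, turn_locations
from .mql import INTERVAL_NAMES, TrackingSeries

__all__ = ["SessionSpec", "NeuronSpec", "SessionTruth", "generate_tracking", "generate_spikes"]

_DIR_STEP = {"N": (0.0, 1.0), "E": (1.0, 0.0), "S": (0.0, -1.0), "W": (-1.0, 0.0)}


@dataclass(frozen=True)
class SessionSpec:
    """Study conditions for one synthetic session.

    Defaults mirror the recorded sessions the analyses target: 93 choice
    trials with an error rate of about 0.17 (77 correct / 16 error),
    30 Hz tracking, and occasional camera signal loss in contiguous bursts.
    """

    n_choice_trials: int = 93
    error_rate: float = 16 / 93
    n_guided_trials: Optional[int] = None  # None: one return between choice trials
    tracking_rate_hz: float = 30.0
    dropout_fraction: float = 0.02
    rat_speed: float = 4.0  # length units / s
    jitter_sd: float = 0.05  # positional tracking noise, length units
    reward_dwell: float = 1.0  # s at each reward point
    corner_pause: float = 0.3  # s at each non-choice turn
    choice_pause_correct: float = 0.45  # s pause at the T-junction, correct trials
    choice_pause_error: float = 1.45  # s pause on error trials (slower decisions)
    first_origin: str = "R2"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.n_choice_trials < 1:
            raise ValueError("need at least one choice trial")


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth firing model of one synthetic neuron (rates in spikes/s)."""

    neuron_id: int
    baseline_rate: float = 5.0
    turn_gain: float = 0.0
    trajectory_gain: float = 0.0
    ramp_gain: float = 0.0
    preferred_turn: Optional[str] = None  # "left" | "right" | None
    preferred_origin: Optional[str] = None  # "R1" | "R2" | None
    error_gain_factor: float = 1.0  # multiplies turn/ramp gains on error trials

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if min(self.turn_gain, self.trajectory_gain, self.ramp_gain) < -self.baseline_rate:
            raise ValueError("negative gains may not drive the rate below zero")

    @property
    def ceiling(self) -> float:
        return (
            self.baseline_rate
            + max(self.turn_gain, 0.0)
            + max(self.trajectory_gain, 0.0)
            + max(self.ramp_gain, 0.0)
        )


@dataclass
class SessionTruth:
    """Everything the generator knows about the session it produced."""

    trials: pd.DataFrame  # trial, origin, dest, outcome, choice_dir, t_depart, ...
    turns: pd.DataFrame  # trial, turn_id, direction, t_in, t_out, is_choice_turn
    intervals: pd.DataFrame  # trial, interval (a..j), t0, t1
    ramps: pd.DataFrame  # trial, t0, t1, p0, p1 (piecewise-linear ramp progress)
    duration: float

    @property
    def n_correct(self) -> int:
        return int((self.trials["outcome"] == "correct").sum())

    @property
    def n_error(self) -> int:
        return int((self.trials["outcome"] == "error").sum())


_ROUTES_UP = {"R1": (-1, 1), "R2": (-1, -1), "R3": (1, 1), "R4": (1, -1)}  # (east/west, up/down)


def _trial_route(origin: str, dest: str) -> list[tuple[float, float]]:
    """Node waypoints from one reward point to another through the central arm."""
    c, h = CENTRAL_HALF, CROSS_HALF
    sx, sy = _ROUTES_UP[origin]
    dx, dy = _ROUTES_UP[dest]
    if sx == dx:
        raise ValueError("routes must cross the central arm")
    return [
        (sx * (c + 3.0), sy * h),  # origin reward point
        (sx * c, sy * h),  # corner
        (sx * c, 0.0),  # origin-side junction
        (dx * c, 0.0),  # far junction
        (dx * c, dy * h),  # corner
        (dx * (c + 3.0), dy * h),  # destination reward point
    ]


def _leg_dir(a: tuple[float, float], b: tuple[float, float]) -> str:
    if a[0] == b[0]:
        return "N" if b[1] > a[1] else "S"
    return "E" if b[0] > a[0] else "W"


def _turn_id_for(node, entry_leg: str, exit_leg: str, turns) -> tuple[int, str]:
    from .mql import _turn_direction

    for tid, (tn, legs) in turns.items():
        if tn == node and set(legs) == {entry_leg, exit_leg}:
            return tid, _turn_direction(entry_leg, exit_leg)
    raise ValueError(f"no turn at node {node} joining {entry_leg}/{exit_leg}")


def generate_tracking(
    spec: SessionSpec,
    maze: Optional[MazeGeometry] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TrackingSeries, SessionTruth]:
    """Script a session and sample it as a 30 Hz tracking series.

    Returns the series together with the full ground truth.  Origins
    alternate starting at ``spec.first_origin``; each choice trial is
    followed by a guided return to the next origin.
    """
    maze = maze or default_maze()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    turns = turn_locations(maze)
    v = spec.rat_speed
    margin = 1.25  # query-line distance from turn nodes (arm eighth)

    # --- script the trial sequence -----------------------------------------
    origin = spec.first_origin
    bp_t: list[float] = [0.0]
    bp_x: list[float] = [maze.reward_points[origin][0]]
    bp_y: list[float] = [maze.reward_points[origin][1]]
    t = spec.reward_dwell
    bp_t.append(t)
    bp_x.append(bp_x[-1])
    bp_y.append(bp_y[-1])

    trial_rows, turn_rows, interval_rows, ramp_rows = [], [], [], []

    def walk(route: Sequence[tuple[float, float]], pauses: dict[int, float]):
        """Advance along node waypoints; returns per-node (arrive, leave) times."""
        nonlocal t
        times = []
        for i in range(1, len(route)):
            a, b = route[i - 1], route[i]
            dist = abs(b[0] - a[0]) + abs(b[1] - a[1])
            t += dist / v
            bp_t.append(t)
            bp_x.append(b[0])
            bp_y.append(b[1])
            arrive = t
            pause = pauses.get(i, 0.0)
            if pause > 0:
                t += pause
                bp_t.append(t)
                bp_x.append(b[0])
                bp_y.append(b[1])
            times.append((arrive, t))
        return times

    n_errors = 0
    correct_dest = {"R1": "R3", "R2": "R4"}
    error_dest = {"R1": "R4", "R2": "R3"}
    for trial in range(spec.n_choice_trials):
        is_error = rng.random() < spec.error_rate
        dest = error_dest[origin] if is_error else correct_dest[origin]
        choice_dir = "left" if dest == "R3" else "right"
        outcome = "error" if is_error else "correct"
        n_errors += is_error
        route = _trial_route(origin, dest)
        choice_pause = spec.choice_pause_error if is_error else spec.choice_pause_correct
        pauses = {1: spec.corner_pause, 2: spec.corner_pause, 3: choice_pause, 4: spec.corner_pause}
        t_depart = t
        node_times = walk(route, pauses)
        t_arrive = t

        # turn windows: crossing of entry line (margin before node) to exit line
        for i in range(1, len(route) - 1):
            node = route[i]
            entry_leg = _leg_dir(node, route[i - 1])
            exit_leg = _leg_dir(node, route[i + 1])
            tid, tdir = _turn_id_for(node, entry_leg, exit_leg, turns)
            arrive, leave = node_times[i - 1]
            turn_rows.append(
                {
                    "trial": trial,
                    "turn_id": tid,
                    "direction": tdir,
                    "t_in": arrive - margin / v,
                    "t_out": leave + margin / v,
                    "is_choice_turn": node == maze.choice_junction,
                    "origin": origin,
                    "outcome": outcome,
                }
            )

        # interval windows a..j (7 along the central three-quarters, then
        # choice turn h and post-turn i, j on the destination crossbar)
        wj_arrive, wj_leave = node_times[1]  # origin-side junction
        ej_arrive, ej_leave = node_times[2]  # choice junction
        cent_t0 = wj_leave + margin / v
        cent_t1 = ej_arrive - margin / v
        xs = np.linspace(0, 1, 8)
        bounds = [cent_t0 + float(f) * (cent_t1 - cent_t0) for f in xs]
        bounds.append(ej_leave + margin / v)  # end of h: choice-turn exit line
        bounds.append(ej_leave + (margin + 0.75) / v)
        bounds.append(ej_leave + (margin + 1.5) / v)
        for nm, (b0, b1) in zip(INTERVAL_NAMES, zip(bounds, bounds[1:])):
            interval_rows.append({"trial": trial, "interval": nm, "t0": b0, "t1": b1})

        # ramp progress: 0 at central-arm entry, 1 at choice-turn exit, by
        # path distance (pauses hold progress constant)
        total_dist = (2 * CENTRAL_HALF - 2 * margin) + margin + margin  # entry line to exit line
        segs = [
            (cent_t0, ej_arrive - 0.0, 0.0, (total_dist - margin) / total_dist),
            (ej_arrive, ej_leave, (total_dist - margin) / total_dist, (total_dist - margin) / total_dist),
            (ej_leave, ej_leave + margin / v, (total_dist - margin) / total_dist, 1.0),
        ]
        for t0_, t1_, p0_, p1_ in segs:
            ramp_rows.append({"trial": trial, "t0": t0_, "t1": t1_, "p0": p0_, "p1": p1_})

        trial_rows.append(
            {
                "trial": trial,
                "origin": origin,
                "dest": dest,
                "outcome": outcome,
                "choice_dir": choice_dir,
                "t_depart": t_depart,
                "t_arrive": t_arrive,
                "central_t0": cent_t0,
                "central_t1": cent_t1,
                "h_t0": cent_t1,
                "h_t1": ej_leave + margin / v,
            }
        )

        # reward dwell, then guided return to the next origin
        t += spec.reward_dwell
        bp_t.append(t)
        bp_x.append(bp_x[-1])
        bp_y.append(bp_y[-1])
        if trial == spec.n_choice_trials - 1:
            break
        next_origin = "R1" if origin == "R2" else "R2"
        g_route = _trial_route(dest, next_origin)
        g_pauses = {1: spec.corner_pause, 2: spec.corner_pause, 3: spec.corner_pause, 4: spec.corner_pause}
        g_times = walk(g_route, g_pauses)
        for i in range(1, len(g_route) - 1):
            node = g_route[i]
            entry_leg = _leg_dir(node, g_route[i - 1])
            exit_leg = _leg_dir(node, g_route[i + 1])
            tid, tdir = _turn_id_for(node, entry_leg, exit_leg, turns)
            arrive, leave = g_times[i - 1]
            turn_rows.append(
                {
                    "trial": -1,
                    "turn_id": tid,
                    "direction": tdir,
                    "t_in": arrive - margin / v,
                    "t_out": leave + margin / v,
                    "is_choice_turn": False,
                    "origin": dest,
                    "outcome": "guided",
                }
            )
        t += spec.reward_dwell
        bp_t.append(t)
        bp_x.append(bp_x[-1])
        bp_y.append(bp_y[-1])
        origin = next_origin

    duration = t
    truth = SessionTruth(
        trials=pd.DataFrame(trial_rows),
        turns=pd.DataFrame(turn_rows).sort_values("t_in", ignore_index=True),
        intervals=pd.DataFrame(interval_rows),
        ramps=pd.DataFrame(ramp_rows),
        duration=duration,
    )

    # --- sample the polyline at the camera rate ----------------------------
    n = int(np.floor(duration * spec.tracking_rate_hz)) + 1
    tg = np.arange(n) / spec.tracking_rate_hz
    x = np.interp(tg, bp_t, bp_x) + rng.normal(0.0, spec.jitter_sd, n)
    y = np.interp(tg, bp_t, bp_y) + rng.normal(0.0, spec.jitter_sd, n)
    valid = np.ones(n, dtype=bool)
    if spec.dropout_fraction > 0:
        target = int(round(spec.dropout_fraction * n))
        while valid.size - valid.sum() < target:
            start = int(rng.integers(0, n))
            length = int(rng.geometric(0.1))  # mean burst of 10 samples
            valid[start : start + length] = False
    track = TrackingSeries(t=tg, x=x, y=y, valid=valid)

    if spec.dropout_fraction > 0:
        ok = False
        for _, tr in truth.trials.iterrows():
            i0 = np.searchsorted(tg, tr["central_t0"])
            i1 = np.searchsorted(tg, tr["central_t1"])
            if valid[max(i0 - 1, 0) : i0 + 1].all() and valid[max(i1 - 1, 0) : i1 + 1].all():
                ok = True
                break
        if not ok:
            warnings.warn("dropout so severe that no trial retains valid central-arm crossings")
    return track, truth


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


def _window_mask(times: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of each time in any of the sorted, non-overlapping windows."""
    if starts.size == 0:
        return np.zeros(times.size, dtype=bool)
    idx = np.searchsorted(starts, times, side="right") - 1
    idx_clipped = np.clip(idx, 0, starts.size - 1)
    return (idx >= 0) & (times < ends[idx_clipped])


def rate_function(spec: NeuronSpec, truth: SessionTruth):
    """Return a vectorized instantaneous-rate function lambda(t) for a neuron."""
    trials = truth.trials

    turn_w = truth.turns
    if spec.preferred_turn is not None and spec.turn_gain != 0.0:
        tw = turn_w[turn_w["direction"] == spec.preferred_turn]
        turn_starts = tw["t_in"].to_numpy()
        turn_ends = tw["t_out"].to_numpy()
        turn_err = (tw["outcome"] == "error").to_numpy()
        order = np.argsort(turn_starts)
        turn_starts, turn_ends, turn_err = turn_starts[order], turn_ends[order], turn_err[order]
    else:
        turn_starts = turn_ends = np.empty(0)
        turn_err = np.empty(0, dtype=bool)

    if spec.preferred_origin is not None and spec.trajectory_gain != 0.0:
        sel = trials[trials["origin"] == spec.preferred_origin]
        cen_starts = sel["central_t0"].to_numpy()
        cen_ends = sel["central_t1"].to_numpy()
    else:
        cen_starts = cen_ends = np.empty(0)

    if spec.preferred_turn is not None and spec.ramp_gain != 0.0:
        pref_trials = set(trials.loc[trials["choice_dir"] == spec.preferred_turn, "trial"])
        rr = truth.ramps[truth.ramps["trial"].isin(pref_trials)]
        rr = rr.merge(trials[["trial", "outcome"]], on="trial")
        r_t0 = rr["t0"].to_numpy()
        r_t1 = rr["t1"].to_numpy()
        r_p0 = rr["p0"].to_numpy()
        r_p1 = rr["p1"].to_numpy()
        r_err = (rr["outcome"] == "error").to_numpy()
        order = np.argsort(r_t0)
        r_t0, r_t1, r_p0, r_p1, r_err = (a[order] for a in (r_t0, r_t1, r_p0, r_p1, r_err))
    else:
        r_t0 = r_t1 = r_p0 = r_p1 = np.empty(0)
        r_err = np.empty(0, dtype=bool)

    def rate(times: np.ndarray) -> np.ndarray:
        lam = np.full(times.size, spec.baseline_rate, dtype=float)
        if turn_starts.size:
            idx = np.searchsorted(turn_starts, times, side="right") - 1
            idxc = np.clip(idx, 0, turn_starts.size - 1)
            inside = (idx >= 0) & (times < turn_ends[idxc])
            gain = np.where(turn_err[idxc], spec.turn_gain * spec.error_gain_factor, spec.turn_gain)
            lam += np.where(inside, gain, 0.0)
        if cen_starts.size:
            lam += np.where(_window_mask(times, cen_starts, cen_ends), spec.trajectory_gain, 0.0)
        if r_t0.size:
            idx = np.searchsorted(r_t0, times, side="right") - 1
            idxc = np.clip(idx, 0, r_t0.size - 1)
            inside = (idx >= 0) & (times < r_t1[idxc])
            span = np.maximum(r_t1[idxc] - r_t0[idxc], 1e-12)
            frac = (times - r_t0[idxc]) / span
            p = r_p0[idxc] + frac * (r_p1[idxc] - r_p0[idxc])
            gain = np.where(r_err[idxc], spec.ramp_gain * spec.error_gain_factor, spec.ramp_gain)
            lam += np.where(inside, gain * p, 0.0)
        return np.maximum(lam, 0.0)

    return rate


def generate_spikes(
    truth: SessionTruth,
    specs: Sequence[NeuronSpec],
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> dict[int, np.ndarray]:
    """Inhomogeneous Poisson spike trains by thinning, one per neuron spec.

    Candidate events are drawn homogeneously at each neuron's rate ceiling
    (baseline plus all positive gains) and accepted with probability
    rate(t)/ceiling, which is exact for the piecewise-linear rate profiles
    used here.  Returns ``{neuron_id: sorted spike time array}``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    T = truth.duration
    for spec in specs:
        ceil = spec.ceiling
        if ceil <= 0:
            out[spec.neuron_id] = np.empty(0)
            continue
        n = rng.poisson(ceil * T)
        cand = np.sort(rng.uniform(0.0, T, n))
        lam = rate_function(spec, truth)(cand)
        keep = rng.uniform(0.0, ceil, n) < lam
        out[spec.neuron_id] = cand[keep]
    return out
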