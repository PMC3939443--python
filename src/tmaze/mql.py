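"""Trajectory query engine for maze tracking data.

A query is an ordered list of axis-aligned "query lines" plus optional
"avoid" lines.  Running a query over a tracking series returns the
chronological, non-overlapping sub-trajectories that cross every query line
in the listed order; a candidate is disqualified if any avoid line is
crossed strictly between its first and last query-line crossing.  Crossing
timestamps are linearly interpolated between the two straddling samples,
giving sub-sample resolution, and each crossing carries a validity flag (the
conjunction of the two samples' tracking-validity flags) so analyses can
ignore matches whose required crossings coincide with camera signal loss.

``standard_queries`` builds the canonical query library for the default
end-to-end T-maze: per-origin correct/error choice-trial queries carrying
the interval lines a–j around the choice turn, and left/right queries for
each of the eight maze turns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .maze import CENTRAL_HALF, CROSS_HALF, MazeGeometry, turn_locations

__all__ = [
    "TrackingSeries",
    "QueryLine",
    "Query",
    "Crossing",
    "Match",
    "crossings",
    "run_query",
    "validity_gate",
    "standard_queries",
    "StandardQueryLibrary",
    "INTERVAL_NAMES",
]

INTERVAL_NAMES = tuple("abcdefghij")


@dataclass
class TrackingSeries:
    """Timestamped (t, x, y, valid) position samples, strictly increasing t."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("tracking arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise ValueError("valid samples must have finite coordinates")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y, "valid": self.valid})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrackingSeries":
        return cls(
            t=df["t"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
        )


@dataclass(frozen=True)
class QueryLine:
    """Axis-aligned line: ``vertical`` fixes x = level (span over y),
    ``horizontal`` fixes y = level (span over x)."""

    axis: str  # "vertical" | "horizontal"
    level: float
    span: tuple[float, float]

    def __post_init__(self) -> None:
        if self.axis not in ("vertical", "horizontal"):
            raise ValueError("axis must be 'vertical' or 'horizontal'")
        if not self.span[1] > self.span[0]:
            raise ValueError("span must be a non-degenerate interval")


@dataclass(frozen=True)
class Query:
    lines: tuple[QueryLine, ...]
    avoid: tuple[QueryLine, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.lines) < 1:
            raise ValueError("a query needs at least one ordered line")


@dataclass(frozen=True)
class Crossing:
    time: float
    index: int  # index of the sample preceding (or at) the crossing
    valid: bool


@dataclass(frozen=True)
class Match:
    sample_range: tuple[int, int]  # first..last sample index (inclusive)
    crossing_times: tuple[float, ...]  # one per ordered query line
    crossing_valid: tuple[bool, ...]
    valid: bool  # all crossings valid

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.crossing_times, self.crossing_times[1:])):
            raise ValueError("crossing times must be strictly increasing")


def crossings(track: TrackingSeries, line: QueryLine) -> list[Crossing]:
    """All crossings of ``line`` by the trajectory, in time order.

    A crossing is registered for each consecutive sample pair straddling the
    line's level whose interpolated intersection lies within the span; its
    timestamp interpolates linearly between the samples.  A sample landing
    exactly on the line counts as a crossing completed at that sample's
    timestamp (sided by the preceding sample); it is not double-counted when
    the trajectory then leaves the line.  Crossing validity is the
    conjunction of the two samples' validity flags.
    """
    if len(track) == 0:
        raise ValueError("track is empty")
    if line.axis == "vertical":
        s = track.x - line.level
        other = track.y
    else:
        s = track.y - line.level
        other = track.x
    out: list[Crossing] = []
    lo, hi = line.span
    t, valid = track.t, track.valid
    for i in range(len(track) - 1):
        d0, d1 = s[i], s[i + 1]
        if d0 == 0.0:
            continue  # any crossing here was completed at sample i
        if d1 == 0.0:
            if lo <= other[i + 1] <= hi:
                out.append(Crossing(float(t[i + 1]), i, bool(valid[i] and valid[i + 1])))
            continue
        if (d0 > 0) == (d1 > 0):
            continue
        frac = d0 / (d0 - d1)
        oc = other[i] + frac * (other[i + 1] - other[i])
        if lo <= oc <= hi:
            tc = t[i] + frac * (t[i + 1] - t[i])
            out.append(Crossing(float(tc), i, bool(valid[i] and valid[i + 1])))
    return out


def run_query(
    track: TrackingSeries,
    query: Query | Sequence[QueryLine],
    avoid: Sequence[QueryLine] = (),
) -> list[Match]:
    """Greedy earliest-start, non-overlapping in-order matching.

    A candidate match begins at the earliest uncommitted crossing of the
    first line and completes with the first subsequent crossing of each
    remaining line in order.  Any avoid-line crossing strictly inside the
    candidate's (first, last) crossing window disqualifies it, and the scan
    resumes at the next crossing of the first line.  Committed matches never
    overlap: the next match starts strictly after the previous one ends.
    """
    if isinstance(query, Query):
        lines, avoid = query.lines, tuple(query.avoid) + tuple(avoid)
    else:
        lines = tuple(query)
    per_line = [crossings(track, ln) for ln in lines]
    avoid_times = np.array(
        sorted(c.time for ln in avoid for c in crossings(track, ln))
    )
    matches: list[Match] = []
    ptr0 = 0
    committed_until = -np.inf
    first = per_line[0]
    while ptr0 < len(first):
        c0 = first[ptr0]
        if c0.time <= committed_until:
            ptr0 += 1
            continue
        chain = [c0]
        ok = True
        for cl in per_line[1:]:
            nxt = next((c for c in cl if c.time > chain[-1].time), None)
            if nxt is None:
                ok = False
                break
            chain.append(nxt)
        if not ok:
            break  # no later completion possible for this or any later start
        t_first, t_last = chain[0].time, chain[-1].time
        n_avoid = int(
            np.searchsorted(avoid_times, t_last, side="left")
            - np.searchsorted(avoid_times, t_first, side="right")
        )
        if n_avoid > 0:
            ptr0 += 1
            continue
        i_first = chain[0].index
        i_last = max(c.index + 1 for c in chain)
        matches.append(
            Match(
                sample_range=(i_first, i_last),
                crossing_times=tuple(c.time for c in chain),
                crossing_valid=tuple(c.valid for c in chain),
                valid=all(c.valid for c in chain),
            )
        )
        committed_until = t_last
        ptr0 += 1
    return matches


def validity_gate(match: Match, required_line_indices: Iterable[int]) -> bool:
    """True iff every required crossing of the match is tracking-valid.

    Crossings at lines not listed may be invalid — signal loss elsewhere in
    the maze does not discard the match.
    """
    n = len(match.crossing_valid)
    ok = True
    for i in required_line_indices:
        if not (0 <= i < n):
            raise IndexError(f"query has no line {i}")
        ok = ok and match.crossing_valid[i]
    return ok


# ---------------------------------------------------------------------------
# standard query library for the canonical maze
# ---------------------------------------------------------------------------


def _vline(x: float, y0: float, y1: float) -> QueryLine:
    return QueryLine("vertical", x, (min(y0, y1), max(y0, y1)))


def _hline(y: float, x0: float, x1: float) -> QueryLine:
    return QueryLine("horizontal", y, (min(x0, x1), max(x0, x1)))


@dataclass
class StandardQueryLibrary:
    """Named queries for the canonical end-to-end T-maze.

    * ``choice_query(origin, outcome)`` — one of the four choice-trial
      queries (origins R1/R2 x correct/error).  Lines: one in the origin
      reward arm, then the interval boundary lines a–j: eight vertical lines
      spanning the central three-quarters of the central arm (one eighth in
      from both ends), then three horizontal lines in the destination
      crossbar at the choice-turn exit and beyond.  Interval h (between the
      final central-arm line and the first crossbar line) encompasses the
      choice turn per se; i and j directly follow it.
    * ``turn_query(turn_id, direction)`` — 16 queries, one per turn (1–8)
      and travel direction, whose two crossing times bracket the turn.
    * ``central_arm_lines`` — the pair of vertical lines one eighth into the
      central arm at both ends, delimiting the central three-quarters.

    Avoid lines flank every query so that a greedy matcher cannot stitch
    crossings from two different passes through the maze into one match.
    """

    maze: MazeGeometry
    n_central_intervals: int = 7  # intervals a..g along the central arm
    turn_margin: float = 1.25  # distance of turn query lines from the corner
    guard_margin: float = 2.5  # distance of flanking avoid lines

    queries: dict[str, Query] = field(default_factory=dict, init=False)

    def __post_init__(self) -> None:
        c, h = CENTRAL_HALF, CROSS_HALF
        eighth = 2 * c / 8.0
        self.central_west = -c + eighth  # x = -3.75 in canonical units
        self.central_east = c - eighth  # x = +3.75
        self.central_span = (-0.5, 0.5)
        self._build_choice_queries()
        self._build_turn_queries()
        self.central_arm_lines = (
            _vline(self.central_west, *self.central_span),
            _vline(self.central_east, *self.central_span),
        )

    # -- construction --------------------------------------------------------

    def _build_choice_queries(self) -> None:
        c, h = CENTRAL_HALF, CROSS_HALF
        m, g = self.turn_margin, self.guard_margin
        xs = np.linspace(self.central_west, self.central_east, self.n_central_intervals + 1)
        for origin in ("R1", "R2"):
            o_y = h if origin == "R1" else -h
            origin_line = _vline(-c - m, o_y - 0.5, o_y + 0.5)
            for outcome in ("correct", "error"):
                # destination side of the choice turn
                if (origin == "R1") == (outcome == "correct"):
                    dest_sign = 1.0  # upper crossbar (R3 side)
                else:
                    dest_sign = -1.0  # lower crossbar (R4 side)
                exit_ys = [dest_sign * m, dest_sign * (m + 0.75), dest_sign * (m + 1.5)]
                lines = [origin_line]
                lines += [_vline(float(x), *self.central_span) for x in xs]
                lines += [_hline(y, c - 0.5, c + 0.5) for y in exit_ys]
                avoid = (
                    # opposite choice arm: rejects the other outcome
                    _hline(-dest_sign * m, c - 0.5, c + 0.5),
                    # opposite origin arm: rejects runs touching the other start
                    _vline(-c - m, -o_y - 0.5, -o_y + 0.5),
                )
                name = f"choice_{origin}_{outcome}"
                self.queries[name] = Query(tuple(lines), avoid, name)

    def _build_turn_queries(self) -> None:
        m, g = self.turn_margin, self.guard_margin
        for tid, (node, legs) in turn_locations(self.maze).items():
            nx, ny = node
            line_of = {}
            guard_of = {}
            for d in legs:
                line_of[d] = self._leg_line(node, d, m)
                guard_of[d] = self._leg_line(node, d, g)
            # third branch of a junction also gets a guard
            extra_guards = [
                self._leg_line(node, d, m)
                for d in self.maze.nodes[node]
                if d not in legs
            ]
            a, b = legs
            for entry, exit_ in ((a, b), (b, a)):
                direction = _turn_direction(entry, exit_)
                lines = (line_of[entry], line_of[exit_])
                avoid = tuple([guard_of[entry], guard_of[exit_], *extra_guards])
                name = f"turn{tid}_{direction}"
                self.queries[name] = Query(lines, avoid, name)

    def _leg_line(self, node, d: str, dist: float) -> QueryLine:
        nx, ny = node
        if d == "N":
            return _hline(ny + dist, nx - 0.5, nx + 0.5)
        if d == "S":
            return _hline(ny - dist, nx - 0.5, nx + 0.5)
        if d == "E":
            return _vline(nx + dist, ny - 0.5, ny + 0.5)
        return _vline(nx - dist, ny - 0.5, ny + 0.5)

    # -- access --------------------------------------------------------------

    def __getitem__(self, name: str) -> Query:
        return self.queries[name]

    def choice_query(self, origin: str, outcome: str) -> Query:
        return self.queries[f"choice_{origin}_{outcome}"]

    def turn_query(self, turn_id: int, direction: str) -> Query:
        return self.queries[f"turn{turn_id}_{direction}"]

    @property
    def turn_query_names(self) -> list[str]:
        return [n for n in self.queries if n.startswith("turn")]

    # -- extraction ----------------------------------------------------------

    def interval_windows(self, match: Match) -> dict[str, tuple[float, float]]:
        """Interval name -> (t0, t1) windows a..j from a choice-query match.

        The first crossing is the origin-arm line; the following 12
        crossings bound the 10 intervals a..j (8 central-arm lines then 3
        crossbar lines; the last crossbar line closes j).
        """
        times = match.crossing_times[1:]
        names = INTERVAL_NAMES[: len(times) - 1]
        return {nm: (times[i], times[i + 1]) for i, nm in enumerate(names)}

    def interval_validity(self, match: Match) -> dict[str, bool]:
        flags = match.crossing_valid[1:]
        names = INTERVAL_NAMES[: len(flags) - 1]
        return {nm: (flags[i] and flags[i + 1]) for i, nm in enumerate(names)}

    def choice_turn_window(self, match: Match) -> tuple[float, float]:
        """The choice-turn interval h of a choice-query match."""
        return self.interval_windows(match)["h"]

    def central_arm_window(self, match: Match) -> tuple[float, float]:
        """Central three-quarters traversal window of a choice-query match."""
        times = match.crossing_times[1:]
        return (times[0], times[self.n_central_intervals])

    def central_arm_validity(self, match: Match) -> bool:
        flags = match.crossing_valid[1:]
        return bool(flags[0] and flags[self.n_central_intervals])

    def turn_table(self, track: TrackingSeries, require_valid: bool = True) -> pd.DataFrame:
        """All turn traversals found in a track, one row per traversal.

        Columns: turn_id, direction, t_start, t_end, duration, valid.
        With ``require_valid`` only traversals whose two crossings are valid
        are returned (validity gating at the required lines).
        """
        rows = []
        for tid in range(1, 9):
            for direction in ("left", "right"):
                q = self.queries.get(f"turn{tid}_{direction}")
                if q is None:
                    continue
                for match in run_query(track, q):
                    ok = validity_gate(match, range(len(q.lines)))
                    if require_valid and not ok:
                        continue
                    t0, t1 = match.crossing_times[0], match.crossing_times[-1]
                    rows.append(
                        {
                            "turn_id": tid,
                            "direction": direction,
                            "t_start": t0,
                            "t_end": t1,
                            "duration": t1 - t0,
                            "valid": ok,
                        }
                    )
        df = pd.DataFrame(rows, columns=["turn_id", "direction", "t_start", "t_end", "duration", "valid"])
        return df.sort_values("t_start", ignore_index=True) if len(df) else df

    def choice_trial_table(self, track: TrackingSeries) -> pd.DataFrame:
        """All choice trials found in a track via the four choice queries.

        Columns: origin, outcome, t_start, t_end, central_t0/t1 (+validity),
        interval windows a..j as ``t_<name>_0/1`` with ``valid_<name>``.
        """
        rows = []
        for origin in ("R1", "R2"):
            for outcome in ("correct", "error"):
                q = self.choice_query(origin, outcome)
                for match in run_query(track, q):
                    ivals = self.interval_windows(match)
                    ival_valid = self.interval_validity(match)
                    # trial's choice-turn direction: correct from R1 is the
                    # left turn to R3, correct from R2 the right turn to R4
                    if (origin == "R1") == (outcome == "correct"):
                        choice_dir = "left"
                    else:
                        choice_dir = "right"
                    row = {
                        "origin": origin,
                        "outcome": outcome,
                        "choice_dir": choice_dir,
                        "t_start": match.crossing_times[0],
                        "t_end": match.crossing_times[-1],
                        "central_t0": self.central_arm_window(match)[0],
                        "central_t1": self.central_arm_window(match)[1],
                        "central_valid": self.central_arm_validity(match),
                    }
                    for nm, (a, b) in ivals.items():
                        row[f"t_{nm}_0"], row[f"t_{nm}_1"] = a, b
                        row[f"valid_{nm}"] = ival_valid[nm]
                    rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values("t_start", ignore_index=True) if len(df) else df


def _turn_direction(entry: str, exit_: str) -> str:
    """Traversal direction: entering toward the node along ``entry``'s
    reverse... — entry/exit are directions *from* the node, so the agent
    arrives heading opposite to ``entry`` and leaves heading ``exit_``."""
    from .maze import left_of, reverse_of

    arriving = reverse_of(entry)
    return "left" if left_of(arriving) == exit_ else "right"


def standard_queries(maze: MazeGeometry, **kwargs) -> StandardQueryLibrary:
    """Build the standard query library for the canonical maze geometry."""
    for label in ("R1", "R2", "R3", "R4"):
        if label not in maze.reward_points:
            raise ValueError(f"maze lacks reward point {label}")
    return StandardQueryLibrary(maze, **kwargs)
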