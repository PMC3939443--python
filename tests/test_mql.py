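"""Query engine: crossings, ordered matching, avoid lines, validity gating.

The matching engine is checked against an independent brute-force oracle:
crossings recomputed in pure python and in-order chains enumerated via
itertools.product, reduced by the same greedy non-overlap rule.
"""

import itertools

import numpy as np
import pytest

from tmaze.mql import (
    Match,
    Query,
    QueryLine,
    TrackingSeries,
    crossings,
    run_query,
    standard_queries,
    validity_gate,
)


def track_of(points, valid=None):
    points = np.asarray(points, dtype=float)
    t = points[:, 0] if points.shape[1] == 3 else np.arange(len(points), dtype=float)
    xy = points[:, -2:]
    if valid is None:
        valid = np.ones(len(points), dtype=bool)
    return TrackingSeries(t=t, x=xy[:, 0], y=xy[:, 1], valid=np.asarray(valid, bool))


VLINE = QueryLine("vertical", 0.0, (-10.0, 10.0))


class TestCrossings:
    def test_trajectory_on_one_side_has_no_crossings(self):
        track = track_of([(0, -3, 0), (1, -1, 1), (2, -2, -1)])
        assert crossings(track, VLINE) == []

    def test_straddling_pair_interpolates_midpoint_timestamp(self):
        track = track_of([(0, -1, 0), (1, 1, 0)])
        (c,) = crossings(track, VLINE)
        assert c.time == pytest.approx(0.5)
        assert c.index == 0 and c.valid

    def test_intersection_outside_span_ignored(self):
        line = QueryLine("vertical", 0.0, (2.0, 3.0))
        track = track_of([(0, -1, 0), (1, 1, 0)])  # crosses x=0 at y=0
        assert crossings(track, line) == []

    def test_sample_exactly_on_line_counts_once(self):
        track = track_of([(0, -1, 0), (1, 0, 0), (2, 1, 0)])
        (c,) = crossings(track, VLINE)
        assert c.time == 1.0

    def test_crossing_validity_is_conjunction_of_sample_flags(self):
        track = track_of([(0, -1, 0), (1, 1, 0)], valid=[True, False])
        (c,) = crossings(track, VLINE)
        assert not c.valid

    def test_horizontal_line(self):
        line = QueryLine("horizontal", 1.0, (-5.0, 5.0))
        track = track_of([(0, 0, 0), (2, 0, 2)])
        (c,) = crossings(track, line)
        assert c.time == pytest.approx(1.0)

    def test_empty_track_rejected(self):
        empty = TrackingSeries(np.empty(0), np.empty(0), np.empty(0), np.empty(0, bool))
        with pytest.raises(ValueError, match="empty"):
            crossings(empty, VLINE)


def lines_at(*xs):
    return tuple(QueryLine("vertical", x, (-10.0, 10.0)) for x in xs)


class TestRunQuery:
    def test_canonical_in_order_crossing_yields_one_match(self):
        track = track_of([(0, -1, 0), (1, 1, 0), (2, 3, 0), (3, 5, 0)])
        (m,) = run_query(track, lines_at(0, 2, 4))
        assert len(m.crossing_times) == 3
        assert m.crossing_times == pytest.approx((0.5, 1.5, 2.5))

    def test_out_of_order_crossings_do_not_match(self):
        # crosses the second line (x=2) before the first (x=0), never x=2 again
        track = track_of([(0, 3, 0), (1, 1, 0), (2, -1, 0)])
        assert run_query(track, lines_at(0, 2)) == []
        assert len(run_query(track, lines_at(2, 0))) == 1

    def test_avoid_crossing_inside_window_disqualifies(self):
        track = track_of([(0, -1, 0), (1, 1, 2), (2, 1, -2), (3, 5, 0)])
        q = Query(lines_at(0, 4), avoid=(QueryLine("horizontal", 0.0, (0.0, 2.0)),))
        assert run_query(track, q) == []

    def test_avoid_crossing_outside_window_is_harmless(self):
        track = track_of([(0, 0, 2), (1, 0.5, -2), (2, 1.5, 0), (3, 5, 0)])
        # avoid line crossed before the first query-line crossing
        q = Query(lines_at(1, 4), avoid=(QueryLine("horizontal", 0.0, (-1.0, 1.0)),))
        assert len(run_query(track, q)) == 1

    def test_matches_are_non_overlapping_and_chronological(self):
        xs = [-1, 1, 3, -1, 1, 3, -1, 1, 3]
        track = track_of([(i, x, 0) for i, x in enumerate(xs)])
        ms = run_query(track, lines_at(0, 2))
        assert len(ms) == 3
        ends = [m.crossing_times[-1] for m in ms]
        starts = [m.crossing_times[0] for m in ms]
        assert all(s > e for e, s in zip(ends, starts[1:]))

    def test_reversed_trajectory_loses_the_match(self):
        pts = [(0, -1, 0), (1, 1, 0), (2, 3, 0)]
        fwd = track_of(pts)
        rev = track_of([(i, x, y) for i, (_, x, y) in enumerate(reversed(pts))])
        q = lines_at(0, 2)
        assert len(run_query(fwd, q)) == 1
        assert run_query(rev, q) == []

    def test_match_times_are_a_subset_of_line_crossings(self):
        rng = np.random.default_rng(0)
        track = track_of(
            [(i, x, y) for i, (x, y) in enumerate(rng.uniform(-5, 5, (200, 2)))]
        )
        q = lines_at(-2, 0, 2)
        for m in run_query(track, q):
            for tc, line in zip(m.crossing_times, q):
                assert any(abs(c.time - tc) < 1e-12 for c in crossings(track, line))


class TestValidityGate:
    def make_match(self, flags):
        return Match((0, 10), tuple(float(i) for i in range(len(flags))), tuple(flags), all(flags))

    def test_all_crossings_valid_passes(self):
        assert validity_gate(self.make_match([True, True, True]), [0, 1, 2])

    def test_required_invalid_crossing_fails(self):
        assert not validity_gate(self.make_match([True, False, True]), [0, 1])

    def test_invalid_crossing_at_unrequired_line_is_tolerated(self):
        assert validity_gate(self.make_match([True, False, True]), [0, 2])

    def test_unknown_index_rejected(self):
        with pytest.raises(IndexError):
            validity_gate(self.make_match([True]), [3])


# ---------------------------------------------------------------------------
# brute-force oracle equivalence
# ---------------------------------------------------------------------------


def oracle_crossings(track, line):
    out = []
    for i in range(len(track) - 1):
        if line.axis == "vertical":
            p0, p1 = track.x[i] - line.level, track.x[i + 1] - line.level
            o0, o1 = track.y[i], track.y[i + 1]
        else:
            p0, p1 = track.y[i] - line.level, track.y[i + 1] - line.level
            o0, o1 = track.x[i], track.x[i + 1]
        if p0 == 0.0:
            continue
        if p1 == 0.0:
            if line.span[0] <= o1 <= line.span[1]:
                out.append(float(track.t[i + 1]))
            continue
        if (p0 < 0 < p1) or (p1 < 0 < p0):
            f = p0 / (p0 - p1)
            if line.span[0] <= o0 + f * (o1 - o0) <= line.span[1]:
                out.append(float(track.t[i] + f * (track.t[i + 1] - track.t[i])))
    return out


def oracle_matches(track, lines, avoid):
    """Exhaustive in-order chain enumeration + greedy non-overlap reduction."""
    per = [oracle_crossings(track, ln) for ln in lines]
    avoid_t = sorted(t for ln in avoid for t in oracle_crossings(track, ln))
    best_by_start = {}
    if all(per):
        for combo in itertools.product(*per):
            if all(b > a for a, b in zip(combo, combo[1:])):
                t0 = combo[0]
                if t0 not in best_by_start or combo < best_by_start[t0]:
                    best_by_start[t0] = combo
    out = []
    end = float("-inf")
    for t0 in sorted(best_by_start):
        if t0 <= end:
            continue
        combo = best_by_start[t0]
        if any(combo[0] < a < combo[-1] for a in avoid_t):
            continue
        out.append(combo)
        end = combo[-1]
    return out


@pytest.mark.parametrize("seed", range(25))
def test_engine_agrees_with_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 120))
    track = track_of(
        [(i, x, y) for i, (x, y) in enumerate(rng.uniform(-5, 5, (n, 2)))],
        valid=rng.random(n) > 0.1,
    )
    n_lines = int(rng.integers(1, 4))
    n_avoid = int(rng.integers(0, 3))

    def rand_line():
        axis = "vertical" if rng.random() < 0.5 else "horizontal"
        lo = rng.uniform(-6, 5)
        return QueryLine(axis, float(rng.uniform(-4, 4)), (lo, lo + rng.uniform(0.5, 8)))

    lines = tuple(rand_line() for _ in range(n_lines))
    avoid = tuple(rand_line() for _ in range(n_avoid))
    got = [m.crossing_times for m in run_query(track, lines, avoid)]
    want = [tuple(c) for c in oracle_matches(track, lines, avoid)]
    assert len(got) == len(want)
    for g, w in zip(got, want):
        assert g == pytest.approx(w)


# ---------------------------------------------------------------------------
# standard library
# ---------------------------------------------------------------------------


class TestStandardQueries:
    def test_sixteen_turn_queries(self, library):
        assert len(library.turn_query_names) == 16
        for tid in range(1, 9):
            for d in ("left", "right"):
                assert library.turn_query(tid, d).lines

    def test_central_arm_lines_sit_one_eighth_into_the_arm(self, library):
        # central arm spans x in [-5, 5]; an eighth of its 10-unit length is 1.25
        west, east = library.central_arm_lines
        assert west.level == pytest.approx(-5 + 10 / 8)
        assert east.level == pytest.approx(5 - 10 / 8)

    def test_four_choice_queries_with_ten_intervals(self, library):
        names = [n for n in library.queries if n.startswith("choice")]
        assert sorted(names) == [
            "choice_R1_correct",
            "choice_R1_error",
            "choice_R2_correct",
            "choice_R2_error",
        ]
        q = library.choice_query("R2", "correct")
        # origin line + 8 central-arm boundaries + 3 crossbar boundaries
        assert len(q.lines) == 12

    def test_missing_reward_point_rejected(self, maze):
        import dataclasses

        broken = dataclasses.replace(
            maze, reward_points={k: v for k, v in maze.reward_points.items() if k != "R4"}
        )
        with pytest.raises(ValueError, match="R4"):
            standard_queries(broken)

    def test_correct_trial_matches_correct_query_only(self, library, small_session):
        _, track, truth = small_session
        first = truth.trials.iloc[0]
        q_good = library.choice_query(first["origin"], first["outcome"])
        other = "error" if first["outcome"] == "correct" else "correct"
        q_bad = library.choice_query(first["origin"], other)
        good = run_query(track, q_good)
        assert any(
            abs(m.crossing_times[0] - first["t_depart"]) < 5.0 for m in good
        )
        bad = run_query(track, q_bad)
        n_other = (
            (truth.trials["origin"] == first["origin"])
            & (truth.trials["outcome"] == other)
        ).sum()
        assert len(bad) == n_other
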