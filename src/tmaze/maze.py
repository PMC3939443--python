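"""Virtual 2D end-to-end T-maze: geometry, agent kinematics and sensory coding.

The maze is a planar graph of axis-aligned line segments.  An agent occupies a
point on one segment, faces one of four compass headings, and perceives a
one-hot "scene" out of five possibilities (straight corridor, dead end,
right-hand bend, T-junction, left-hand bend).  The scene drives the sensory
inputs I1..I5 of the accumulator model; movement is constrained to the
segments, with turning permitted only at corners and junctions.

The canonical maze has nine segments arranged as an H: a horizontal central
arm, a vertical crossbar at each end, and four short horizontal reward arms
ending at the reward points R1 (top left), R2 (bottom left), R3 (top right)
and R4 (bottom right).  Only the topology and relative lengths matter to the
model; the coordinates below are the package's canonical choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "HEADINGS",
    "ACTIONS",
    "MazeGeometry",
    "AgentPose",
    "SensoryScene",
    "OffMazeError",
    "default_maze",
    "classify_location",
    "legal_actions",
    "advance",
    "left_of",
    "right_of",
    "reverse_of",
]

HEADINGS = ("N", "E", "S", "W")
ACTIONS = ("straight", "turn_around", "right", "left")

_VEC = {"N": (0.0, 1.0), "E": (1.0, 0.0), "S": (0.0, -1.0), "W": (-1.0, 0.0)}
_LEFT = {"N": "W", "W": "S", "S": "E", "E": "N"}
_RIGHT = {"N": "E", "E": "S", "S": "W", "W": "N"}
_REVERSE = {"N": "S", "S": "N", "E": "W", "W": "E"}

_TOL = 1e-9


def left_of(heading: str) -> str:
    """Compass direction 90 degrees to the left of ``heading``."""
    return _LEFT[heading]


def right_of(heading: str) -> str:
    """Compass direction 90 degrees to the right of ``heading``."""
    return _RIGHT[heading]


def reverse_of(heading: str) -> str:
    return _REVERSE[heading]


class OffMazeError(ValueError):
    """Raised when a pose does not lie on any maze segment."""


@dataclass(frozen=True)
class SensoryScene:
    """One-hot sensory inputs of the model.

    Exactly one of I1 (straight corridor), I2 (dead end), I3 (right-hand
    bend), I4 (T-junction) and I5 (left-hand bend) equals 1.
    """

    i1: int = 0
    i2: int = 0
    i3: int = 0
    i4: int = 0
    i5: int = 0

    def __post_init__(self) -> None:
        if sum((self.i1, self.i2, self.i3, self.i4, self.i5)) != 1:
            raise ValueError("scene must be one-hot")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.i1, self.i2, self.i3, self.i4, self.i5)

    @property
    def active(self) -> int:
        """Index (1-based) of the active input."""
        return 1 + self.as_tuple().index(1)


SCENES = {
    1: SensoryScene(i1=1),
    2: SensoryScene(i2=1),
    3: SensoryScene(i3=1),
    4: SensoryScene(i4=1),
    5: SensoryScene(i5=1),
}


@dataclass(frozen=True)
class AgentPose:
    x: float
    y: float
    heading: str
    segment_id: int

    def __post_init__(self) -> None:
        if self.heading not in HEADINGS:
            raise ValueError(f"unknown heading {self.heading!r}")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class MazeGeometry:
    """Axis-aligned segment graph with labelled reward points.

    ``segments`` is a list of endpoint pairs ``((x1, y1), (x2, y2))``; every
    segment must be horizontal or vertical.  ``reward_points`` maps labels
    (R1..R4) to degree-1 endpoints.  Junction connectivity is derived from
    shared endpoints and stored in ``nodes``: a mapping from node coordinate
    to ``{direction: segment_id}`` for each segment leaving that node.
    """

    segments: list[tuple[tuple[float, float], tuple[float, float]]]
    reward_points: dict[str, tuple[float, float]]
    choice_junction: tuple[float, float]
    guided_junction: tuple[float, float]
    nodes: dict[tuple[float, float], dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = [
            (tuple(map(float, a)), tuple(map(float, b))) for a, b in self.segments
        ]
        self.reward_points = {
            k: tuple(map(float, v)) for k, v in self.reward_points.items()
        }
        self.choice_junction = tuple(map(float, self.choice_junction))
        self.guided_junction = tuple(map(float, self.guided_junction))
        self.nodes = {}
        for sid, (a, b) in enumerate(self.segments):
            if not (abs(a[0] - b[0]) < _TOL or abs(a[1] - b[1]) < _TOL):
                raise ValueError(f"segment {sid} is not axis-aligned")
            if a == b:
                raise ValueError(f"segment {sid} is degenerate")
            for start, end in ((a, b), (b, a)):
                d = _direction(start, end)
                self.nodes.setdefault(start, {})[d] = sid
        self._validate()

    def _validate(self) -> None:
        # connectivity via union-find over shared endpoints
        parent = list(range(len(self.segments)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for exits in self.nodes.values():
            sids = list(exits.values())
            for s in sids[1:]:
                parent[find(s)] = find(sids[0])
        if len({find(i) for i in range(len(self.segments))}) != 1:
            raise ValueError("maze segment graph is not connected")
        for label, p in self.reward_points.items():
            if p not in self.nodes or len(self.nodes[p]) != 1:
                raise ValueError(f"reward point {label} is not a degree-1 endpoint")

    # -- queries -------------------------------------------------------------

    def is_node(self, x: float, y: float) -> bool:
        return (x, y) in self.nodes

    def node_exits(
        self, node: tuple[float, float], blocked: Iterable[tuple] = ()
    ) -> dict[str, int]:
        """Open exits at ``node``: direction -> segment id, minus barriers."""
        blocked = set(blocked)
        return {
            d: sid
            for d, sid in self.nodes[node].items()
            if (node, d) not in blocked
        }

    def segment_of(self, x: float, y: float) -> int:
        for sid, (a, b) in enumerate(self.segments):
            if _on_segment((x, y), a, b):
                return sid
        raise OffMazeError(f"position ({x}, {y}) lies on no segment")

    def contains(self, x: float, y: float) -> bool:
        try:
            self.segment_of(x, y)
            return True
        except OffMazeError:
            return False

    def reward_label_at(self, x: float, y: float) -> str | None:
        for label, p in self.reward_points.items():
            if abs(p[0] - x) < _TOL and abs(p[1] - y) < _TOL:
                return label
        return None

    # -- (de)serialization ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": self.segments,
                "reward_points": {k: list(v) for k, v in self.reward_points.items()},
                "choice_junction": list(self.choice_junction),
                "guided_junction": list(self.guided_junction),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MazeGeometry":
        d = json.loads(text)
        return cls(
            segments=[(tuple(a), tuple(b)) for a, b in d["segments"]],
            reward_points={k: tuple(v) for k, v in d["reward_points"].items()},
            choice_junction=tuple(d["choice_junction"]),
            guided_junction=tuple(d["guided_junction"]),
        )


def _direction(a: tuple[float, float], b: tuple[float, float]) -> str:
    if abs(a[0] - b[0]) < _TOL:
        return "N" if b[1] > a[1] else "S"
    return "E" if b[0] > a[0] else "W"


def _on_segment(p, a, b) -> bool:
    x, y = p
    lo_x, hi_x = min(a[0], b[0]), max(a[0], b[0])
    lo_y, hi_y = min(a[1], b[1]), max(a[1], b[1])
    return (lo_x - _TOL <= x <= hi_x + _TOL) and (lo_y - _TOL <= y <= hi_y + _TOL) and (
        abs(a[0] - b[0]) < _TOL
        and abs(x - a[0]) < _TOL
        or abs(a[1] - b[1]) < _TOL
        and abs(y - a[1]) < _TOL
    )


# canonical geometry ---------------------------------------------------------

CENTRAL_HALF = 5.0  # central arm runs x in [-5, 5] along y = 0
CROSS_HALF = 3.0  # crossbars run y in [-3, 3] at x = +/-5
REWARD_ARM = 3.0  # reward arms extend outward to |x| = 8


def load_geometry(path) -> MazeGeometry:
    """Load a maze geometry from a JSON file (see ``MazeGeometry.to_json``)."""
    from pathlib import Path

    return MazeGeometry.from_json(Path(path).read_text())


def default_geometry_path():
    """Path of the canonical geometry file shipped with the package."""
    from importlib.resources import files

    return files("tmaze").joinpath("data/default_maze.json")


def default_maze() -> MazeGeometry:
    """The canonical nine-segment end-to-end T-maze.

    Segment order: central arm, west crossbar halves (upper, lower), east
    crossbar halves (upper, lower), then reward arms R1..R4.
    """
    c, h, r = CENTRAL_HALF, CROSS_HALF, REWARD_ARM
    segs = [
        ((-c, 0.0), (c, 0.0)),        # 0 central
        ((-c, 0.0), (-c, h)),         # 1 west upper
        ((-c, -h), (-c, 0.0)),        # 2 west lower
        ((c, 0.0), (c, h)),           # 3 east upper
        ((c, -h), (c, 0.0)),          # 4 east lower
        ((-c - r, h), (-c, h)),       # 5 R1 arm
        ((-c - r, -h), (-c, -h)),     # 6 R2 arm
        ((c, h), (c + r, h)),         # 7 R3 arm
        ((c, -h), (c + r, -h)),       # 8 R4 arm
    ]
    rp = {
        "R1": (-c - r, h),
        "R2": (-c - r, -h),
        "R3": (c + r, h),
        "R4": (c + r, -h),
    }
    return MazeGeometry(
        segments=segs,
        reward_points=rp,
        choice_junction=(c, 0.0),
        guided_junction=(-c, 0.0),
    )


# the eight turn locations of the canonical maze, used by the standard queries
# and the synthetic generator.  Each is a (node, legs) pair where legs are the
# two directions (from the node) joined by the turn.  Turns 6 and 7 are the
# left and right choice turns at the T-junction.
def turn_locations(maze: MazeGeometry) -> dict[int, tuple[tuple[float, float], tuple[str, str]]]:
    c, h = CENTRAL_HALF, CROSS_HALF
    wj, ej = maze.guided_junction, maze.choice_junction
    return {
        1: ((-c, h), ("W", "S")),   # R1 arm <-> west upper
        2: ((-c, -h), ("W", "N")),  # R2 arm <-> west lower
        3: (wj, ("N", "E")),        # west junction <-> upper crossbar
        4: (wj, ("S", "E")),        # west junction <-> lower crossbar
        5: ((c, h), ("E", "S")),    # R3 arm <-> east upper
        6: (ej, ("W", "N")),        # choice junction <-> upper (choice left)
        7: (ej, ("W", "S")),        # choice junction <-> lower (choice right)
        8: ((c, -h), ("E", "N")),   # R4 arm <-> east lower
    }


# sensory classification ------------------------------------------------------


def _node_for_pose(pose: AgentPose, maze: MazeGeometry) -> tuple[float, float] | None:
    for node in maze.nodes:
        if abs(node[0] - pose.x) < _TOL and abs(node[1] - pose.y) < _TOL:
            return node
    return None


def classify_location(
    pose: AgentPose,
    maze: MazeGeometry,
    blocked: Iterable[tuple] = (),
) -> SensoryScene:
    """Map an agent pose to the one-hot sensory scene.

    Mid-segment poses facing along their segment see a straight corridor
    (I1).  At a node, the open exits (excluding the direction the agent came
    from and any barrier-blocked exits) determine the scene: no exit is a
    dead end (I2); both lateral exits with no straight continuation is a
    T-junction (I4); a single right or left exit is the corresponding bend
    (I3/I5); an open straight continuation reads as corridor (I1).
    """
    if not maze.contains(pose.x, pose.y):
        raise OffMazeError(f"pose at ({pose.x}, {pose.y}) is off the maze")
    node = _node_for_pose(pose, maze)
    if node is None:
        a, b = maze.segments[pose.segment_id]
        seg_dirs = {_direction(a, b), _direction(b, a)}
        if pose.heading not in seg_dirs:
            raise OffMazeError("mid-segment pose must face along its segment")
        return SCENES[1]
    exits = maze.node_exits(node, blocked)
    exits.pop(reverse_of(pose.heading), None)
    straight = pose.heading in exits
    right = right_of(pose.heading) in exits
    left = left_of(pose.heading) in exits
    if not exits:
        return SCENES[2]
    if right and left and not straight:
        return SCENES[4]
    if straight:
        return SCENES[1]
    if right:
        return SCENES[3]
    return SCENES[5]


def legal_actions(
    pose: AgentPose,
    maze: MazeGeometry,
    blocked: Iterable[tuple] = (),
) -> set[str]:
    """Actions that would not drive the agent into a wall.

    Turning left/right is only legal at a node with an open exit in the
    turned direction; moving straight requires open track ahead; turning
    around is always legal (it does not leave the segment).
    """
    legal = {"turn_around"}
    node = _node_for_pose(pose, maze)
    if node is None:
        a, b = maze.segments[pose.segment_id]
        seg_dirs = {_direction(a, b), _direction(b, a)}
        if pose.heading in seg_dirs:
            legal.add("straight")
        return legal
    exits = maze.node_exits(node, blocked)
    if pose.heading in exits:
        legal.add("straight")
    if right_of(pose.heading) in exits:
        legal.add("right")
    if left_of(pose.heading) in exits:
        legal.add("left")
    return legal


def advance(
    pose: AgentPose,
    action: str,
    maze: MazeGeometry,
    speed: float = 2.0,
    duration: float = 0.1,
    blocked: Iterable[tuple] = (),
) -> AgentPose:
    """Execute one action: move ``speed * duration`` along the heading or turn.

    Straight motion is clipped at the end of the current segment (the agent
    stops exactly on the node; it never passes through a junction within one
    step).  Illegal moves (wall ahead, turn away from any exit) leave the
    pose unchanged except that ``turn_around`` always flips the heading.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    if action == "turn_around":
        return AgentPose(pose.x, pose.y, reverse_of(pose.heading), pose.segment_id)

    node = _node_for_pose(pose, maze)
    if action in ("right", "left"):
        if node is None:
            return pose
        new_heading = right_of(pose.heading) if action == "right" else left_of(pose.heading)
        exits = maze.node_exits(node, blocked)
        if new_heading not in exits:
            return pose
        return AgentPose(pose.x, pose.y, new_heading, exits[new_heading])

    # straight
    step = speed * duration
    seg_id = pose.segment_id
    if node is not None:
        exits = maze.node_exits(node, blocked)
        if pose.heading not in exits:
            return pose  # wall ahead: position unchanged
        seg_id = exits[pose.heading]
    a, b = maze.segments[seg_id]
    dx, dy = _VEC[pose.heading]
    # forward endpoint of the segment in the heading direction
    fwd = b if _direction(a, b) == pose.heading else a
    if _direction(a, b) not in (pose.heading, reverse_of(pose.heading)):
        return pose  # heading perpendicular to segment: blocked
    dist_to_end = abs(fwd[0] - pose.x) + abs(fwd[1] - pose.y)
    if dist_to_end < _TOL:
        return pose
    d = min(step, dist_to_end)
    nx, ny = pose.x + dx * d, pose.y + dy * d
    if d == dist_to_end or abs(d - dist_to_end) < _TOL:
        nx, ny = fwd  # land exactly on the node
    return AgentPose(nx, ny, pose.heading, seg_id)
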