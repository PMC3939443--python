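"""Leaky competing accumulator dynamics for the T-maze decision model.

Six leaky integrators — four output units O1..O4 (move straight, turn
around, turn right, turn left) and two working-memory units M1, M2 (memory
of a right / left turn) — evolve by Euler–Maruyama steps of

    dO1 = (I1               - k*O1 - w*(O2+O3+O4)) dt + c dW
    dO2 = (I2               - k*O2 - w*(O1+O3+O4)) dt + c dW
    dO3 = (I3 + I4 + M1     - k*O3 - w*(O1+O2+O4)) dt + c dW
    dO4 = (I4 + I5 + M2     - k*O4 - w*(O1+O2+O3)) dt + c dW
    dM1 = (I3               - k_wm*M1 - w*M2)      dt + c dW
    dM2 = (I5               - k_wm*M2 - w*M1)      dt + c dW

where I1..I5 are the one-hot sensory inputs, k the decay (leak) rate, w the
mutual-inhibition weight and c scales independent Wiener-process noise (each
dW is an independent Gaussian increment with standard deviation sqrt(dt)).
Any unit driven negative by a step is reset to 0.  When k_wm = w and c = 0
the difference M1 - M2 changes only with the inputs, d(M1-M2) = (I3-I5) dt,
so working memories do not decay.

An action is selected when at least one output unit exceeds the decision
threshold; among supra-threshold (and, optionally, physically legal) units
the one with the greatest excitation wins, ties broken by fixed unit order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .maze import SensoryScene

__all__ = ["IntegratorState", "ModelParams", "integrate_step", "select_action", "ACTION_OF_UNIT"]

#: motor meaning of each output unit, in unit order O1..O4
ACTION_OF_UNIT = ("straight", "turn_around", "right", "left")


@dataclass(frozen=True)
class IntegratorState:
    """Excitations of the six integrators; all non-negative."""

    o1: float = 0.0
    o2: float = 0.0
    o3: float = 0.0
    o4: float = 0.0
    m1: float = 0.0
    m2: float = 0.0

    def outputs(self) -> tuple[float, float, float, float]:
        return (self.o1, self.o2, self.o3, self.o4)

    def as_array(self) -> np.ndarray:
        return np.array([self.o1, self.o2, self.o3, self.o4, self.m1, self.m2])


@dataclass(frozen=True)
class ModelParams:
    """Model parameters; defaults follow the reference simulation protocol.

    ``k_wm`` is the leak rate of the working-memory integrators and defaults
    to ``k``; it can be raised independently to degrade memory retention
    while leaving the output layer untouched.
    """

    w: float = 0.2
    k: float = 0.2
    c: float = 0.0001
    dt: float = 0.1
    threshold: float = 1.0
    speed: float = 2.0
    k_wm: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("w", "k", "c", "dt"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not (math.isfinite(self.threshold) and self.threshold > 0):
            raise ValueError("threshold must be positive")
        if self.k_wm is not None and not (math.isfinite(self.k_wm) and self.k_wm >= 0):
            raise ValueError("k_wm must be finite and >= 0")

    @property
    def wm_leak(self) -> float:
        return self.k if self.k_wm is None else self.k_wm


def integrate_step(
    state: IntegratorState,
    scene: SensoryScene,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[Iterable[float]] = None,
) -> IntegratorState:
    """One Euler–Maruyama step of the six coupled integrator equations.

    Noise increments may be supplied directly via ``noise`` (six standard
    normal draws) or drawn from ``rng``; with ``c == 0`` no draws are used
    and the step is deterministic.  Negative results are reset to 0.
    """
    o1, o2, o3, o4, m1, m2 = state.o1, state.o2, state.o3, state.o4, state.m1, state.m2
    for v in (o1, o2, o3, o4, m1, m2):
        if not math.isfinite(v):
            raise ValueError("non-finite integrator state")
    i1, i2, i3, i4, i5 = scene.as_tuple()
    k, w, dt = params.k, params.w, params.dt
    km = params.wm_leak

    n1 = n2 = n3 = n4 = n5 = n6 = 0.0
    if params.c > 0.0:
        if noise is None:
            if rng is None:
                raise ValueError("c > 0 requires an rng or explicit noise draws")
            noise = rng.standard_normal(6)
        n1, n2, n3, n4, n5, n6 = (params.c * math.sqrt(dt) * z for z in noise)

    new = (
        o1 + (i1 - k * o1 - w * (o2 + o3 + o4)) * dt + n1,
        o2 + (i2 - k * o2 - w * (o1 + o3 + o4)) * dt + n2,
        o3 + (i3 + i4 + m1 - k * o3 - w * (o1 + o2 + o4)) * dt + n3,
        o4 + (i4 + i5 + m2 - k * o4 - w * (o1 + o2 + o3)) * dt + n4,
        m1 + (i3 - km * m1 - w * m2) * dt + n5,
        m2 + (i5 - km * m2 - w * m1) * dt + n6,
    )
    clipped = tuple(v if v > 0.0 else 0.0 for v in new)
    return IntegratorState(*clipped)


def select_action(
    state: IntegratorState,
    threshold: float,
    legal: Optional[Iterable[str]] = None,
) -> Optional[str]:
    """Threshold-with-max action selection.

    Returns the action of the output unit with the greatest excitation among
    those exceeding ``threshold`` (restricted to ``legal`` actions when
    given), or ``None`` if no candidate unit is supra-threshold.  Exact ties
    are broken by fixed unit order O1 < O2 < O3 < O4.  While the returned
    action executes, the caller is expected to hold the integrator state
    fixed (enforced by the session loop).
    """
    legal_set = None if legal is None else set(legal)
    best: Optional[str] = None
    best_val = threshold
    for val, action in zip(state.outputs(), ACTION_OF_UNIT):
        if legal_set is not None and action not in legal_set:
            continue
        if val > best_val:  # strict: first (lowest-order) unit wins ties
            best, best_val = action, val
    return best
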