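"""Parabolic approach paths and their traversal under three laws of motion.

A target ball travels in the observer's sagittal plane along a parabola that
launches and lands at eye height.  The parabola is the one a projectile would
trace under gravity ``g`` for flight duration ``D`` and horizontal range ``L``:
vertex height ``h = g D^2 / 8``, launch angle ``atan(4h/L)``.  The same spatial
path can be traversed with three different kinematics:

* ``GRAVITATIONAL`` — constant horizontal velocity, vertical free flight
  (the only law fully consistent with Newtonian projectile motion);
* ``CONST_VERTICAL`` — constant absolute vertical velocity (a triangular
  height profile in time), which makes the horizontal velocity diverge at the
  vertex;
* ``CONST_TANGENTIAL`` — constant speed along the arc, i.e. an arc-length
  reparameterization of the parabola.

All three laws take exactly ``D`` seconds from launch to arrival, so duration
judgements cannot rely on the path itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

G_DEFAULT = 9.8
"""Gravitational acceleration (m/s^2) implied by the experimental design."""

#: half-width (s) of the exclusion window around the constant-vertical vertex
#: inside which analytic horizontal-velocity queries are capped and flagged
VERTEX_CAP_WINDOW = 1e-6


class MotionLaw(Enum):
    """The three kinematic laws used to traverse a parabolic path."""

    CONST_TANGENTIAL = "const_tangential"
    CONST_VERTICAL = "const_vertical"
    GRAVITATIONAL = "gravitational"


@dataclass(frozen=True)
class Condition:
    """One experimental stimulus condition (comparison path).

    Conditions 1-7 are the experimental durations 0.7-1.3 s; condition 4
    (D = 1 s) is the reference.  Conditions 8 and 9 are distance controls:
    they match the initial horizontal distance of conditions 3 and 5 but
    last exactly the reference duration.
    """

    id: int
    L: float
    D: float
    is_control: bool = False
    matched_experimental_id: int | None = None


_CONDITION_ROWS = [
    (1, 1.31, 0.700, False, None),
    (2, 2.01, 0.800, False, None),
    (3, 2.82, 0.900, False, None),
    (4, 3.71, 1.000, False, None),
    (5, 4.70, 1.100, False, None),
    (6, 5.79, 1.200, False, None),
    (7, 6.96, 1.300, False, None),
    (8, 2.83, 1.000, True, 3),
    (9, 4.55, 1.000, True, 5),
]

REFERENCE_CONDITION_ID = 4
T_REF = 1.0
"""Reference motion duration (s)."""


def condition_table() -> list[Condition]:
    """The nine stimulus conditions (7 experimental + 2 distance controls)."""
    return [Condition(*row) for row in _CONDITION_ROWS]


def get_condition(cond_id: int) -> Condition:
    for row in _CONDITION_ROWS:
        if row[0] == cond_id:
            return Condition(*row)
    raise KeyError(f"no condition #{cond_id}")


@dataclass(frozen=True)
class ParabolicPath:
    """A gravity-compatible parabola at eye height.

    Attributes
    ----------
    D, L, g : duration (s), horizontal range (m), gravity (m/s^2).
    h : vertex height above launch, ``g D^2 / 8`` (m).
    alpha0 : launch angle above horizontal (rad).
    S : total arc length (m), closed form.
    """

    D: float
    L: float
    g: float
    h: float
    alpha0: float
    S: float

    def height(self, x: float | np.ndarray) -> float | np.ndarray:
        """Height y(x) = 4 h x (L - x) / L^2 above eye level."""
        return 4.0 * self.h * x * (self.L - x) / self.L**2

    def slope(self, x: float | np.ndarray) -> float | np.ndarray:
        """dy/dx = 4 h (L - 2x) / L^2."""
        return 4.0 * self.h * (self.L - 2.0 * x) / self.L**2

    def arc_length_to(self, x: float | np.ndarray) -> float | np.ndarray:
        """Arc length s(x) from launch, closed form (monotone in x)."""
        a = 4.0 * self.h / self.L  # |slope| at launch
        u = self.slope(x)
        return self.L**2 / (16.0 * self.h) * (_arc_primitive(a) - _arc_primitive(u))


def _arc_primitive(u):
    """Antiderivative kernel u*sqrt(1+u^2) + asinh(u) for the parabola arc."""
    return u * np.sqrt(1.0 + u * u) + np.arcsinh(u)


def make_path(D: float, L: float, g: float = G_DEFAULT) -> ParabolicPath:
    """Build the gravity-compatible parabola for duration ``D`` and range ``L``.

    Raises
    ------
    ValueError
        If any of ``D``, ``L``, ``g`` is not strictly positive.
    """
    if D <= 0 or L <= 0 or g <= 0:
        raise ValueError(f"D, L, g must be positive (got D={D}, L={L}, g={g})")
    h = g * D * D / 8.0
    a = 4.0 * h / L
    alpha0 = math.atan(a)
    S = L * L / (8.0 * h) * (a * math.sqrt(1.0 + a * a) + math.asinh(a))
    return ParabolicPath(D=D, L=L, g=g, h=h, alpha0=alpha0, S=S)


def path_for_condition(cond: Condition, g: float = G_DEFAULT) -> ParabolicPath:
    return make_path(cond.D, cond.L, g)


@dataclass(frozen=True)
class TrajectoryState:
    """Instantaneous state of the ball on a path.

    ``x`` is horizontal progress from launch toward the observer, ``y`` height
    above eye level.  ``capped`` marks constant-vertical states inside the
    vertex exclusion window, where the analytic horizontal velocity diverges
    and the reported value is truncated.
    """

    t: float
    x: float
    y: float
    v_x: float
    v_y: float
    v: float
    capped: bool = False


def _check_t(t: float, D: float) -> None:
    if t < -1e-12 or t > D + 1e-12:
        raise ValueError(f"t={t} outside flight interval [0, {D}]")


def state_gravitational(path: ParabolicPath, t: float) -> TrajectoryState:
    """State under gravitational kinematics: constant v_x, vertical free flight."""
    _check_t(t, path.D)
    v_x = path.L / path.D
    v_y0 = path.g * path.D / 2.0
    x = v_x * t
    y = v_y0 * t - 0.5 * path.g * t * t
    v_y = v_y0 - path.g * t
    return TrajectoryState(t, x, y, v_x, v_y, math.hypot(v_x, v_y))


def state_constant_vertical(path: ParabolicPath, t: float) -> TrajectoryState:
    """State under constant absolute vertical velocity.

    The height profile is triangular: up at ``2h/D`` for the first half, down
    at the same rate for the second.  Horizontal position follows from the
    path equation, so the horizontal velocity grows without bound toward the
    vertex; queries within ``VERTEX_CAP_WINDOW`` of ``D/2`` are evaluated at
    the window edge and flagged ``capped``.
    """
    _check_t(t, path.D)
    D, L, h = path.D, path.L, path.h
    w = 2.0 * h / D  # |v_y| = g D / 4
    half = D / 2.0
    capped = abs(t - half) < VERTEX_CAP_WINDOW
    tq = half - VERTEX_CAP_WINDOW if capped and t <= half else t
    if capped and t > half:
        tq = half + VERTEX_CAP_WINDOW
    ascending = tq <= half
    y = w * tq if ascending else w * (D - tq)
    y = min(y, h)
    root = math.sqrt(max(1.0 - y / h, 0.0))
    x = 0.5 * L * (1.0 - root) if ascending else 0.5 * L * (1.0 + root)
    v_y = w if ascending else -w
    if t == half and not capped:  # pragma: no cover - window covers exact hit
        v_y = 0.0
    v_x = w * L / (4.0 * h * root) if root > 0 else math.inf
    if capped:
        v_y = w * (1.0 if t < half else (-1.0 if t > half else 0.0))
    return TrajectoryState(t, x, y, v_x, v_y, math.hypot(v_x, v_y), capped=capped)


def _invert_arc_length(path: ParabolicPath, s_target: float) -> float:
    """Solve s(x) = s_target by Newton with bisection fallback.

    Converges to ``|s(x) - s_target| < 1e-10 * S``; raises ``RuntimeError``
    if neither scheme reaches that tolerance.
    """
    S, L = path.S, path.L
    tol = 1e-10 * S
    x = L * s_target / S  # chord-proportional first guess
    lo, hi = 0.0, L
    for _ in range(100):
        f = path.arc_length_to(x) - s_target
        if abs(f) < tol:
            return float(x)
        if f > 0:
            hi = x
        else:
            lo = x
        deriv = math.sqrt(1.0 + path.slope(x) ** 2)
        x_new = x - f / deriv
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        x = x_new
    if abs(path.arc_length_to(x) - s_target) < 1e3 * tol:
        return float(x)
    raise RuntimeError("arc-length inversion did not converge")


def state_constant_tangential(path: ParabolicPath, t: float) -> TrajectoryState:
    """State under constant tangential speed ``S/D`` along the arc."""
    _check_t(t, path.D)
    t = min(max(t, 0.0), path.D)
    v = path.S / path.D
    if t == 0.0:
        x = 0.0
    elif t == path.D:
        x = path.L
    else:
        x = _invert_arc_length(path, v * t)
    yp = path.slope(x)
    norm = math.sqrt(1.0 + yp * yp)
    v_x = v / norm
    v_y = v * yp / norm
    return TrajectoryState(t, x, float(path.height(x)), v_x, v_y, v)


_STATE_FUNCS = {
    MotionLaw.GRAVITATIONAL: state_gravitational,
    MotionLaw.CONST_VERTICAL: state_constant_vertical,
    MotionLaw.CONST_TANGENTIAL: state_constant_tangential,
}


def state(path: ParabolicPath, law: MotionLaw, t: float) -> TrajectoryState:
    """Dispatch to the state function for ``law``."""
    return _STATE_FUNCS[law](path, t)


def frame_times(D: float, frame_rate: float) -> np.ndarray:
    """Sampling instants 0, 1/f, ... plus the arrival time ``D`` itself."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n = int(math.floor(D * frame_rate + 1e-9))
    t = np.arange(n + 1) / frame_rate
    if D - t[-1] > 1e-9:
        t = np.append(t, D)
    else:
        t[-1] = D
    return t


def sample_trajectory(
    path: ParabolicPath, law: MotionLaw, frame_rate: float
) -> list[TrajectoryState]:
    """Sample the trajectory at the display frame rate (final instant included).

    For the constant-vertical law a sample landing in the vertex window gets
    its horizontal velocity replaced by the symmetric one-frame central
    difference at the sampling rate (the analytic value diverges there).
    """
    times = frame_times(path.D, frame_rate)
    states = [state(path, law, float(t)) for t in times]
    if law is MotionLaw.CONST_VERTICAL:
        dt = 1.0 / frame_rate
        for i, st in enumerate(states):
            if st.capped:
                tm = max(st.t - dt, 0.0)
                tp = min(st.t + dt, path.D)
                xm = state_constant_vertical(path, tm).x
                xp = state_constant_vertical(path, tp).x
                v_x = (xp - xm) / (tp - tm)
                states[i] = replace(
                    st, v_x=v_x, v=math.hypot(v_x, st.v_y), capped=True
                )
    return states


def trajectory_frame(
    path: ParabolicPath,
    law: MotionLaw,
    frame_rate: float,
    condition_id: int | None = None,
) -> pd.DataFrame:
    """Sampled trajectory as a tidy table (t, x, y, v_x, v_y, v, law, condition_id)."""
    states = sample_trajectory(path, law, frame_rate)
    df = pd.DataFrame(
        {
            "t": [s.t for s in states],
            "x": [s.x for s in states],
            "y": [s.y for s in states],
            "v_x": [s.v_x for s in states],
            "v_y": [s.v_y for s in states],
            "v": [s.v for s in states],
        }
    )
    df["law"] = law.value
    df["condition_id"] = condition_id
    return df


def initial_velocities(cond: Condition, g: float = G_DEFAULT) -> dict[str, tuple[float, float]]:
    """Launch (v_x0, v_y0) per law for one condition, analytic values."""
    path = path_for_condition(cond, g)
    out = {}
    for law in MotionLaw:
        s0 = state(path, law, 0.0)
        out[law.value] = (s0.v_x, s0.v_y)
    return out
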