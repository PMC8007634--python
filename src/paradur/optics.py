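"""Observer-relative optic variables for the approaching ball.

The observer sits at eye height, ``final_offset`` metres beyond the arrival
point of every parabola, fixating a cross 13.8 m ahead and 3.2 m above the
eyes.  From a trajectory state we derive the eye-to-ball distance ``d``, the
ball's angular size θ = 2·atan(r/d) (dilation), the elevation angle γ of the
ball's sightline relative to the fixation line, the binocular disparity δ
(vergence difference between ball and cross), the radial velocity
``v_r = -dd/dt`` and the time derivatives of the angles.

θ, γ and δ depend only on the spatial point; their rates inherit the time
parameterization of the law of motion, which is what the discriminability
index below quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .kinematics import (
    MotionLaw,
    ParabolicPath,
    TrajectoryState,
    frame_times,
    state,
)


@dataclass(frozen=True)
class ObserverGeometry:
    """Static viewing geometry of the experiment.

    Distances in metres, angles in radians.  ``ipd`` (inter-pupillary
    distance) is not printed in the experimental report; 0.063 m is a standard
    adult value and is configurable.
    """

    final_offset: float = 0.5
    fix_dx: float = 13.8
    fix_dy: float = 3.2
    ipd: float = 0.063
    ball_radius: float = 0.045
    fov_half: float = 0.58

    @property
    def fixation_elevation(self) -> float:
        """Elevation of the fixation line above the horizontal eye line (rad)."""
        return math.atan2(self.fix_dy, self.fix_dx)

    @property
    def fixation_distance(self) -> float:
        return math.hypot(self.fix_dx, self.fix_dy)

    @property
    def ball_size(self) -> float:
        """Ball diameter (m), the size ``s`` entering the flight-time estimator."""
        return 2.0 * self.ball_radius


@dataclass(frozen=True)
class OpticState:
    """Optic variables at one instant (angles rad, rates rad/s, v_r m/s)."""

    t: float
    d: float
    theta: float
    gamma: float
    delta: float
    v_r: float
    theta_dot: float
    gamma_dot: float
    delta_dot: float
    capped: bool = False


class CrossingTimes(NamedTuple):
    """Times at which the ball crosses the fixation line (None if absent)."""

    ascending: float | None
    descending: float | None


class DILocation(Enum):
    START = "start"
    ASCENDING_CROSS = "ascending_cross"
    DESCENDING_CROSS = "descending_cross"


@dataclass(frozen=True)
class DIResult:
    """Relative elevation-rate difference between comparison and reference."""

    di: float
    gamma_dot_comp: float
    gamma_dot_ref: float
    condition_id: int | None = None
    law: MotionLaw | None = None
    location: DILocation | None = None


def optic_state(
    st: TrajectoryState, path: ParabolicPath, obs: ObserverGeometry
) -> OpticState:
    """Optic variables for one trajectory state, with analytic rates.

    Rates come from the state's velocities; for constant-vertical states
    inside the vertex window they inherit the ``capped`` flag.
    """
    u = obs.final_offset + path.L - st.x  # horizontal eye-to-ball distance
    y = st.y
    d = math.hypot(u, y)
    if d == 0.0:
        raise ValueError("ball at the eye: optic variables undefined")
    r = obs.ball_radius
    theta = 2.0 * math.atan(r / d)
    gamma = math.atan2(y, u) - obs.fixation_elevation
    d_fix = obs.fixation_distance
    delta = 2.0 * math.atan(obs.ipd / (2.0 * d)) - 2.0 * math.atan(
        obs.ipd / (2.0 * d_fix)
    )
    # d d_dot = u u_dot + y y_dot, with u_dot = -v_x
    d_dot = (-u * st.v_x + y * st.v_y) / d
    v_r = -d_dot
    gamma_dot = (st.v_y * u + y * st.v_x) / (u * u + y * y)
    theta_dot = -2.0 * r * d_dot / (d * d + r * r)
    delta_dot = -obs.ipd * d_dot / (d * d + obs.ipd**2 / 4.0)
    return OpticState(
        t=st.t,
        d=d,
        theta=theta,
        gamma=gamma,
        delta=delta,
        v_r=v_r,
        theta_dot=theta_dot,
        gamma_dot=gamma_dot,
        delta_dot=delta_dot,
        capped=st.capped,
    )


def optic_series(
    path: ParabolicPath,
    law: MotionLaw,
    obs: ObserverGeometry,
    frame_rate: float,
    rates: str = "fd",
) -> list[OpticState]:
    """Per-frame optic states.

    ``rates="fd"`` (default) differentiates the sampled angle series by
    central finite differences (one-sided at the endpoints), which is what a
    frame-based display actually shows; ``rates="analytic"`` propagates the
    law's instantaneous velocities instead.  Constant-vertical frames whose
    difference stencil straddles the mid-trajectory singularity keep a
    ``capped`` flag.
    """
    times = frame_times(path.D, frame_rate)
    states = [state(path, law, float(t)) for t in times]
    series = [optic_state(s, path, obs) for s in states]
    if rates == "analytic":
        return series
    if rates != "fd":
        raise ValueError(f"unknown rates mode {rates!r}")
    t = np.array([s.t for s in series])
    half = path.D / 2.0
    out: list[OpticState] = []
    arrays = {
        name: np.array([getattr(s, name) for s in series])
        for name in ("d", "theta", "gamma", "delta")
    }
    grads = {name: np.gradient(vals, t) for name, vals in arrays.items()}
    for i, s in enumerate(series):
        lo = t[max(i - 1, 0)]
        hi = t[min(i + 1, len(t) - 1)]
        straddles = law is MotionLaw.CONST_VERTICAL and lo < half < hi
        out.append(
            OpticState(
                t=s.t,
                d=s.d,
                theta=s.theta,
                gamma=s.gamma,
                delta=s.delta,
                v_r=-grads["d"][i],
                theta_dot=grads["theta"][i],
                gamma_dot=grads["gamma"][i],
                delta_dot=grads["delta"][i],
                capped=bool(s.capped or straddles),
            )
        )
    return out


def optic_frame(
    path: ParabolicPath,
    law: MotionLaw,
    obs: ObserverGeometry,
    frame_rate: float,
    condition_id: int | None = None,
    rates: str = "fd",
) -> pd.DataFrame:
    """Optic series as a tidy table."""
    series = optic_series(path, law, obs, frame_rate, rates=rates)
    cols = ("t", "d", "theta", "gamma", "delta", "theta_dot", "gamma_dot",
            "delta_dot", "v_r", "capped")
    df = pd.DataFrame({c: [getattr(s, c) for s in series] for c in cols})
    df["law"] = law.value
    df["condition_id"] = condition_id
    return df


def _gamma_of_t(path: ParabolicPath, law: MotionLaw, obs: ObserverGeometry, t: float) -> float:
    return optic_state(state(path, law, t), path, obs).gamma


def fixation_crossings(
    path: ParabolicPath, law: MotionLaw, obs: ObserverGeometry
) -> CrossingTimes:
    """Times at which γ(t) = 0 (ball on the fixation line).

    The ball starts and ends below the fixation line; if its peak elevation
    stays below the line there is no crossing and ``None`` is returned for
    both phases.  All three laws reach the vertex at ``D/2`` (their speed
    profiles are symmetric in time), which brackets the two roots.
    """
    half = path.D / 2.0
    g_mid = _gamma_of_t(path, law, obs, half)
    if g_mid <= 0.0:
        return CrossingTimes(None, None)

    def f(t: float) -> float:
        return _gamma_of_t(path, law, obs, t)

    t_a = brentq(f, 0.0, half, xtol=1e-12, rtol=1e-15)
    t_d = brentq(f, half, path.D, xtol=1e-12, rtol=1e-15)
    assert abs(f(t_a)) < 1e-9 and abs(f(t_d)) < 1e-9
    return CrossingTimes(float(t_a), float(t_d))


def max_elevation(path: ParabolicPath, obs: ObserverGeometry) -> float:
    """Maximum elevation γ of the ball relative to the fixation line (rad).

    γ depends only on the spatial point, so the maximization runs over
    horizontal progress x; the optimum sits past the vertex, where the ball is
    lower but much closer.
    """

    def neg_gamma(x: float) -> float:
        u = obs.final_offset + path.L - x
        return -(math.atan2(float(path.height(x)), u) - obs.fixation_elevation)

    res = minimize_scalar(
        neg_gamma, bounds=(0.0, path.L), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(-res.fun)


def discriminability_index(comp: OpticState, ref: OpticState) -> DIResult | None:
    """Relative elevation-rate difference DI = |γ̇_comp − γ̇_ref| / |γ̇_ref|.

    Rates are taken in magnitude so the sign convention of γ̇ cannot flip the
    index.  Returns ``None`` when the reference rate vanishes (index
    undefined).
    """
    gref = abs(ref.gamma_dot)
    if gref == 0.0:
        return None
    gcomp = abs(comp.gamma_dot)
    return DIResult(
        di=abs(gcomp - gref) / gref,
        gamma_dot_comp=gcomp,
        gamma_dot_ref=gref,
    )


def di_table(
    obs: ObserverGeometry | None = None,
    g: float | None = None,
    reference_id: int = 4,
    include_descending: bool = True,
) -> pd.DataFrame:
    """Discriminability index of every comparison condition vs the reference.

    For each experimental comparison condition (1-3, 5-7), law, and location
    (start of motion, ascending fixation-line crossing, optionally the
    descending crossing), computes DI against the same-law reference at the
    matched location.  Elevation rates are analytic.
    """
    from .kinematics import G_DEFAULT, condition_table, path_for_condition

    obs = obs or ObserverGeometry()
    g = G_DEFAULT if g is None else g
    conds = [c for c in condition_table() if not c.is_control]
    paths = {c.id: path_for_condition(c, g) for c in conds}

    def rates_at_locations(cond_id: int, law: MotionLaw) -> dict[DILocation, float]:
        path = paths[cond_id]
        out = {DILocation.START: optic_state(state(path, law, 0.0), path, obs).gamma_dot}
        cross = fixation_crossings(path, law, obs)
        for loc, t in (
            (DILocation.ASCENDING_CROSS, cross.ascending),
            (DILocation.DESCENDING_CROSS, cross.descending),
        ):
            if t is not None:
                out[loc] = optic_state(state(path, law, t), path, obs).gamma_dot
        return out

    rows = []
    for law in MotionLaw:
        ref_rates = rates_at_locations(reference_id, law)
        for cond in conds:
            if cond.id == reference_id:
                continue
            comp_rates = rates_at_locations(cond.id, law)
            for loc, g_ref in ref_rates.items():
                if loc is DILocation.DESCENDING_CROSS and not include_descending:
                    continue
                if loc not in comp_rates or g_ref == 0.0:
                    continue
                g_comp = comp_rates[loc]
                rows.append(
                    {
                        "condition_id": cond.id,
                        "law": law.value,
                        "location": loc.value,
                        "gamma_dot_comp": abs(g_comp),
                        "gamma_dot_ref": abs(g_ref),
                        "di": abs(abs(g_comp) - abs(g_ref)) / abs(g_ref),
                    }
                )
    return pd.DataFrame(rows)


def flight_time_gs(
    theta: float, gamma: float, gamma_dot: float, v_r: float, s: float
) -> float | None:
    """Flight-duration estimate from optic variables and ball size.

    ``T = s / (v_r·θ + tan(γ)·s·γ̇)`` — the combination of looming (v_r·θ)
    and elevation-rate information that specifies the flight duration of a
    parabolic approach when the physical ball size ``s`` is known.  Returns
    ``None`` when the denominator is not positive (estimate undefined).
    """
    denom = v_r * theta + math.tan(gamma) * s * gamma_dot
    if denom <= 0.0:
        return None
    return s / denom


def flight_time_from_state(
    st: TrajectoryState,
    path: ParabolicPath,
    obs: ObserverGeometry,
    gamma_origin: str = "horizontal",
) -> float | None:
    """Evaluate the optical flight-duration estimator at a trajectory state.

    ``gamma_origin`` selects whether γ is measured from the horizontal eye
    line (the source model's convention, default) or from the fixation line.
    """
    o = optic_state(st, path, obs)
    if gamma_origin == "horizontal":
        gamma = o.gamma + obs.fixation_elevation
    elif gamma_origin == "fixation":
        gamma = o.gamma
    else:
        raise ValueError(f"unknown gamma_origin {gamma_origin!r}")
    return flight_time_gs(o.theta, gamma, o.gamma_dot, o.v_r, obs.ball_size)
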