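"""Synthetic 2AFC observers for the duration-discrimination task.

The decision model is the exact generative dual of the logistic psychometric
analysis: the probability of judging the comparison longer is

    P = lapse/2 + (1 - lapse) * logistic(decision / sigma_law)

with ``decision = w_D (D_comp - PSE_law) + w_H kappa (H_comp - H_ref)`` and
``sigma_law = JND_law / log 3``, so a logit fit on duration recovers the
generative PSE and JND exactly in expectation.  The distance weight ``w_H``
lets an observer respond from the initial horizontal distance instead of (or
mixed with) duration; ``kappa`` normalizes distance to the duration scale so
the two strategies are indistinguishable on the experimental conditions and
separable only through the duration-matched control conditions #8/#9.

Response times exist only to exercise the protocol's filtering rules, not as
a psychological model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import TrialRecord, TrialSchedule, with_response
from .kinematics import MotionLaw, condition_table, get_condition

LOG3 = float(np.log(3.0))

H_REF = get_condition(4).L

_exp = [c for c in condition_table() if not c.is_control]
#: slope of duration on horizontal distance over conditions 1-7 (s/m); maps a
#: distance difference onto the duration scale so duration- and
#: distance-responders match on the experimental conditions
KAPPA = float(np.polyfit([c.L for c in _exp], [c.D for c in _exp], 1)[0])
del _exp

# study-condition cohort means (per law), from the duration analysis they are
# meant to emulate: mean JND/PSE per law of motion, with between-subject SDs
# back-derived from the reported 95% confidence intervals at n = 15
COHORT_JND_MEAN = {
    MotionLaw.CONST_TANGENTIAL: 0.076,
    MotionLaw.CONST_VERTICAL: 0.101,
    MotionLaw.GRAVITATIONAL: 0.091,
}
COHORT_JND_SD = {
    MotionLaw.CONST_TANGENTIAL: 0.030,
    MotionLaw.CONST_VERTICAL: 0.046,
    MotionLaw.GRAVITATIONAL: 0.036,
}
COHORT_PSE_MEAN = {
    MotionLaw.CONST_TANGENTIAL: 1.006,
    MotionLaw.CONST_VERTICAL: 1.014,
    MotionLaw.GRAVITATIONAL: 1.021,
}
COHORT_PSE_SD = {
    MotionLaw.CONST_TANGENTIAL: 0.027,
    MotionLaw.CONST_VERTICAL: 0.033,
    MotionLaw.GRAVITATIONAL: 0.020,
}

JND_FLOOR = 0.02  # s; truncation keeping every drawn observer discriminating


@dataclass(frozen=True)
class ObserverProfile:
    """Generative parameters of one synthetic observer.

    ``u0``/``u1`` store the standardized subject-level draws behind the
    per-law PSE and JND shifts (the analogue of the mixed model's random
    intercept and slope).
    """

    subject_id: str
    pse: dict[MotionLaw, float]
    jnd: dict[MotionLaw, float]
    lapse: float = 0.0
    w_d: float = 1.0
    w_h: float = 0.0
    u0: float = 0.0
    u1: float = 0.0
    rt_log_loc: float = 0.18  # lognormal location: median rt ~ 1.2 s
    rt_log_scale: float = 0.40
    bad_rt_rate: float = 0.0  # fraction of trials with rt outside [0, 10] s
    inattention_rate: float = 0.0

    def sigma(self, law: MotionLaw) -> float:
        """Decision scale: sigma = JND / log 3 under the logit link."""
        return self.jnd[law] / LOG3


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative settings (defaults = the study conditions)."""

    n_subjects: int = 15
    jnd_mean: dict[MotionLaw, float] = field(
        default_factory=lambda: dict(COHORT_JND_MEAN))
    jnd_sd: dict[MotionLaw, float] = field(
        default_factory=lambda: dict(COHORT_JND_SD))
    pse_mean: dict[MotionLaw, float] = field(
        default_factory=lambda: dict(COHORT_PSE_MEAN))
    pse_sd: dict[MotionLaw, float] = field(
        default_factory=lambda: dict(COHORT_PSE_SD))
    rho: float = 0.0  # correlation between the PSE and JND subject draws
    lapse: float = 0.0
    w_d: float = 1.0
    w_h: float = 0.0
    distance_responder_fraction: float = 0.0
    bad_rt_rate: float = 0.03
    inattention_rate: float = 0.005
    seed: int = 0


def response_probability(
    profile: ObserverProfile, law: MotionLaw, D_comp: float, H_comp: float
) -> float:
    """P(judge the comparison longer) for one stimulus pair."""
    decision = profile.w_d * (D_comp - profile.pse[law]) + profile.w_h * KAPPA * (
        H_comp - H_REF
    )
    p_core = expit(decision / profile.sigma(law))
    return profile.lapse / 2.0 + (1.0 - profile.lapse) * p_core


def simulate_subject(
    profile: ObserverProfile, schedule: TrialSchedule, seed: int
) -> list[TrialRecord]:
    """Simulate one subject's responses over a schedule (seeded)."""
    rng = np.random.default_rng(seed)
    out: list[TrialRecord] = []
    for tr in schedule.trials:
        p = response_probability(profile, tr.law, tr.D_comp, tr.H_comp)
        comparison_longer = bool(rng.random() < p)
        if rng.random() < profile.bad_rt_rate:
            # contaminated timing: pre-emptive or over-deadline response
            rt = float(rng.uniform(-0.2, -0.001)) if rng.random() < 0.5 else float(
                rng.uniform(10.05, 12.0)
            )
        else:
            rt = float(rng.lognormal(profile.rt_log_loc, profile.rt_log_scale))
        attention = bool(rng.random() < profile.inattention_rate)
        out.append(with_response(tr, comparison_longer, rt, attention))
    return out


def make_cohort(spec: CohortSpec) -> list[ObserverProfile]:
    """Draw ``n_subjects`` observer profiles (deterministic under the seed).

    Each subject gets a standardized bivariate-normal pair (u0, u1) with
    correlation ``rho``; u0 shifts the per-law PSE by the per-law SD, u1
    shifts the per-law JND likewise (truncated at a small positive floor).
    With all SDs zero the cohort is ``n_subjects`` copies of the means.
    """
    for law in MotionLaw:
        if spec.jnd_sd[law] < 0 or spec.pse_sd[law] < 0:
            raise ValueError("between-subject SDs must be >= 0")
    rng = np.random.default_rng(spec.seed)
    cov = [[1.0, spec.rho], [spec.rho, 1.0]]
    draws = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n_subjects)
    n_distance = int(round(spec.distance_responder_fraction * spec.n_subjects))
    profiles = []
    for i in range(spec.n_subjects):
        u0, u1 = draws[i]
        pse = {law: spec.pse_mean[law] + spec.pse_sd[law] * u0 for law in MotionLaw}
        jnd = {
            law: max(spec.jnd_mean[law] + spec.jnd_sd[law] * u1, JND_FLOOR)
            for law in MotionLaw
        }
        if i < n_distance:
            w_d, w_h = 0.0, 1.0
        else:
            w_d, w_h = spec.w_d, spec.w_h
        profiles.append(
            ObserverProfile(
                subject_id=f"s{i + 1:02d}",
                pse=pse,
                jnd=jnd,
                lapse=spec.lapse,
                w_d=w_d,
                w_h=w_h,
                u0=float(u0),
                u1=float(u1),
                bad_rt_rate=spec.bad_rt_rate,
                inattention_rate=spec.inattention_rate,
            )
        )
    return profiles


def simulate_cohort(
    spec: CohortSpec,
    replications: int = 15,
    schedule_seed: int = 100,
    response_seed: int = 200,
) -> pd.DataFrame:
    """Simulate a whole cohort; returns one tidy trial table for all subjects.

    Every subject receives their own pseudo-random trial order
    (``schedule_seed + i``) and response stream (``response_seed + i``).
    """
    from .design import build_schedule, records_to_frame

    frames = []
    for i, profile in enumerate(make_cohort(spec)):
        sched = build_schedule(
            replications=replications,
            seed=schedule_seed + i,
            subject_id=profile.subject_id,
        )
        frames.append(records_to_frame(simulate_subject(profile, sched, response_seed + i)))
    return pd.concat(frames, ignore_index=True)
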