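"""Trial schedule and response filtering for the 2AFC duration task.

Each trial presents a reference stimulus (the 1-s condition-4 path) and a
comparison stimulus in random order, both moving under the same law of motion;
the observer reports which interval lasted longer.  The full design crosses
3 laws x 9 conditions x 15 replications = 405 trials in a seeded pseudo-random
order.  Responses with impossible or over-long reaction times, or flagged for
inattention, are excluded before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import MotionLaw, condition_table

RT_MAX_DEFAULT = 10.0  # s; maximum response time allowed by the protocol
ISI = 0.5  # s; inter-stimulus interval, recorded as metadata only


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial: comparison condition, order, response and timing.

    ``response`` is 1 or 2 (the interval judged longer) and ``None`` before
    simulation; ``comparison_longer`` is derived from ``response`` and
    ``ref_first``.  Missing responses are represented as attention-flagged
    rows.
    """

    subject_id: str
    trial_index: int
    condition_id: int
    law: MotionLaw
    ref_first: bool
    D_comp: float
    H_comp: float
    response: int | None = None
    comparison_longer: bool | None = None
    rt: float | None = None
    attention_flag: bool = False


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered list of response-less trial stubs plus the seed that made it."""

    trials: tuple[TrialRecord, ...]
    seed: int
    replications: int

    def __len__(self) -> int:
        return len(self.trials)


def build_schedule(
    replications: int = 15,
    seed: int = 0,
    subject_id: str = "s01",
) -> TrialSchedule:
    """Full factorial (3 laws x 9 conditions) x replications, seeded shuffle.

    Presentation order of reference vs comparison is drawn uniformly per
    trial.  The same seed always yields the same schedule.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    rng = np.random.default_rng(seed)
    cells = [
        (cond, law)
        for cond in condition_table()
        for law in MotionLaw
        for _ in range(replications)
    ]
    order = rng.permutation(len(cells))
    ref_first = rng.random(len(cells)) < 0.5
    trials = tuple(
        TrialRecord(
            subject_id=subject_id,
            trial_index=i,
            condition_id=cells[j][0].id,
            law=cells[j][1],
            ref_first=bool(ref_first[i]),
            D_comp=cells[j][0].D,
            H_comp=cells[j][0].L,
        )
        for i, j in enumerate(order)
    )
    return TrialSchedule(trials=trials, seed=seed, replications=replications)


def filter_responses(
    trials: list[TrialRecord] | tuple[TrialRecord, ...],
    rt_max: float = RT_MAX_DEFAULT,
) -> tuple[list[TrialRecord], list[TrialRecord], float]:
    """Apply the exclusion rules; returns (kept, excluded, fraction excluded).

    A trial is excluded when its response time is negative (the response
    pre-empted the second stimulus), exceeds ``rt_max``, or the trial is
    attention-flagged (including missing responses).
    """
    kept: list[TrialRecord] = []
    excluded: list[TrialRecord] = []
    for tr in trials:
        bad = (
            tr.attention_flag
            or tr.rt is None
            or tr.rt < 0.0
            or tr.rt > rt_max
        )
        (excluded if bad else kept).append(tr)
    frac = len(excluded) / len(trials) if trials else 0.0
    return kept, excluded, frac


_COLUMNS = [
    "subject_id", "trial_index", "condition_id", "law", "ref_first",
    "D_comp", "H_comp", "response", "comparison_longer", "rt",
    "attention_flag",
]


def records_to_frame(trials) -> pd.DataFrame:
    """Trial records as a tidy table (one row per trial)."""
    rows = []
    for tr in trials:
        d = {c: getattr(tr, c) for c in _COLUMNS}
        d["law"] = tr.law.value
        rows.append(d)
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                trial_index=int(row.trial_index),
                condition_id=int(row.condition_id),
                law=MotionLaw(row.law),
                ref_first=bool(row.ref_first),
                D_comp=float(row.D_comp),
                H_comp=float(row.H_comp),
                response=None if pd.isna(row.response) else int(row.response),
                comparison_longer=(
                    None if pd.isna(row.comparison_longer)
                    else bool(row.comparison_longer)
                ),
                rt=None if pd.isna(row.rt) else float(row.rt),
                attention_flag=bool(row.attention_flag),
            )
        )
    return recs


def with_response(
    trial: TrialRecord, comparison_longer: bool, rt: float | None,
    attention_flag: bool = False,
) -> TrialRecord:
    """Fill in a response, mapping the judgement back through interval order."""
    comp_interval = 2 if trial.ref_first else 1
    ref_interval = 1 if trial.ref_first else 2
    response = comp_interval if comparison_longer else ref_interval
    return replace(
        trial,
        response=response,
        comparison_longer=comparison_longer,
        rt=rt,
        attention_flag=attention_flag,
    )
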