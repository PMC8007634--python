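import numpy as np
import pytest

from paradur.kinematics import condition_table, path_for_condition
from paradur.observer import CohortSpec, simulate_cohort
from paradur.optics import ObserverGeometry


@pytest.fixture(scope="session")
def obs():
    return ObserverGeometry()


@pytest.fixture(scope="session")
def paths():
    """Condition id -> ParabolicPath for all nine conditions, g = 9.8."""
    return {c.id: path_for_condition(c) for c in condition_table()}


@pytest.fixture(scope="session")
def small_cohort_trials():
    """A small duration-only cohort (8 subjects, 8 replications), filtered.

    Clean timing (no contaminated RTs) so every simulated trial is analyzable.
    """
    spec = CohortSpec(n_subjects=8, bad_rt_rate=0.0, inattention_rate=0.0, seed=7)
    return simulate_cohort(spec, replications=8, schedule_seed=70, response_seed=71)


@pytest.fixture(scope="session")
def study_cohort_trials():
    """One cohort at the full design size (15 subjects x 405 trials)."""
    spec = CohortSpec(seed=3)
    return simulate_cohort(spec, replications=15, schedule_seed=30, response_seed=31)
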