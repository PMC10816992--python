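import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from abratio.cohort import Group, Participant, Sex

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Published cross-tabulations of plasmatic calls against CSF/PET amyloid
# status: (tp, fn, fp, tn) per (threshold population).
TABLE_GMM_ALL = (65, 9, 34, 43)
TABLE_GMM_NONDEM = (44, 9, 31, 42)
TABLE_TREE_ALL = (64, 10, 32, 45)
TABLE_TREE_NONDEM = (43, 10, 29, 44)

PREV_60 = 0.158
PREV_80 = 0.326


def labeled_from_counts(tp, fn, fp, tn, threshold):
    """Reconstruct (values, truth) realising a confusion table at a cutoff.

    Called-positive participants get a ratio just below the cutoff,
    called-negative ones just above; truth follows the table margins.
    """
    lo, hi = threshold - 0.002, threshold + 0.002
    values = [lo] * tp + [hi] * fn + [lo] * fp + [hi] * tn
    truth = [True] * tp + [True] * fn + [False] * fp + [False] * tn
    return np.array(values), truth


def make_participant(pid="P001", group=Group.VOLUNTEER, age=70.0, sex=Sex.FEMALE,
                     blood_date=dt.date(2021, 6, 1), **kw):
    return Participant(id=pid, group=group, age=age, sex=sex, blood_date=blood_date, **kw)


@pytest.fixture
def participant_factory():
    return make_participant


@pytest.fixture
def rng():
    return np.random.default_rng(20240118)
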