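import math
from collections import Counter

import pytest

import engagekit as ek


def pe_oracle(seq, order, delay=1):
    """Brute-force normalized permutation entropy by explicit pattern counting.

    Independent of the library implementation: every window is reduced to
    its ordinal pattern by sorting (value, position) pairs, patterns are
    counted in a dict, and the Shannon entropy is accumulated term by term.
    """
    n = len(seq)
    n_windows = n - (order - 1) * delay
    assert n_windows >= 1
    patterns = Counter(
        tuple(sorted(range(order), key=lambda k: (seq[i + k * delay], k)))
        for i in range(n_windows)
    )
    h = 0.0
    for count in patterns.values():
        p = count / n_windows
        h -= p * math.log(p)
    return h / math.log(math.factorial(order))


@pytest.fixture(scope="session")
def study_cohort():
    """The standard 233-patient synthetic cohort and its ground truth."""
    return ek.emulate_study_shape(7)


@pytest.fixture(scope="session")
def fitted_study(study_cohort):
    """The full comparison study fitted on the standard cohort."""
    log, _ = study_cohort
    return ek.EngagementStudy(log).fit()


def make_activity(visit_weeks, menus_per_week, total_weeks, visit_days=None):
    """Hand-build a WindowedActivity for index unit tests."""
    visit_weeks = tuple(sorted(visit_weeks))
    if visit_days is None:
        visit_days = tuple(7 * (w - 1) for w in visit_weeks)
    counts = [0] * total_weeks
    for d in visit_days:
        counts[d // 7] += 1
    return ek.WindowedActivity(
        "p", tuple(sorted(visit_days)), visit_weeks, dict(menus_per_week),
        total_weeks, tuple(counts),
    )
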