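"""The existing engagement index: click depth, loyalty, recency, and their mean.

These three indices are the web-analytics Visitor Index components that can
be computed from app access logs alone, adapted to a session = one calendar
day and a weekly resolution:

* click depth  — weeks with ≥2 distinct menus accessed / total window weeks
* loyalty      — weeks with any access / total window weeks
* recency      — 1 / mean(inter-visit gap in weeks); regular weekly users
                 score 1, sparse returners score low
* EI           — the arithmetic mean of the three.

All components live in [0, 1].  A patient with fewer than two visit weeks
has no gaps; recency is defined as 0 for them (a one-shot or never user
shows no return behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidWindowError
from .log import StudyWindow, UsageLog, WindowedActivity, intervisit_gaps, window_activity


@dataclass(frozen=True)
class ExistingIndexVector:
    """Per-patient component indices and their mean for one window."""

    patient_id: str
    click_depth: float
    loyalty: float
    recency: float
    ei: float
    window_label: str


def _require_weeks(activity: WindowedActivity) -> int:
    if activity.total_weeks <= 0:
        raise InvalidWindowError("window contains zero weeks")
    return activity.total_weeks


def click_depth_index(activity: WindowedActivity) -> float:
    """Fraction of window weeks in which ≥2 distinct menus were accessed."""
    total = _require_weeks(activity)
    deep = sum(1 for n in activity.menus_per_week.values() if n >= 2)
    return deep / total


def loyalty_index(activity: WindowedActivity) -> float:
    """Fraction of window weeks with any access."""
    total = _require_weeks(activity)
    return activity.n_visit_weeks / total


def recency_index(activity: WindowedActivity) -> float:
    """Reciprocal of the mean week gap between visits; 0 with <2 visit weeks."""
    _require_weeks(activity)
    gaps = intervisit_gaps(activity)
    if not gaps:
        return 0.0
    return 1.0 / float(np.mean(gaps))


def existing_ei(activity: WindowedActivity, window_label: str = "") -> ExistingIndexVector:
    cd = click_depth_index(activity)
    lo = loyalty_index(activity)
    re = recency_index(activity)
    return ExistingIndexVector(
        patient_id=activity.patient_id,
        click_depth=cd,
        loyalty=lo,
        recency=re,
        ei=(cd + lo + re) / 3.0,
        window_label=window_label,
    )


def existing_ei_cohort(
    log: UsageLog,
    window: StudyWindow,
    menus=None,
) -> pd.DataFrame:
    """Existing EI components for every patient in the log.

    Returns a DataFrame indexed by ``patient_id`` with columns
    ``click_depth, loyalty, recency, ei, window_label``.
    """
    activities = window_activity(log, window, menus=menus)
    rows = [existing_ei(act, window.label) for act in activities.values()]
    frame = pd.DataFrame([vars(r) for r in rows]).set_index("patient_id")
    return frame.sort_index()
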