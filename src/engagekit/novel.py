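"""The newly developed engagement index (MI, enriched LI, permutation-entropy RI).

Three refinements of the classic click-depth / loyalty / recency triad:

**Menu abundancy (MI).**  For each menu in a chosen combination, compute its
*survival time*: days from the first in-window use until the menu is
discontinued, where discontinuation means the start of ≥45 consecutive
days of nonusage of that menu (the 45-day threshold mirrors the cohort's
75th-percentile inter-usage gap).  Each patient then owns a vector of
per-menu survival days; MI is the Euclidean distance of that vector from
the least-engaged patient's vector (minimum Euclidean norm), normalized by
the distance between the most- and least-engaged patients' vectors, and
clipped to [0, 1].

**Enriched loyalty (LI).**  (accessed weeks + ln(final usage week)) /
total window weeks, then rescaled by the cohort maximum so the cohort's
most loyal patient scores exactly 1.

**Permutation-entropy recency (RI).**  Normalized permutation entropy of
the patient's weekly visit-count series measures irregularity of usage;
RI = 1 − PE so that, like the classic recency index, higher means more
regular.  An optional truncated-normal calibration maps cohort PE values
through the CDF of a normal fitted to them and truncated to [0, 1].

The new EI is the arithmetic mean of the three components.  Menu
combinations EI1 (self-logging menus), EI2 (free-version menus) and EI3
(all menus) select which menus enter MI and which events count as visits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .log import MENUS, StudyWindow, UsageLog, WindowedActivity, window_activity


@dataclass(frozen=True)
class MenuCombination:
    """A labelled subset of the menu enumeration defining one EI variant."""

    label: str
    menus: tuple[str, ...]

    def __post_init__(self):
        if not self.menus:
            raise ValidationError("a menu combination must contain at least one menu")


#: The three studied combinations: EI1 = self-logging menus for active users,
#: EI2 = menus available in the app's free version, EI3 = all six menus.
COMBINATIONS: dict[str, MenuCombination] = {
    "EI1": MenuCombination(
        "EI1", ("meal_log", "exercise_log", "message_sent", "reading_content", "weight_log")
    ),
    "EI2": MenuCombination(
        "EI2", ("meal_log", "exercise_log", "weight_log", "step_count")
    ),
    "EI3": MenuCombination("EI3", MENUS),
}


@dataclass(frozen=True)
class MenuSurvival:
    """Per-menu survival times (days) for one patient, one combination."""

    patient_id: str
    survival_days: tuple[float, ...]

    @property
    def euclidean_norm(self) -> float:
        return float(np.linalg.norm(self.survival_days))


@dataclass(frozen=True)
class NewIndexVector:
    patient_id: str
    mi: float
    li: float
    ri: float
    ei: float
    combination_label: str
    window_label: str


# ---------------------------------------------------------------------------
# Menu survival and the menu abundancy index
# ---------------------------------------------------------------------------

def menu_survival(
    days: Sequence[int],
    window: StudyWindow,
    gap_threshold_days: int = 45,
) -> float:
    """Survival time in days of one menu for one patient.

    ``days`` are the (sorted) in-window days on which the menu was used.
    Scanning forward from the first use, the menu is discontinued at the
    last use preceding the first gap of ``gap_threshold_days`` or more
    (gaps between successive uses, and from the last use to the window
    end, both count as nonusage periods).  Survival is measured as
    (last qualifying use − first use); a never-used menu survives 0 days.
    """
    in_window = sorted(d for d in days if window.contains(d))
    if not in_window:
        return 0.0
    first = in_window[0]
    end = first
    for cur, nxt in zip(in_window[:-1], in_window[1:]):
        if nxt - cur >= gap_threshold_days:
            return float(end - first)
        end = nxt
    return float(end - first)


def menu_survival_cohort(
    log: UsageLog,
    window: StudyWindow,
    combination: MenuCombination,
    gap_threshold_days: int = 45,
) -> pd.DataFrame:
    """Per-patient, per-menu survival days as a patients × menus DataFrame."""
    frame = log.to_frame()
    frame = frame[
        frame["menu"].isin(combination.menus)
        & (frame["day"] >= window.start_day)
        & (frame["day"] < window.end_day)
    ]
    grouped = {
        key: sub["day"].to_numpy()
        for key, sub in frame.groupby(["patient_id", "menu"], sort=False)
    }
    data = {
        menu: [
            menu_survival(grouped.get((pid, menu), ()), window, gap_threshold_days)
            for pid in log.patients
        ]
        for menu in combination.menus
    }
    return pd.DataFrame(data, index=pd.Index(log.patients, name="patient_id"))


def menu_abundancy(survivals: pd.DataFrame) -> pd.Series:
    """Cohort-normalized MI from a patients × menus survival table.

    The reference patients are those with the minimum and maximum Euclidean
    norm (distance from the origin) of their survival vector, ties broken
    by patient id order.  ``mi(p) = ‖v_p − v_min‖ / ‖v_max − v_min‖``,
    clipped to [0, 1].  If every patient is identical the index is
    undefined; all MI are set to 0 with a warning.
    """
    if len(survivals) < 2:
        raise ValidationError("menu abundancy needs at least 2 patients")
    vectors = survivals.to_numpy(dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    order = survivals.index.to_numpy()
    # stable argsort on (norm, patient_id): first row = min, last = max
    rank = np.lexsort((order, norms))
    v_min = vectors[rank[0]]
    v_max = vectors[rank[-1]]
    denom = float(np.linalg.norm(v_max - v_min))
    if denom == 0.0:
        warnings.warn(
            "all survival vectors identical; menu abundancy undefined, set to 0",
            stacklevel=2,
        )
        return pd.Series(0.0, index=survivals.index, name="mi")
    dist = np.linalg.norm(vectors - v_min, axis=1)
    mi = dist / denom
    n_clipped = int(np.sum(mi > 1.0))
    if n_clipped:
        warnings.warn(
            f"menu abundancy clipped to 1 for {n_clipped} patient(s)", stacklevel=2
        )
    return pd.Series(np.clip(mi, 0.0, 1.0), index=survivals.index, name="mi")


# ---------------------------------------------------------------------------
# Enriched loyalty
# ---------------------------------------------------------------------------

def new_loyalty(activities: Mapping[str, WindowedActivity]) -> pd.Series:
    """Log-enriched, cohort-rescaled loyalty index.

    raw(p) = (accessed weeks + ln(final usage week)) / total weeks, with the
    log term 0 when the final usage week is ≤ 1; the cohort maximum raw
    value is rescaled to exactly 1.  An all-zero cohort maps to all-zero LI.
    """
    raw = {}
    for pid, act in activities.items():
        if act.total_weeks <= 0:
            raise ValidationError("loyalty needs a window with ≥1 week")
        log_term = math.log(act.final_usage_week) if act.final_usage_week > 1 else 0.0
        raw[pid] = (act.n_visit_weeks + log_term) / act.total_weeks
    series = pd.Series(raw, name="li")
    series.index.name = "patient_id"
    top = series.max()
    if top <= 0:
        return series * 0.0
    return series / top


# ---------------------------------------------------------------------------
# Permutation entropy and the new recency index
# ---------------------------------------------------------------------------

def permutation_entropy(series: Sequence[float], order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy of a numeric sequence, in [0, 1].

    Every length-``order`` subsequence at lag ``delay`` is reduced to its
    ordinal pattern (the permutation that sorts it; equal values are ranked
    by position, earlier index = smaller rank).  The Shannon entropy of the
    pattern distribution, in nats, is divided by ``ln(order!)``.  0 means a
    single pattern dominates (perfectly regular series); 1 means all
    patterns are equally likely (maximally irregular).
    """
    if order < 2:
        raise ValidationError("permutation entropy needs order ≥ 2")
    if delay < 1:
        raise ValidationError("delay must be ≥ 1")
    x = np.asarray(series, dtype=float)
    n = x.size
    n_windows = n - (order - 1) * delay
    if n_windows < 1:
        raise InsufficientDataError(
            f"series of length {n} too short for order={order}, delay={delay}"
        )
    idx = np.arange(n_windows)[:, None] + np.arange(order)[None, :] * delay
    # stable argsort ranks ties by position
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))
    counts = np.unique(codes, return_counts=True)[1]
    p = counts / n_windows
    entropy = max(float(-(p * np.log(p)).sum()), 0.0)
    return entropy / math.log(math.factorial(order))


def new_recency(
    activities: Mapping[str, WindowedActivity],
    order: int = 3,
    delay: int = 1,
    calibration: str = "none",
) -> pd.Series:
    """Permutation-entropy recency index for a cohort.

    RI = 1 − PE of each patient's weekly visit-count series; a perfectly
    regular user (constant weekly counts) scores 1, an erratic user scores
    near 0.  Patients whose series is too short for the ordinal analysis
    get RI = 0.  With ``calibration="truncated_normal_cdf"`` the cohort's
    PE values are first mapped through the CDF of a normal distribution
    fitted to them and truncated to [0, 1]; ``"none"`` uses the already
    normalized PE directly.
    """
    if calibration not in ("none", "truncated_normal_cdf"):
        raise ValidationError(f"unknown calibration {calibration!r}")
    pe_vals: dict[str, float] = {}
    short: set[str] = set()
    for pid, act in activities.items():
        try:
            pe_vals[pid] = permutation_entropy(act.weekly_visit_counts, order, delay)
        except InsufficientDataError:
            short.add(pid)
            pe_vals[pid] = np.nan
    series = pd.Series(pe_vals, name="pe")
    series.index.name = "patient_id"

    if calibration == "truncated_normal_cdf":
        valid = series.dropna()
        mu = float(valid.mean()) if len(valid) else 0.0
        sd = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
        if sd > 1e-12:
            a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
            series = pd.Series(
                stats.truncnorm.cdf(series.to_numpy(), a, b, loc=mu, scale=sd),
                index=series.index,
            )
        # degenerate cohort (all PE equal): keep raw PE values

    ri = 1.0 - series
    ri[list(short)] = 0.0
    ri.name = "ri"
    return ri


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def new_ei_cohort(
    log: UsageLog,
    window: StudyWindow,
    combination: MenuCombination | str = "EI3",
    gap_threshold_days: int = 45,
    order: int = 3,
    delay: int = 1,
    calibration: str = "none",
) -> pd.DataFrame:
    """The new EI and its components for every patient in the log.

    Returns a DataFrame indexed by ``patient_id`` with columns
    ``mi, li, ri, ei, combination_label, window_label``.  MI and the LI
    rescale are cohort-relative and computed per window per combination.

    A patient with no in-window events on the combination's menus receives
    MI by the formula (their survival vector is all-zero), LI = 0 and
    RI = 0 — the zero-activity guard, so that an absent user's constant
    all-zero visit series cannot score as maximally regular.
    """
    if isinstance(combination, str):
        try:
            combination = COMBINATIONS[combination]
        except KeyError:
            raise ValidationError(
                f"unknown combination {combination!r}; known: {sorted(COMBINATIONS)}"
            ) from None

    activities = window_activity(log, window, menus=combination.menus)
    survivals = menu_survival_cohort(log, window, combination, gap_threshold_days)
    mi = menu_abundancy(survivals)
    li = new_loyalty(activities)
    ri = new_recency(activities, order=order, delay=delay, calibration=calibration)

    inactive = [pid for pid, act in activities.items() if not act.visit_days]
    li[inactive] = 0.0
    ri[inactive] = 0.0

    frame = pd.concat([mi, li, ri], axis=1)
    missing = frame.isna().any(axis=1)
    if missing.any():
        bad = frame[missing].isna().stack()
        pid, comp = bad.index[0]
        raise ValidationError(f"component {comp!r} missing for patient {pid!r}")
    frame["ei"] = frame[["mi", "li", "ri"]].mean(axis=1)
    frame["combination_label"] = combination.label
    frame["window_label"] = window.label
    return frame.sort_index()


def nonusage_gap_percentile(log: UsageLog, q: float = 75.0) -> float:
    """Auditing helper: the cohort's q-th percentile inter-usage gap in days.

    Gaps are day differences between a patient's successive sessions
    (all menus pooled).  The default q = 75 mirrors the provenance of the
    45-day discontinuation threshold; the threshold itself is a config
    value and is never recomputed automatically.
    """
    gaps: list[int] = []
    frame = log.to_frame()
    for _, sub in frame.groupby("patient_id", sort=False):
        days = np.unique(sub["day"].to_numpy())
        if days.size >= 2:
            gaps.extend(np.diff(days).tolist())
    if not gaps:
        raise ValidationError("no inter-usage gaps in the log")
    return float(np.percentile(gaps, q))
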