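"""Usage-event logs: data model, I/O, windowing and weekly binning.

The raw material for every engagement index is an app usage log: one record
per (patient, menu, day), where ``day`` counts days since the patient's own
enrollment (day 0).  A *session* is one calendar day with at least one
event; all indices operate on weekly summaries of these sessions within a
fixed study window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: The closed menu enumeration of the health-management app under study.
MENUS: tuple[str, ...] = (
    "meal_log",
    "exercise_log",
    "message_sent",
    "reading_content",
    "weight_log",
    "step_count",
)


@dataclass(frozen=True, order=True)
class UsageEvent:
    """A single app interaction: a patient touched one menu on one day.

    ``day`` is the offset in days from the patient's baseline (enrollment);
    multiple events by the same patient on the same day are legal and
    collapse into a single session at analysis time.
    """

    patient_id: str
    menu: str
    day: int

    def validate(self, menus: Sequence[str] = MENUS) -> None:
        if self.day < 0:
            raise ValidationError(
                f"event for patient {self.patient_id!r} has negative day {self.day}"
            )
        if self.menu not in menus:
            raise ValidationError(
                f"unknown menu {self.menu!r} for patient {self.patient_id!r}; "
                f"allowed: {', '.join(menus)}"
            )


class UsageLog:
    """A validated collection of usage events over a fixed study period.

    Internally a sorted :class:`pandas.DataFrame` with columns
    ``patient_id, menu, day``.  Construction validates every event against
    the menu enumeration and the study length; per-patient event streams are
    retrievable sorted by day.

    Parameters
    ----------
    events
        Iterable of :class:`UsageEvent` or a DataFrame with the three
        canonical columns.
    study_length_days
        Total observation span; every event must satisfy
        ``0 <= day < study_length_days``.
    menus
        The menu enumeration; closed by default, extensible via config.
    patient_ids
        Optional roster of patients known to the study.  Patients with zero
        events (never-users) can only be represented this way.
    """

    def __init__(
        self,
        events: Iterable[UsageEvent] | pd.DataFrame,
        study_length_days: int,
        menus: Sequence[str] = MENUS,
        patient_ids: Sequence[str] | None = None,
    ):
        if study_length_days <= 0:
            raise ValidationError("study_length_days must be positive")
        if isinstance(events, pd.DataFrame):
            frame = events.loc[:, ["patient_id", "menu", "day"]].copy()
        else:
            frame = pd.DataFrame(
                [(e.patient_id, e.menu, e.day) for e in events],
                columns=["patient_id", "menu", "day"],
            )
        frame["patient_id"] = frame["patient_id"].astype(str)
        frame["menu"] = frame["menu"].astype(str)
        frame["day"] = frame["day"].astype(np.int64)

        bad_menu = ~frame["menu"].isin(menus)
        if bad_menu.any():
            unknown = sorted(frame.loc[bad_menu, "menu"].unique())
            raise ValidationError(
                f"unknown menu label(s) {unknown}; allowed: {', '.join(menus)}"
            )
        if (frame["day"] < 0).any():
            raise ValidationError("events with negative day offsets are invalid")
        if (frame["day"] >= study_length_days).any():
            raise ValidationError(
                f"events beyond study_length_days={study_length_days} are invalid"
            )

        frame = frame.sort_values(["patient_id", "day", "menu"], kind="stable")
        self._frame = frame.reset_index(drop=True)
        self.study_length_days = int(study_length_days)
        self.menus = tuple(menus)
        roster = set(self._frame["patient_id"].unique())
        if patient_ids is not None:
            roster |= {str(p) for p in patient_ids}
        self._patients = tuple(sorted(roster))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self):
        for row in self._frame.itertuples(index=False):
            yield UsageEvent(row.patient_id, row.menu, int(row.day))

    def __eq__(self, other) -> bool:
        if not isinstance(other, UsageLog):
            return NotImplemented
        return (
            self.study_length_days == other.study_length_days
            and self._patients == other._patients
            and self._frame.equals(other._frame)
        )

    @property
    def patients(self) -> tuple[str, ...]:
        """All patient ids, including event-free patients on the roster."""
        return self._patients

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def events_for(self, patient_id: str, menu: str | None = None) -> np.ndarray:
        """Sorted event days for one patient, optionally for one menu."""
        mask = self._frame["patient_id"] == patient_id
        if menu is not None:
            mask &= self._frame["menu"] == menu
        return self._frame.loc[mask, "day"].to_numpy()

    # -- I/O ----------------------------------------------------------------
    def write(self, path: str | Path, format: str = "csv") -> None:
        path = Path(path)
        if format == "csv":
            self._frame.to_csv(path, index=False)
        elif format == "jsonl":
            with path.open("w") as fh:
                for row in self._frame.itertuples(index=False):
                    fh.write(
                        json.dumps(
                            {"patient_id": row.patient_id, "menu": row.menu, "day": int(row.day)}
                        )
                        + "\n"
                    )
        else:
            raise ValueError(f"unknown format {format!r}")


def read_usage_log(
    path: str | Path,
    study_length_days: int,
    format: str = "csv",
    menus: Sequence[str] = MENUS,
    baseline_path: str | Path | None = None,
    patient_ids: Sequence[str] | None = None,
) -> UsageLog:
    """Read a usage log from CSV or JSONL.

    Two CSV dialects are supported: ``patient_id,menu,day`` with integer
    baseline-relative day offsets, or ``patient_id,menu,date`` (ISO dates)
    together with a companion baseline table ``patient_id,baseline_date``
    passed as ``baseline_path``; dates are resolved to day offsets before
    construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "csv":
        try:
            frame = pd.read_csv(path, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error paths
            raise ParseError(str(exc)) from exc
        required_day = {"patient_id", "menu", "day"}
        required_date = {"patient_id", "menu", "date"}
        cols = set(frame.columns)
        if required_day <= cols:
            pass
        elif required_date <= cols:
            if baseline_path is None:
                raise ParseError(
                    "date-based log requires a baseline table (patient_id,baseline_date)"
                )
            baselines = pd.read_csv(baseline_path, dtype=str)
            baselines["baseline_date"] = pd.to_datetime(baselines["baseline_date"])
            frame["date"] = pd.to_datetime(frame["date"])
            frame = frame.merge(baselines, on="patient_id", how="left")
            if frame["baseline_date"].isna().any():
                missing = sorted(
                    frame.loc[frame["baseline_date"].isna(), "patient_id"].unique()
                )
                raise ValidationError(f"no baseline date for patient(s) {missing}")
            frame["day"] = (frame["date"] - frame["baseline_date"]).dt.days
        else:
            raise ParseError(
                f"need columns patient_id,menu,day (or date); got {sorted(cols)}"
            )
        for i, value in enumerate(frame["day"]):
            try:
                int(value)
            except (TypeError, ValueError):
                raise ParseError(f"day {value!r} is not an integer", row=i + 1) from None
        frame["day"] = frame["day"].astype(np.int64)
    elif format == "jsonl":
        records = []
        with path.open() as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    records.append(
                        (str(obj["patient_id"]), str(obj["menu"]), int(obj["day"]))
                    )
                except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                    raise ParseError(str(exc), row=i + 1) from exc
        frame = pd.DataFrame(records, columns=["patient_id", "menu", "day"])
        if frame.empty:
            frame = pd.DataFrame({"patient_id": [], "menu": [], "day": []})
    else:
        raise ValueError(f"unknown format {format!r}")

    return UsageLog(frame, study_length_days, menus=menus, patient_ids=patient_ids)


@dataclass(frozen=True)
class StudyWindow:
    """A half-open observation window ``[start_day, end_day)``.

    Week numbering inside the window is 1-based:
    ``week(d) = (d - start_day) // 7 + 1``.  ``total_weeks`` counts started
    weeks, ``ceil((end_day - start_day) / 7)``, and is identical for every
    patient — the retrospective "current week" denominator of the indices.
    """

    start_day: int
    end_day: int
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start_day < self.end_day):
            raise ValidationError(
                f"invalid window [{self.start_day}, {self.end_day})"
            )
        if not self.label:
            object.__setattr__(self, "label", f"{self.start_day}:{self.end_day}")

    @property
    def length_days(self) -> int:
        return self.end_day - self.start_day

    @property
    def total_weeks(self) -> int:
        return math.ceil(self.length_days / 7)

    def week_of(self, day: int) -> int:
        return (day - self.start_day) // 7 + 1

    def contains(self, day: int) -> bool:
        return self.start_day <= day < self.end_day


def month_window(start_month: int, end_month: int, month_days: int = 30) -> StudyWindow:
    """A window expressed in study months, e.g. ``month_window(3, 6)`` → [90, 180).

    Months are fixed 30-day blocks; the study's windows of interest are
    3–6 and 6–9 months after enrollment.
    """
    return StudyWindow(
        start_month * month_days, end_month * month_days, f"{start_month}-{end_month}mo"
    )


@dataclass(frozen=True)
class WindowedActivity:
    """Weekly activity summary for one patient inside one window.

    ``visit_days`` are in-window calendar days with at least one event (the
    session unit); ``menus_per_week`` counts *distinct* menus touched per
    1-based window week; ``weekly_visit_counts`` is the length-
    ``total_weeks`` series of visit-day counts that feeds the
    permutation-entropy recency index.
    """

    patient_id: str
    visit_days: tuple[int, ...]
    visit_weeks: tuple[int, ...]
    menus_per_week: Mapping[int, int]
    total_weeks: int
    weekly_visit_counts: tuple[int, ...] = field(default=())

    @property
    def final_usage_week(self) -> int:
        return max(self.visit_weeks) if self.visit_weeks else 0

    @property
    def n_visit_weeks(self) -> int:
        return len(self.visit_weeks)


def window_activity(
    log: UsageLog,
    window: StudyWindow,
    menus: Sequence[str] | None = None,
) -> dict[str, WindowedActivity]:
    """Summarize every patient's in-window activity on a menu subset.

    Only events with ``menu in menus`` and ``start_day <= day < end_day``
    count.  Every patient on the log's roster yields a summary; a patient
    with zero qualifying events yields empty visit sets.
    """
    menus = tuple(menus) if menus is not None else log.menus
    if not menus:
        raise ValidationError("menus subset must be nonempty")
    unknown = set(menus) - set(log.menus)
    if unknown:
        raise ValidationError(f"menus {sorted(unknown)} not in the log's enumeration")

    frame = log.to_frame()
    frame = frame[
        frame["menu"].isin(menus)
        & (frame["day"] >= window.start_day)
        & (frame["day"] < window.end_day)
    ]
    frame = frame.assign(week=(frame["day"] - window.start_day) // 7 + 1)

    total_weeks = window.total_weeks
    out: dict[str, WindowedActivity] = {}
    grouped = dict(tuple(frame.groupby("patient_id", sort=False)))
    for pid in log.patients:
        sub = grouped.get(pid)
        if sub is None or sub.empty:
            out[pid] = WindowedActivity(
                pid, (), (), {}, total_weeks, (0,) * total_weeks
            )
            continue
        visit_days = tuple(sorted(sub["day"].unique()))
        visit_weeks = tuple(sorted(sub["week"].unique()))
        menus_per_week = {
            int(w): int(g["menu"].nunique()) for w, g in sub.groupby("week")
        }
        counts = [0] * total_weeks
        for d in visit_days:
            counts[(d - window.start_day) // 7] += 1
        out[pid] = WindowedActivity(
            pid,
            visit_days,
            visit_weeks,
            menus_per_week,
            total_weeks,
            tuple(counts),
        )
    return out


def intervisit_gaps(activity: WindowedActivity) -> tuple[int, ...]:
    """Successive differences of the sorted visit weeks; empty with <2 weeks."""
    weeks = activity.visit_weeks
    if len(weeks) < 2:
        return ()
    return tuple(int(b - a) for a, b in zip(weeks[:-1], weeks[1:]))
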