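"""Synthetic usage-log cohorts with known ground truth.

No public mHealth usage-log dataset carries the structure the engagement
indices assume (per-menu event streams, decaying weekly activity,
engagement-dependent discontinuation), so this module generates one.  A
cohort is a mixture of *archetypes* — parameter bundles describing how
often a patient visits in a week, how many days they visit on an active
week, which menus they touch, how fast their activity decays, and how
their (archetype-level, true) engagement drives the weekly hazard of
abandoning the app.  Dropout is driven by these true engagement summaries,
not by the computed indices, so parameter-recovery tests can check that the
computed indices inherit the association without circularity.

Generation is week-level with uniform day placement inside the week: that
matches the indices' weekly resolution while still exercising the day-based
45-day discontinuation rule.  Ground truth (archetype, parameters, true
dropout week) is emitted alongside the log.  Everything is reproducible
from the seed.

The default cohort parameters live in ``data/default_cohort.yaml``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .log import MENUS, UsageEvent, UsageLog


@dataclass(frozen=True)
class ArchetypeSpec:
    """One engagement archetype of the synthetic population.

    ``weekly_visit_prob`` is the chance of ≥1 visit day in week 0; it
    declines by the factor ``decay_rate`` each week.  On an active week the
    number of visit days is 1 + Poisson(``visits_per_active_week`` − 1),
    capped at 7.  On each visit day every menu is used independently with
    its ``menu_probs`` entry (at least one menu is guaranteed).
    ``dropout_log_hazard_coeffs`` (b_mi, b_li, b_ri) link the archetype's
    true engagement summaries to the weekly log-hazard of discontinuation.
    """

    label: str
    weekly_visit_prob: float
    visits_per_active_week: float
    menu_probs: Mapping[str, float]
    decay_rate: float = 1.0
    dropout_log_hazard_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (0.0 <= self.weekly_visit_prob <= 1.0):
            raise ValidationError("weekly_visit_prob must be in [0,1]")
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValidationError("decay_rate must be in (0,1]")
        if self.visits_per_active_week < 1.0:
            raise ValidationError("visits_per_active_week must be ≥ 1")
        for menu, p in self.menu_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"menu_probs[{menu!r}] must be in [0,1]")

    @property
    def true_engagement(self) -> tuple[float, float, float]:
        """Archetype-level (s_mi, s_li, s_ri) engagement summaries.

        s_mi is the mean per-menu usage probability (menu breadth); s_li and
        s_ri both equal the weekly visit probability — under week-level
        Bernoulli activity, the regularity of the visit series and the
        fraction of accessed weeks are governed by the same parameter.
        """
        s_mi = float(np.mean(list(self.menu_probs.values())))
        return (s_mi, self.weekly_visit_prob, self.weekly_visit_prob)

    @property
    def weekly_dropout_hazard_factor(self) -> float:
        b = self.dropout_log_hazard_coeffs
        s = self.true_engagement
        return math.exp(sum(bi * si for bi, si in zip(b, s)))


@dataclass(frozen=True)
class CohortSpec:
    """Size, duration and archetype mixture of a synthetic cohort."""

    archetypes: tuple[ArchetypeSpec, ...]
    proportions: tuple[float, ...]
    n_patients: int = 233
    study_length_days: int = 540
    base_weekly_hazard: float = 0.15

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValidationError("n_patients must be ≥ 2")
        if len(self.archetypes) != len(self.proportions):
            raise ValidationError("one proportion per archetype required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError(
                f"archetype proportions must sum to 1, got {sum(self.proportions)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortSpec":
        archetypes = []
        proportions = []
        for a in raw["archetypes"]:
            coeffs = a.get("dropout_log_hazard_coeffs", {})
            if isinstance(coeffs, Mapping):
                coeffs = (
                    float(coeffs.get("mi", 0.0)),
                    float(coeffs.get("li", 0.0)),
                    float(coeffs.get("ri", 0.0)),
                )
            archetypes.append(
                ArchetypeSpec(
                    label=a["label"],
                    weekly_visit_prob=float(a["weekly_visit_prob"]),
                    visits_per_active_week=float(a["visits_per_active_week"]),
                    menu_probs=dict(a["menu_probs"]),
                    decay_rate=float(a.get("decay_rate", 1.0)),
                    dropout_log_hazard_coeffs=tuple(coeffs),
                )
            )
            proportions.append(float(a["proportion"]))
        return cls(
            archetypes=tuple(archetypes),
            proportions=tuple(proportions),
            n_patients=int(raw.get("n_patients", 233)),
            study_length_days=int(raw.get("study_length_days", 540)),
            base_weekly_hazard=float(raw.get("base_weekly_hazard", 0.15)),
        )


def default_cohort_spec() -> CohortSpec:
    """The packaged default: 233 patients, 540 days, three archetypes."""
    with resources.files("engagekit.data").joinpath("default_cohort.yaml").open() as fh:
        return CohortSpec.from_dict(yaml.safe_load(fh))


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator = 0
) -> tuple[UsageLog, pd.DataFrame]:
    """Sample a synthetic usage log and its ground-truth table.

    Per patient: draw an archetype; sample a discontinuation week from the
    geometric distribution implied by the archetype's weekly hazard
    ``base_weekly_hazard · exp(b · true_engagement)``; for each week before
    dropout, be active with probability ``weekly_visit_prob · decay^w``;
    on active weeks place visit days uniformly inside the week and sample
    per-day menu uses.  Returns the log (roster includes event-free
    patients) and a per-patient truth table with archetype, parameters and
    the true dropout week/day (−1 if never dropping out in-study).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_weeks = math.ceil(spec.study_length_days / 7)
    width = len(str(spec.n_patients))
    arch_idx = rng.choice(len(spec.archetypes), size=spec.n_patients, p=spec.proportions)

    events: list[UsageEvent] = []
    truth_rows = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:0{width}d}"
        arch = spec.archetypes[arch_idx[i]]
        menus = list(arch.menu_probs)
        probs = np.array([arch.menu_probs[m] for m in menus])

        hazard = spec.base_weekly_hazard * arch.weekly_dropout_hazard_factor
        p_drop = 1.0 - math.exp(-hazard)
        # geometric dropout week; None (=-1) if beyond the study
        u = rng.random()
        if p_drop > 0 and u < 1.0 - (1.0 - p_drop) ** n_weeks:
            dropout_week = int(np.floor(np.log1p(-u) / np.log1p(-p_drop)))
            dropout_week = min(dropout_week, n_weeks - 1)
        else:
            dropout_week = -1

        last_week = n_weeks if dropout_week < 0 else dropout_week
        for w in range(last_week):
            if rng.random() >= arch.weekly_visit_prob * arch.decay_rate**w:
                continue
            week_days = [
                d for d in range(7 * w, 7 * w + 7) if d < spec.study_length_days
            ]
            if not week_days:
                continue
            n_visits = 1 + rng.poisson(arch.visits_per_active_week - 1.0)
            n_visits = min(n_visits, len(week_days))
            days = rng.choice(week_days, size=n_visits, replace=False)
            for day in sorted(int(d) for d in days):
                used = rng.random(len(menus)) < probs
                if not used.any():
                    used[rng.choice(len(menus), p=probs / probs.sum())] = True
                for m, u_flag in zip(menus, used):
                    if u_flag:
                        events.append(UsageEvent(pid, m, day))

        s_mi, s_li, s_ri = arch.true_engagement
        truth_rows.append(
            {
                "patient_id": pid,
                "archetype": arch.label,
                "weekly_visit_prob": arch.weekly_visit_prob,
                "visits_per_active_week": arch.visits_per_active_week,
                "decay_rate": arch.decay_rate,
                "s_mi": s_mi,
                "s_li": s_li,
                "s_ri": s_ri,
                "weekly_hazard": hazard,
                "dropout_week": dropout_week,
                "dropout_day": -1 if dropout_week < 0 else 7 * dropout_week,
            }
        )

    log = UsageLog(
        events,
        spec.study_length_days,
        menus=MENUS,
        patient_ids=[row["patient_id"] for row in truth_rows],
    )
    truth = pd.DataFrame(truth_rows).set_index("patient_id").sort_index()
    return log, truth


def emulate_study_shape(seed: int = 7) -> tuple[UsageLog, pd.DataFrame]:
    """The repository's standard fixture: the default 233-patient cohort.

    A fixed 233-patient, 6-menu, 540-day log mixing engaged-regular,
    engaged-decaying and sporadic archetypes; identical seeds give
    bit-identical logs.
    """
    return generate_cohort(default_cohort_spec(), seed)


# ---------------------------------------------------------------------------
# Direct survival simulators for parameter-recovery and calibration tests
# ---------------------------------------------------------------------------

def simulate_cox_cohort(
    n: int = 233,
    beta: Mapping[str, float] | None = None,
    baseline_hazard: float = 0.01,
    censor_day: float = 450.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival records with a known proportional-hazards structure.

    Covariates named by ``beta`` (default ``{"li": -1.5}``) are drawn
    i.i.d. Uniform(0, 1); event times are exponential with rate
    ``baseline_hazard · exp(β · x)`` (in 1/day) and administratively
    censored at ``censor_day``.  Returns ``(records, covariates)`` in the
    shapes :func:`engagekit.evaluation.fit_cox` expects.
    """
    beta = dict(beta) if beta is not None else {"li": -1.5}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    covariates = pd.DataFrame(
        {name: rng.random(n) for name in beta}, index=pd.Index(ids, name="patient_id")
    )
    lin = sum(b * covariates[name].to_numpy() for name, b in beta.items())
    rate = baseline_hazard * np.exp(lin)
    t = rng.exponential(1.0 / rate)
    time = np.minimum(t, censor_day)
    event = t <= censor_day
    records = pd.DataFrame(
        {"time_days": np.maximum(time, 1e-6), "event": event},
        index=covariates.index,
    )
    return records, covariates


def simulate_two_group_survival(
    n_per_group: int = 100,
    hazard_ratio: float = 1.0,
    baseline_hazard: float = 0.01,
    censor_day: float = 450.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two equal groups with a given hazard ratio, for log-rank calibration.

    Returns ``(records, group_indicator)`` where the indicator series is
    0/1 and can be fed to :func:`engagekit.evaluation.logrank_by_index`
    (median split recovers the two groups).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 2 * n_per_group
    ids = pd.Index([f"G{i + 1:04d}" for i in range(n)], name="patient_id")
    group = np.repeat([0.0, 1.0], n_per_group)
    rate = baseline_hazard * np.where(group > 0, hazard_ratio, 1.0)
    t = rng.exponential(1.0 / rate)
    time = np.minimum(t, censor_day)
    event = t <= censor_day
    records = pd.DataFrame(
        {"time_days": np.maximum(time, 1e-6), "event": event}, index=ids
    )
    return records, pd.Series(group, index=ids, name="group")
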