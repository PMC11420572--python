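"""Evaluation of engagement indices: cross-window regression and usage survival.

Two arms judge whether an index captures long-term engagement:

1.  **Cross-window prediction.**  Ordinary least squares of the later
    window's EI (6–9 months) on the earlier window's three component
    indices (3–6 months) plus an intercept:

        EI_B = β0 + β1·MI_A + β2·LI_A + β3·RI_A + ε

    scored by in-sample MSE, RMSE and R².  (A same-window fit, regressing
    a window's EI on its own components, is available via
    ``same_window=True`` for completeness; since the EI is the exact mean
    of its components that fit is trivially perfect.)

2.  **Usage survival.**  The app-level discontinuation time — last session
    preceding the first ≥45-day all-menu nonusage gap, censored at study
    end otherwise — modelled by a Cox proportional-hazards fit on the
    earlier window's component indices (Efron handling of tied days), plus
    a two-group log-rank test per component at a median split.

Hazard ratios below 1 mean higher index values go with longer continued
app usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.stattools import durbin_watson

from .errors import DegenerateSplitError, DesignError, ValidationError
from .log import UsageLog


# ---------------------------------------------------------------------------
# Regression arm
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """An OLS fit of a later-window EI on earlier-window components."""

    coefficients: pd.Series            # const + one per component
    mse: float
    rmse: float
    r2: float
    n: int
    window_pair: tuple[str, str]
    combination_label: str
    patient_ids: tuple[str, ...] = field(repr=False, default=())
    bse: pd.Series | None = field(repr=False, default=None)
    diagnostics: dict[str, float] = field(default_factory=dict)

    def summary_row(self) -> dict[str, float]:
        return {"MSE": self.mse, "RMSE": self.rmse, "R2": self.r2}


def _check_design(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        corr = X.corr().abs()
        pairs = [
            f"{a}~{b}"
            for i, a in enumerate(X.columns)
            for b in X.columns[i + 1 :]
            if np.isclose(corr.loc[a, b], 1.0)
        ]
        detail = "; ".join(
            filter(None, [
                f"constant column(s): {constant}" if constant else "",
                f"perfectly collinear: {pairs}" if pairs else "",
            ])
        ) or "rank-deficient design"
        raise DesignError(f"cannot fit regression: {detail}")


def fit_ei_regression(
    predictors: pd.DataFrame,
    outcome: pd.Series,
    window_pair: tuple[str, str] = ("", ""),
    combination_label: str = "",
    diagnostics: bool = False,
) -> RegressionResult:
    """OLS of ``outcome`` (EI at window B) on three component indices at window A.

    ``predictors`` is a patients × components frame (e.g. columns
    ``mi, li, ri``); ``outcome`` a patient-indexed EI series.  Patients are
    matched by id and must coincide exactly.  Metrics are in-sample
    goodness of fit.  With ``diagnostics=True``, Shapiro-Wilk normality of
    residuals and the Durbin-Watson statistic are attached as optional
    report fields.
    """
    unmatched = set(predictors.index).symmetric_difference(outcome.index)
    if unmatched:
        raise ValidationError(
            f"predictor/outcome patient sets differ: {sorted(unmatched)[:10]}"
        )
    n = len(predictors)
    if n < predictors.shape[1] + 2:
        raise ValidationError(
            f"need at least {predictors.shape[1] + 2} patients, got {n}"
        )
    X = predictors.sort_index().astype(float)
    y = outcome.sort_index().astype(float)
    _check_design(X)

    model = sm.OLS(y, sm.add_constant(X)).fit()
    resid = model.resid.to_numpy()
    mse = float(np.mean(resid**2))
    diag: dict[str, float] = {}
    if diagnostics:
        diag["shapiro_w"], diag["shapiro_p"] = (
            float(v) for v in sps.shapiro(resid)
        )
        diag["durbin_watson"] = float(durbin_watson(resid))
    return RegressionResult(
        coefficients=model.params,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        r2=float(model.rsquared),
        n=n,
        window_pair=window_pair,
        combination_label=combination_label,
        patient_ids=tuple(X.index),
        bse=model.bse,
        diagnostics=diag,
    )


def compare_models(results: Mapping[str, RegressionResult]) -> pd.DataFrame:
    """Side-by-side MSE/RMSE/R² table for several fitted index variants.

    All fits must cover the same patient set and window pair.  The variant
    with the largest R² is flagged in a boolean ``best`` column.
    """
    if not results:
        raise ValidationError("no results to compare")
    items = list(results.items())
    ref_patients = set(items[0][1].patient_ids)
    ref_pair = items[0][1].window_pair
    for label, res in items[1:]:
        if set(res.patient_ids) != ref_patients:
            raise ValidationError(f"model {label!r} fitted on a different patient set")
        if res.window_pair != ref_pair:
            raise ValidationError(f"model {label!r} fitted on a different window pair")
    table = pd.DataFrame(
        {label: res.summary_row() for label, res in items}
    ).T
    table["best"] = table["R2"] == table["R2"].max()
    table.index.name = "model"
    return table


# ---------------------------------------------------------------------------
# Survival arm
# ---------------------------------------------------------------------------

def derive_usage_survival(
    log: UsageLog,
    origin_day: int = 90,
    gap_threshold_days: int = 45,
) -> pd.DataFrame:
    """App-level discontinuation time per patient from ``origin_day``.

    Scanning all-menu sessions on or after the origin: the patient
    discontinues at the last session preceding the first ≥45-day all-menu
    nonusage gap (gaps between sessions and the trailing gap to study end
    both count); otherwise they are censored at study end.  A patient with
    no post-origin session is assigned time = 1 day, discontinued (zero
    durations are invalid in proportional-hazards fitting).

    Returns a DataFrame indexed by patient with ``time_days`` and boolean
    ``event`` (True = discontinued).
    """
    if not (0 <= origin_day < log.study_length_days):
        raise ValidationError(f"origin_day {origin_day} outside the study period")
    horizon = log.study_length_days
    rows = {}
    for pid in log.patients:
        days = log.events_for(pid)
        days = np.unique(days[days >= origin_day])
        if days.size == 0:
            rows[pid] = (1.0, True)
            continue
        end = days[0]
        discontinued = False
        for cur, nxt in zip(days[:-1], days[1:]):
            if nxt - cur >= gap_threshold_days:
                discontinued = True
                break
            end = nxt
        else:
            end = days[-1]
            if horizon - days[-1] >= gap_threshold_days:
                discontinued = True
        if discontinued:
            time = max(float(end - origin_day), 1.0)
        else:
            time = float(horizon - origin_day)
        rows[pid] = (time, discontinued)
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["time_days", "event"]
    )
    frame.index.name = "patient_id"
    frame["time_days"] = frame["time_days"].astype(float)
    frame["event"] = frame["event"].astype(bool)
    return frame.sort_index()


@dataclass
class SurvivalResult:
    """A Cox proportional-hazards fit of usage survival on component indices."""

    table: pd.DataFrame                # per component: hr, ci_low, ci_high, p
    n_events: int
    n_censored: int
    time_unit: str = "days"
    logrank_p: dict[str, float] = field(default_factory=dict)
    combination_label: str = ""
    fitters: dict[str, CoxPHFitter] = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.n_events + self.n_censored


def fit_cox(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    univariate: bool = False,
    combination_label: str = "",
) -> SurvivalResult:
    """Cox proportional-hazards fit of discontinuation on component indices.

    ``records`` comes from :func:`derive_usage_survival`; ``covariates`` is
    a patient-indexed frame of component indices (e.g. ``mi, li, ri``).
    By default all components enter jointly (the proportional-hazards
    formula with β1..β3); ``univariate=True`` fits one model per component
    instead.  Ties in event days are handled with the Efron approximation
    (the lifelines default).  Returns per-component hazard ratios with 95%
    CIs and Wald p-values.
    """
    unmatched = set(records.index).symmetric_difference(covariates.index)
    if unmatched:
        raise ValidationError(
            f"survival/covariate patient sets differ: {sorted(unmatched)[:10]}"
        )
    if not np.isfinite(covariates.to_numpy(dtype=float)).all():
        raise ValidationError("covariates must be finite")
    if int(records["event"].sum()) < 2:
        raise ValidationError("need at least 2 discontinuation events")
    _check_design(covariates)

    records = records.sort_index()
    covariates = covariates.sort_index().astype(float)
    components = list(covariates.columns)
    groups = [[c] for c in components] if univariate else [components]

    rows = {}
    fitters: dict[str, CoxPHFitter] = {}
    for group in groups:
        data = pd.concat([records[["time_days", "event"]], covariates[group]], axis=1)
        cph = CoxPHFitter()
        try:
            cph.fit(data, duration_col="time_days", event_col="event")
        except Exception as exc:
            raise DesignError(f"Cox fit failed for {group}: {exc}") from exc
        for comp in group:
            rows[comp] = {
                "hr": float(np.exp(cph.params_[comp])),
                "ci_low": float(np.exp(cph.confidence_intervals_.loc[comp].iloc[0])),
                "ci_high": float(np.exp(cph.confidence_intervals_.loc[comp].iloc[1])),
                "p": float(cph.summary.loc[comp, "p"]),
                "coef": float(cph.params_[comp]),
                "se": float(cph.standard_errors_[comp]),
            }
            fitters[comp] = cph
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "component"
    n_events = int(records["event"].sum())
    return SurvivalResult(
        table=table,
        n_events=n_events,
        n_censored=len(records) - n_events,
        logrank_p={},
        combination_label=combination_label,
        fitters=fitters,
    )


def logrank_by_index(
    records: pd.DataFrame,
    index_values: pd.Series,
    split: str = "median",
) -> tuple[float, float]:
    """Two-group log-rank test of usage survival, high vs low index.

    Groups are formed at the stated split of the index (currently only the
    median: high = value strictly above the median).  Returns
    ``(statistic, p_value)``.  A constant index cannot be split and raises
    :class:`DegenerateSplitError`.
    """
    if split != "median":
        raise ValidationError(f"unknown split {split!r}")
    unmatched = set(records.index).symmetric_difference(index_values.index)
    if unmatched:
        raise ValidationError(f"patient sets differ: {sorted(unmatched)[:10]}")
    values = index_values.sort_index().astype(float)
    records = records.sort_index()
    cut = float(values.median())
    high = values > cut
    if high.all() or not high.any():
        raise DegenerateSplitError(
            "median split produced an empty group (index constant?)"
        )
    res = logrank_test(
        records.loc[high.values, "time_days"],
        records.loc[~high.values, "time_days"],
        event_observed_A=records.loc[high.values, "event"],
        event_observed_B=records.loc[~high.values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def km_curves(
    records: pd.DataFrame,
    index_values: pd.Series,
    label: str = "index",
) -> tuple[KaplanMeierFitter, KaplanMeierFitter]:
    """Kaplan-Meier fitters for the high/low median-split groups (plotting aid)."""
    values = index_values.sort_index().astype(float)
    records = records.sort_index()
    high = values > float(values.median())
    if high.all() or not high.any():
        raise DegenerateSplitError("median split produced an empty group")
    fits = []
    for mask, name in ((high, f"{label} high"), (~high, f"{label} low")):
        km = KaplanMeierFitter()
        km.fit(
            records.loc[mask.values, "time_days"],
            records.loc[mask.values, "event"],
            label=name,
        )
        fits.append(km)
    return tuple(fits)
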