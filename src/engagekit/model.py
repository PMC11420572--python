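"""The end-to-end engagement study as a model/results pair.

:class:`EngagementStudy` bundles a usage log with a predictor window and an
outcome window; :meth:`EngagementStudy.fit` computes the existing EI and
the new EI under each requested menu combination in both windows, fits the
cross-window regressions and the usage-survival Cox models, and returns an
:class:`EngagementStudyResults` carrying the comparison table, per-model
coefficient estimates, hazard ratios with confidence intervals, log-rank
p-values and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .config import EngageConfig
from .errors import DegenerateSplitError
from .evaluation import (
    RegressionResult,
    SurvivalResult,
    compare_models,
    derive_usage_survival,
    fit_cox,
    fit_ei_regression,
    km_curves,
    logrank_by_index,
)
from .existing import existing_ei_cohort
from .log import StudyWindow, UsageLog, month_window
from .novel import new_ei_cohort

EXISTING = "existing"
_COMPONENTS = {EXISTING: ["click_depth", "loyalty", "recency"]}


class EngagementStudy:
    """An engagement-index comparison study on one usage log.

    Parameters
    ----------
    log
        The cohort's usage log.
    predictor_window, outcome_window
        The earlier window whose component indices act as predictors and
        the later window whose EI is the outcome.  Defaults: 3–6 and 6–9
        study months (30-day months, so days [90, 180) and [180, 270)).
    combinations
        Labels of the new-EI menu combinations to evaluate.
    config
        Index parameters (gap threshold, PE embedding, calibration...).
    """

    def __init__(
        self,
        log: UsageLog,
        predictor_window: StudyWindow | None = None,
        outcome_window: StudyWindow | None = None,
        combinations: Sequence[str] = ("EI1", "EI2", "EI3"),
        config: EngageConfig | None = None,
    ):
        self.log = log
        self.config = config or EngageConfig()
        md = self.config.month_days
        self.predictor_window = predictor_window or month_window(3, 6, md)
        self.outcome_window = outcome_window or month_window(6, 9, md)
        self.combinations = tuple(combinations)
        for label in self.combinations:
            self.config.combination(label)  # validate early

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, study_length_days: int, **kwargs
    ) -> "EngagementStudy":
        """Build a study from a ``patient_id, menu, day`` event frame."""
        return cls(UsageLog(frame, study_length_days), **kwargs)

    # -- index computation --------------------------------------------------
    def indices(self, window: StudyWindow) -> dict[str, pd.DataFrame]:
        """Component indices per model label ({'existing', 'EI1', ...}) in a window."""
        cfg = self.config
        out = {EXISTING: existing_ei_cohort(self.log, window)}
        for label in self.combinations:
            out[label] = new_ei_cohort(
                self.log,
                window,
                combination=cfg.combination(label),
                gap_threshold_days=cfg.gap_threshold_days,
                order=cfg.pe_order,
                delay=cfg.pe_delay,
                calibration=cfg.calibration,
            )
        return out

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        survival: bool = True,
        univariate: bool = False,
        same_window: bool = False,
        diagnostics: bool = False,
    ) -> "EngagementStudyResults":
        """Run both evaluation arms and return the bundled results.

        ``same_window=True`` reproduces the literal same-window regression
        (outcome EI and predictors from the predictor window);
        ``univariate=True`` fits the Cox model one component at a time
        instead of jointly.
        """
        pred = self.indices(self.predictor_window)
        outc = pred if same_window else self.indices(self.outcome_window)

        regressions: dict[str, RegressionResult] = {}
        for label, pframe in pred.items():
            cols = _COMPONENTS.get(label, ["mi", "li", "ri"])
            regressions[label] = fit_ei_regression(
                pframe[cols],
                outc[label]["ei"],
                window_pair=(self.predictor_window.label, self.outcome_window.label),
                combination_label=label,
                diagnostics=diagnostics,
            )
        comparison = compare_models(regressions)

        survival_results: dict[str, SurvivalResult] = {}
        records = None
        if survival:
            records = derive_usage_survival(
                self.log,
                origin_day=self.config.survival_origin_day,
                gap_threshold_days=self.config.gap_threshold_days,
            )
            for label, pframe in pred.items():
                cols = _COMPONENTS.get(label, ["mi", "li", "ri"])
                res = fit_cox(
                    records,
                    pframe[cols],
                    univariate=univariate,
                    combination_label=label,
                )
                for comp in cols:
                    try:
                        _, p = logrank_by_index(records, pframe[comp])
                    except DegenerateSplitError:
                        p = float("nan")
                    res.logrank_p[comp] = p
                survival_results[label] = res

        return EngagementStudyResults(
            study=self,
            regressions=regressions,
            comparison=comparison,
            survival=survival_results,
            records=records,
            predictor_indices=pred,
        )


@dataclass
class EngagementStudyResults:
    """Fitted comparison of engagement-index variants on one cohort."""

    study: EngagementStudy
    regressions: dict[str, RegressionResult]
    comparison: pd.DataFrame
    survival: dict[str, SurvivalResult]
    records: pd.DataFrame | None
    predictor_indices: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)

    @property
    def best_model(self) -> str:
        return str(self.comparison["R2"].idxmax())

    def survival_table(self, label: str) -> pd.DataFrame:
        """Per-component HR, 95% CI, Wald p and log-rank p for one variant."""
        res = self.survival[label]
        table = res.table[["hr", "ci_low", "ci_high", "p"]].copy()
        table["logrank_p"] = pd.Series(res.logrank_p)
        return table

    def plot_km(self, label: str, component: str, ax=None):
        """Kaplan-Meier curves for the median split of one component index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.predictor_indices[label]
        for km in km_curves(self.records, frame[component], label=f"{label} {component}"):
            km.plot_survival_function(ax=ax)
        ax.set_xlabel("days since survival origin")
        ax.set_ylabel("fraction still using the app")
        return ax

    def summary(self) -> str:
        """A printable report: regression comparison plus survival tables."""
        lines = [
            "Engagement index comparison",
            "===========================",
            f"patients: {self.regressions[EXISTING].n}    "
            f"windows: {self.study.predictor_window.label} -> "
            f"{self.study.outcome_window.label}",
            "",
            "Cross-window EI prediction (in-sample):",
            self.comparison.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            f"best model by R2: {self.best_model}",
        ]
        if self.survival:
            n_ev = next(iter(self.survival.values())).n_events
            n_cen = next(iter(self.survival.values())).n_censored
            lines += [
                "",
                f"Usage survival from day {self.study.config.survival_origin_day} "
                f"({n_ev} discontinuations, {n_cen} censored):",
            ]
            for label in self.survival:
                lines += [
                    f"-- {label}",
                    self.survival_table(label).to_string(
                        float_format=lambda v: f"{v:.4g}"
                    ),
                ]
        return "\n".join(lines)
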