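"""Run configuration: menus, combinations, windows and index parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ValidationError
from .log import MENUS
from .novel import COMBINATIONS, MenuCombination


@dataclass(frozen=True)
class EngageConfig:
    """All tunable knobs of the index pipeline, with study defaults.

    * ``gap_threshold_days`` — nonusage span defining discontinuation
      (45 days: the cohort's 75th-percentile inter-usage gap).
    * ``pe_order`` / ``pe_delay`` — permutation-entropy embedding (m=3,
      τ=1: standard choices for short weekly series).
    * ``calibration`` — ``"none"`` (normalized PE) or
      ``"truncated_normal_cdf"`` (cohort-fitted truncated-normal CDF map).
    * ``survival_origin_day`` — day the usage-survival clock starts
      (default 90 = start of the 3–6-month window).
    * ``month_days`` — fixed month length used to spell windows (30).
    """

    menus: tuple[str, ...] = MENUS
    combinations: dict[str, MenuCombination] = field(
        default_factory=lambda: dict(COMBINATIONS)
    )
    gap_threshold_days: int = 45
    pe_order: int = 3
    pe_delay: int = 1
    calibration: str = "none"
    survival_origin_day: int = 90
    month_days: int = 30

    def combination(self, label: str) -> MenuCombination:
        try:
            return self.combinations[label]
        except KeyError:
            raise ValidationError(
                f"unknown combination {label!r}; known: {sorted(self.combinations)}"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngageConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        menus = tuple(raw.get("menus", cfg.menus))
        combos = dict(cfg.combinations)
        for label, menu_list in raw.get("combinations", {}).items():
            combos[label] = MenuCombination(label, tuple(menu_list))
        for combo in combos.values():
            unknown = set(combo.menus) - set(menus)
            if unknown:
                raise ValidationError(
                    f"combination {combo.label!r} uses unknown menus {sorted(unknown)}"
                )
        return replace(
            cfg,
            menus=menus,
            combinations=combos,
            gap_threshold_days=int(raw.get("gap_threshold_days", cfg.gap_threshold_days)),
            pe_order=int(raw.get("pe_order", cfg.pe_order)),
            pe_delay=int(raw.get("pe_delay", cfg.pe_delay)),
            calibration=str(raw.get("calibration", cfg.calibration)),
            survival_origin_day=int(
                raw.get("survival_origin_day", cfg.survival_origin_day)
            ),
            month_days=int(raw.get("month_days", cfg.month_days)),
        )
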