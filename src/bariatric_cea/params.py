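"""Intervention charges, cost conversion, and the base-case parameter set.

All monetary amounts are 2013 US$.  Charges are stored per phase/category so
the aggregation from billing lines to the total intervention cost is
auditable; the canonical printed total ($47,438) differs from the component
sum ($47,437) by $1 of per-row rounding, which is kept as-is rather than
"fixed".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .mortality import MortalityModel
from .trajectory import ArmSpec, RegainSchedule

__all__ = [
    "ChargeLine",
    "CostParameters",
    "ModelParameters",
    "CalibrationTargets",
    "aggregate_charges",
    "charges_to_costs",
    "load_charge_lines",
    "bundled_charge_lines",
    "default_parameters",
    "load_config",
]

Phase = Literal["preoperative", "perioperative", "postoperative", "foundation"]


@dataclass(frozen=True)
class ChargeLine:
    """One billing category's mean and SD of charges (2013 US$)."""

    phase: Phase
    category: str
    mean_charge: float
    sd_charge: float

    def __post_init__(self) -> None:
        if self.phase not in ("preoperative", "perioperative", "postoperative", "foundation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.mean_charge < 0:
            raise ValueError(f"mean_charge must be >= 0, got {self.mean_charge}")
        if self.sd_charge < 0:
            raise ValueError(f"sd_charge must be >= 0, got {self.sd_charge}")


@dataclass(frozen=True)
class CostParameters:
    """Total charges and their conversion to intervention costs."""

    total_charges: float = 47_438.0
    cost_to_charge_ratio: float = 0.545
    intervention_cost: float = 25_854.0
    intervention_cost_sd: float = 2_044.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cost_to_charge_ratio <= 1.0:
            raise ValueError(
                f"cost_to_charge_ratio must be in (0, 1], got {self.cost_to_charge_ratio}"
            )
        if min(self.total_charges, self.intervention_cost, self.intervention_cost_sd) < 0:
            raise ValueError("monetary fields must be >= 0")
        implied = self.total_charges * self.cost_to_charge_ratio
        if abs(implied - self.intervention_cost) > 1.0:
            raise ValueError(
                f"intervention_cost {self.intervention_cost} is not "
                f"total_charges x ratio = {implied:.2f} within rounding"
            )


def aggregate_charges(lines: Iterable[ChargeLine]) -> float:
    """Sum of mean charges over billing lines (empty list -> 0)."""
    return float(sum(line.mean_charge for line in lines))


def charges_to_costs(total_charges: float, ratio: float) -> float:
    """Convert billed charges to economic costs via a cost-to-charge ratio."""
    if total_charges < 0:
        raise ValueError(f"total_charges must be >= 0, got {total_charges}")
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    return total_charges * ratio


def load_charge_lines(path: str | Path) -> list[ChargeLine]:
    """Read a 4-column delimited table (phase, category, mean, sd)."""
    frame = pd.read_csv(path)
    expected = ["phase", "category", "mean_charge", "sd_charge"]
    if list(frame.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(frame.columns)}")
    return [
        ChargeLine(
            phase=row.phase,
            category=row.category,
            mean_charge=float(row.mean_charge),
            sd_charge=float(row.sd_charge),
        )
        for row in frame.itertuples()
    ]


def bundled_charge_lines() -> list[ChargeLine]:
    """The bundled per-category charge table (13 billing lines)."""
    with resources.as_file(
        resources.files("bariatric_cea").joinpath("data/charge_lines.csv")
    ) as path:
        return load_charge_lines(path)


@dataclass(frozen=True)
class CalibrationTargets:
    """Published outputs the mortality link and baseline utility are tuned to."""

    added_life_years_y1: float = 0.00624
    added_life_years_y7: float = 0.15815
    added_qalys_y1: float = 0.060


@dataclass(frozen=True)
class ModelParameters:
    """Complete base-case input set for the cohort model.

    ``u_base`` is the utility of the no-surgery reference state.  It is not an
    external input: provenance is "calibrated" (to the year-1 added-QALY
    target) unless overridden via configuration.
    """

    cost_params: CostParameters = field(default_factory=CostParameters)
    savings_per_bmi: float = 157.0
    savings_per_bmi_se: float = 47.0
    hrql_gain_per_bmi: float = 0.0042
    hrql_gain_per_bmi_se: float = 0.0011
    bmi_pre: float = 48.7
    bmi_reduction: float = 13.2
    weight_loss_kg: float = 37.5
    weight_loss_kg_sd: float = 13.5
    regain: RegainSchedule = field(default_factory=RegainSchedule)
    mortality: MortalityModel = field(default_factory=MortalityModel)
    u_base: float = 1.0
    discount_rate: float = 0.03
    start_age: int = 18
    wtp_threshold: float = 100_000.0
    n_patients: int = 11

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if not 0.0 < self.u_base <= 1.0:
            raise ValueError(f"u_base must be in (0, 1], got {self.u_base}")
        if not self.bmi_reduction < self.bmi_pre:
            raise ValueError("bmi_reduction must be smaller than bmi_pre")
        monetary = (
            self.savings_per_bmi,
            self.savings_per_bmi_se,
            self.wtp_threshold,
        )
        if min(monetary) < 0:
            raise ValueError("monetary fields must be >= 0")

    @property
    def intervention_cost(self) -> float:
        return self.cost_params.intervention_cost

    def surgery_arm(self) -> ArmSpec:
        return ArmSpec(arm="surgery", bmi_pre=self.bmi_pre, bmi_reduction=self.bmi_reduction)

    def no_surgery_arm(self) -> ArmSpec:
        return ArmSpec(arm="no_surgery", bmi_pre=self.bmi_pre, bmi_reduction=0.0)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def with_mortality(self, model: MortalityModel) -> "ModelParameters":
        return dataclasses.replace(self, mortality=model)


def default_parameters() -> ModelParameters:
    """Base-case inputs as published; mortality link and u_base uncalibrated.

    Run :func:`bariatric_cea.model.calibrate_parameters` to obtain the fully
    calibrated parameter set used by the base-case analysis.
    """
    return ModelParameters()


_CONFIG_FLOAT_KEYS = {
    "total_charges",
    "cost_to_charge_ratio",
    "intervention_cost",
    "intervention_cost_sd",
    "savings_per_bmi",
    "savings_per_bmi_se",
    "hrql_gain_per_bmi",
    "hrql_gain_per_bmi_se",
    "bmi_pre",
    "bmi_reduction",
    "weight_loss_kg",
    "weight_loss_kg_sd",
    "regain_annual_fraction",
    "regain_plateau_fraction",
    "q0",
    "u_base",
    "discount_rate",
    "wtp_threshold",
    "added_life_years_y1",
    "added_life_years_y7",
    "added_qalys_y1",
}
_CONFIG_INT_KEYS = {"start_age", "regain_first_regain_cycle", "n_patients"}


def load_config(path: str | Path) -> dict[str, float | int]:
    """Parse a flat ``key = value`` config file; unknown keys are hard errors."""
    overrides: dict[str, float | int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _CONFIG_INT_KEYS:
            overrides[key] = int(value)
        elif key in _CONFIG_FLOAT_KEYS:
            overrides[key] = float(value)
        else:
            valid = sorted(_CONFIG_FLOAT_KEYS | _CONFIG_INT_KEYS)
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}; valid keys: {valid}")
    return overrides


def apply_config(params: ModelParameters, overrides: dict[str, float | int]) -> ModelParameters:
    """Return a copy of `params` with flat config overrides applied."""
    cost_kwargs = {}
    regain_kwargs = {}
    top_kwargs = {}
    for key, value in overrides.items():
        if key in ("added_life_years_y1", "added_life_years_y7", "added_qalys_y1"):
            continue  # calibration targets, handled by the caller
        if key in ("total_charges", "cost_to_charge_ratio", "intervention_cost", "intervention_cost_sd"):
            cost_kwargs[key] = value
        elif key.startswith("regain_"):
            regain_kwargs[key.removeprefix("regain_")] = value
        elif key == "q0":
            top_kwargs["mortality"] = dataclasses.replace(params.mortality, q0=float(value))
        else:
            top_kwargs[key] = value
    if cost_kwargs:
        top_kwargs["cost_params"] = dataclasses.replace(params.cost_params, **cost_kwargs)
    if regain_kwargs:
        top_kwargs["regain"] = dataclasses.replace(params.regain, **regain_kwargs)
    return params.replace(**top_kwargs)
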