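"""Age- and BMI-dependent annual mortality.

A parametric (Gompertz) synthetic life table stands in for a national
age-indexed life table: the annual death probability rises exponentially with
age from an anchor value at the cohort's starting age.  The benefit of a lower
BMI enters as a log-linear hazard multiplier, exp(-beta * delta_bmi), whose
magnitude is not assumed but calibrated so that the cohort model reproduces
target added-life-year values at two horizons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

if TYPE_CHECKING:  # pragma: no cover
    from .params import ModelParameters

__all__ = [
    "LifeTable",
    "MortalityModel",
    "CalibrationError",
    "make_gompertz_life_table",
    "death_prob",
    "calibrate_mortality",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be met inside the search box."""


@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death by integer age over a closed age range."""

    start_age: int
    max_age: int
    annual_death_prob: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.max_age <= self.start_age:
            raise ValueError("max_age must exceed start_age")
        for age in range(self.start_age, self.max_age + 1):
            if age not in self.annual_death_prob:
                raise ValueError(f"life table missing age {age}")
            p = self.annual_death_prob[age]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"death probability at age {age} outside [0, 1]: {p}")

    def prob(self, age: int) -> float:
        if not self.start_age <= age <= self.max_age:
            raise ValueError(
                f"age {age} outside life-table range [{self.start_age}, {self.max_age}]"
            )
        return self.annual_death_prob[age]

    def to_frame(self) -> pd.DataFrame:
        ages = range(self.start_age, self.max_age + 1)
        return pd.DataFrame(
            {"age": list(ages), "annual_death_prob": [self.annual_death_prob[a] for a in ages]}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "LifeTable":
        frame = pd.read_csv(path, sep="\t")
        ages = frame["age"].astype(int).to_numpy()
        return cls(
            start_age=int(ages.min()),
            max_age=int(ages.max()),
            annual_death_prob=dict(zip(ages, frame["annual_death_prob"].astype(float))),
        )


@dataclass(frozen=True)
class MortalityModel:
    """Gompertz anchor + slope and the BMI-mortality hazard coefficient.

    q0 is the annual death probability at the starting age for the reference
    (no-surgery) BMI; g is the log-slope per year of age; beta is the
    log-hazard reduction per unit of BMI reduction.
    """

    q0: float = 0.008
    gompertz_slope: float = 0.0
    bmi_log_hazard: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.q0 < 1.0:
            raise ValueError(f"q0 must be in (0, 1), got {self.q0}")
        if self.bmi_log_hazard < 0:
            raise ValueError(f"beta must be >= 0, got {self.bmi_log_hazard}")


def make_gompertz_life_table(
    q0: float, g: float, start_age: int, max_age: int = 110
) -> LifeTable:
    """Life table with annual_death_prob(a) = min(1, q0 * exp(g * (a - start_age)))."""
    if not 0.0 < q0 < 1.0:
        raise ValueError(f"q0 must be in (0, 1), got {q0}")
    probs = {
        age: min(1.0, q0 * math.exp(g * (age - start_age)))
        for age in range(start_age, max_age + 1)
    }
    return LifeTable(start_age=start_age, max_age=max_age, annual_death_prob=probs)


def death_prob(table: LifeTable, model: MortalityModel, age: int, delta_bmi: float) -> float:
    """Annual death probability at `age` given a BMI reduction `delta_bmi`."""
    if delta_bmi < 0:
        raise ValueError(f"delta_bmi must be >= 0, got {delta_bmi}")
    base = table.prob(age)
    return min(1.0, base * math.exp(-model.bmi_log_hazard * delta_bmi))


def calibrate_mortality(
    params: "ModelParameters",
    ly_target_y1: float,
    ly_target_y7: float,
    *,
    g_bounds: tuple[float, float] = (-0.5, 0.5),
    rtol: float = 1e-9,
) -> MortalityModel:
    """Find (g, beta) so the cohort model hits two added-life-year targets.

    The two-dimensional root problem decomposes exactly: the year-1 added
    life-years depend only on beta (closed form), after which the year-7
    residual is a monotone function of g solved by Brent's method.  Added
    life-years follow the model's reporting convention (discounted survival
    gap, see :mod:`bariatric_cea.model`).

    Raises
    ------
    CalibrationError
        If the targets are not positive and increasing, if the year-1 target
        is infeasible for the anchor probability, or if no root for g lies in
        `g_bounds` (the error reports residuals at the box corners).
    """
    from .model import added_life_years  # local import: model depends on this module

    if not (0.0 < ly_target_y1 < ly_target_y7):
        raise CalibrationError(
            f"targets must be positive and increasing, got ({ly_target_y1}, {ly_target_y7})"
        )
    q0 = params.mortality.q0
    r = params.discount_rate
    d1 = params.bmi_reduction * (1.0 - params.regain.cumulative_regain(1))
    # Year 1: added LY = q0 * (1 - exp(-beta*d1)) / (1+r)  =>  closed form for beta.
    frac = ly_target_y1 * (1.0 + r) / q0
    if not 0.0 < frac < 1.0:
        raise CalibrationError(
            f"year-1 target {ly_target_y1} infeasible for q0={q0} "
            f"(requires 0 < target*(1+r)/q0 < 1, got {frac:.6g}); "
            "with beta forced to 0 added life-years are 0 at every horizon"
        )
    if d1 <= 0:
        raise CalibrationError("surgery arm has no BMI reduction; beta unidentifiable")
    beta = -math.log(1.0 - frac) / d1

    def residual_y7(g: float) -> float:
        model = MortalityModel(q0=q0, gompertz_slope=g, bmi_log_hazard=beta)
        return added_life_years(params.with_mortality(model), horizon=7) - ly_target_y7

    lo, hi = g_bounds
    r_lo, r_hi = residual_y7(lo), residual_y7(hi)
    if r_lo * r_hi > 0:
        raise CalibrationError(
            f"no root for g in [{lo}, {hi}]: residuals {r_lo:.6g} and {r_hi:.6g} "
            "have the same sign"
        )
    g = brentq(residual_y7, lo, hi, xtol=1e-14, rtol=8.9e-16)
    model = MortalityModel(q0=q0, gompertz_slope=g, bmi_log_hazard=beta)
    resid = residual_y7(g)
    if abs(resid) > rtol * ly_target_y7:
        raise CalibrationError(f"year-7 residual {resid:.3g} exceeds tolerance")
    return model
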