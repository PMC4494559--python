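"""Post-surgical BMI trajectories with partial weight regain.

The surgery arm starts each model cycle with a BMI reduction relative to the
pre-operative value; a fraction of that reduction is regained each year from
the second post-surgical year onward, up to a plateau.  The comparator arm
keeps its pre-operative BMI throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "RegainSchedule",
    "ArmSpec",
    "delta_bmi_at_cycle",
    "delta_bmi_series",
]


@dataclass(frozen=True)
class RegainSchedule:
    """Fractional reversal of the initial BMI reduction over time.

    Parameters
    ----------
    annual_fraction
        Fraction of the *initial* reduction regained per year (simple, not
        compounding).  Base case 0.05.
    first_regain_cycle
        First cycle in which regain applies; cycle 1 is the first
        post-surgical year and carries the full measured reduction.
    plateau_fraction
        Maximum cumulative regain.  Base case 0.25, reached after five
        regain years (cycles 2-6) and constant thereafter.
    """

    annual_fraction: float = 0.05
    first_regain_cycle: int = 2
    plateau_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_fraction <= 1.0:
            raise ValueError(f"annual_fraction must be in [0, 1], got {self.annual_fraction}")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError(f"plateau_fraction must be in [0, 1], got {self.plateau_fraction}")
        if self.first_regain_cycle < 1:
            raise ValueError(f"first_regain_cycle must be >= 1, got {self.first_regain_cycle}")

    def cumulative_regain(self, cycle: int) -> float:
        """Cumulative regained fraction of the initial reduction at `cycle`."""
        n_regain_years = max(0, cycle - self.first_regain_cycle + 1)
        return min(self.plateau_fraction, self.annual_fraction * n_regain_years)


@dataclass(frozen=True)
class ArmSpec:
    """One cohort arm: pre-operative BMI and initial BMI reduction.

    The comparator (``no_surgery``) arm must have zero reduction.
    """

    arm: Literal["surgery", "no_surgery"]
    bmi_pre: float
    bmi_reduction: float

    def __post_init__(self) -> None:
        if self.arm not in ("surgery", "no_surgery"):
            raise ValueError(f"arm must be 'surgery' or 'no_surgery', got {self.arm!r}")
        if self.arm == "no_surgery" and self.bmi_reduction != 0.0:
            raise ValueError("no_surgery arm must have bmi_reduction = 0")
        if self.bmi_reduction < 0:
            raise ValueError("bmi_reduction must be >= 0")
        if self.bmi_reduction >= self.bmi_pre > 0 and self.bmi_reduction > 0:
            raise ValueError(
                f"bmi_reduction ({self.bmi_reduction}) must be smaller than "
                f"bmi_pre ({self.bmi_pre})"
            )


def delta_bmi_at_cycle(arm: ArmSpec, schedule: RegainSchedule, cycle: int) -> float:
    """BMI reduction relative to the pre-operative BMI at a given cycle.

    Cycle 1 is the first post-surgical year (full reduction, no regain).
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    if arm.arm == "no_surgery":
        return 0.0
    return arm.bmi_reduction * (1.0 - schedule.cumulative_regain(cycle))


def delta_bmi_series(arm: ArmSpec, schedule: RegainSchedule, horizon: int) -> np.ndarray:
    """BMI reductions for cycles 1..horizon as a float array."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return np.array(
        [delta_bmi_at_cycle(arm, schedule, t) for t in range(1, horizon + 1)], dtype=float
    )
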