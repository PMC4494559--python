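"""Two-arm, two-state (alive/dead) yearly-cycle Markov cohort model.

Accrual conventions
-------------------
Cycle t = 1 is the first post-surgical year (ages ``start_age + t - 1``).
Within cycle t:

* medical-cost savings accrue to the fraction alive at the *start* of the
  cycle, discounted by (1+r)^t;
* utility accrues to the fraction alive at the *end* of the cycle (the dead
  state is absorbing, with zero cost and zero utility), discounted by
  (1+r)^t;
* the reported added-life-year column uses the same discounted end-of-cycle
  survival gap, matching the published accounting (see docs/methods.md);
  the per-cycle ledger also keeps the raw, undiscounted survival.

The one-time intervention cost is incurred at time 0 and never discounted.
The comparator arm accrues zero incremental medical cost by construction:
the model is specified directly in incremental savings per BMI unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mortality import CalibrationError, death_prob, make_gompertz_life_table
from .params import CalibrationTargets, ModelParameters
from .trajectory import ArmSpec, delta_bmi_series

__all__ = [
    "CycleLedger",
    "IncrementalResults",
    "run_arm",
    "incremental_outcomes",
    "base_case_results",
    "icer",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "added_life_years",
    "calibrate_baseline_utility",
    "calibrate_parameters",
    "threshold_crossing_year",
    "results_to_frame",
]

# ICER classification sentinels (returned instead of a misleading ratio).
DOMINANT = "dominant"  # cheaper and more effective
DOMINATED = "dominated"  # costlier and less effective
UNDEFINED = "undefined"  # zero QALY gain


@dataclass(frozen=True)
class CycleLedger:
    """Per-cycle accounting for one arm (arrays indexed by cycle 1..horizon)."""

    arm: str
    cycle: np.ndarray
    age: np.ndarray
    alive_prob_start: np.ndarray
    alive_prob_end: np.ndarray
    delta_bmi: np.ndarray
    savings_t: np.ndarray  # discounted US$
    utility_t: np.ndarray  # discounted QALYs
    life_years_t: np.ndarray  # undiscounted survival at cycle end

    @property
    def horizon(self) -> int:
        return len(self.cycle)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "age": self.age,
                "alive_prob_start": self.alive_prob_start,
                "alive_prob_end": self.alive_prob_end,
                "delta_bmi": self.delta_bmi,
                "savings_t": self.savings_t,
                "utility_t": self.utility_t,
                "life_years_t": self.life_years_t,
            }
        )


def run_arm(params: ModelParameters, arm: ArmSpec, horizon: int) -> CycleLedger:
    """Simulate one cohort arm for `horizon` yearly cycles."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    table = make_gompertz_life_table(
        params.mortality.q0, params.mortality.gompertz_slope, params.start_age
    )
    last_age = params.start_age + horizon - 1
    if last_age > table.max_age:
        raise ValueError(
            f"horizon {horizon} reaches age {last_age}, beyond the life table's "
            f"maximum age {table.max_age}"
        )
    deltas = delta_bmi_series(arm, params.regain, horizon)
    r = params.discount_rate
    cycles = np.arange(1, horizon + 1)
    ages = params.start_age + cycles - 1
    alive_start = np.empty(horizon)
    alive_end = np.empty(horizon)
    savings = np.empty(horizon)
    utility = np.empty(horizon)
    alive = 1.0
    for i, t in enumerate(cycles):
        q = death_prob(table, params.mortality, int(ages[i]), float(deltas[i]))
        disc = (1.0 + r) ** t
        alive_start[i] = alive
        savings[i] = params.savings_per_bmi * deltas[i] * alive / disc
        alive *= 1.0 - q
        alive_end[i] = alive
        utility[i] = (params.u_base + params.hrql_gain_per_bmi * deltas[i]) * alive / disc
    return CycleLedger(
        arm=arm.arm,
        cycle=cycles,
        age=ages,
        alive_prob_start=alive_start,
        alive_prob_end=alive_end,
        delta_bmi=deltas,
        savings_t=savings,
        utility_t=utility,
        life_years_t=alive_end.copy(),
    )


@dataclass(frozen=True)
class IncrementalResults:
    """Incremental outcomes of surgery vs. no surgery at one horizon."""

    horizon: int
    cumulative_savings: float  # discounted US$ (positive = money saved)
    incremental_cost: float  # intervention cost net of savings
    added_life_years: float  # discounted survival gap
    added_qalys: float  # discounted
    wtp: float

    @property
    def nmb(self) -> float:
        """Net monetary benefit at the willingness-to-pay threshold."""
        return self.wtp * self.added_qalys - self.incremental_cost


def icer(inc: IncrementalResults) -> float | str:
    """ICER in US$/QALY, or a dominance flag instead of a misleading ratio."""
    if inc.added_qalys > 0:
        if inc.incremental_cost < 0:
            return DOMINANT
        return inc.incremental_cost / inc.added_qalys
    if inc.added_qalys < 0:
        if inc.incremental_cost > 0:
            return DOMINATED
        return inc.incremental_cost / inc.added_qalys
    return UNDEFINED


def incremental_outcomes(
    surg: CycleLedger,
    ns: CycleLedger,
    params: ModelParameters,
    horizons: Sequence[int],
) -> list[IncrementalResults]:
    """Cumulative incremental outcomes at each requested horizon."""
    if surg.horizon != ns.horizon:
        raise ValueError(
            f"ledger lengths differ: surgery {surg.horizon}, no-surgery {ns.horizon}"
        )
    horizons = list(horizons)
    if not horizons:
        raise ValueError("horizons must be non-empty")
    if max(horizons) > surg.horizon:
        raise ValueError(
            f"requested horizon {max(horizons)} exceeds ledger horizon {surg.horizon}"
        )
    r = params.discount_rate
    disc = (1.0 + r) ** surg.cycle.astype(float)
    savings_diff = np.cumsum(surg.savings_t - ns.savings_t)
    ly_diff = np.cumsum((surg.alive_prob_end - ns.alive_prob_end) / disc)
    qaly_diff = np.cumsum(surg.utility_t - ns.utility_t)
    out = []
    for h in horizons:
        if h < 1:
            raise ValueError(f"horizon must be >= 1, got {h}")
        sav = float(savings_diff[h - 1])
        out.append(
            IncrementalResults(
                horizon=h,
                cumulative_savings=sav,
                incremental_cost=params.intervention_cost - sav,
                added_life_years=float(ly_diff[h - 1]),
                added_qalys=float(qaly_diff[h - 1]),
                wtp=params.wtp_threshold,
            )
        )
    return out


def base_case_results(
    params: ModelParameters, horizons: Sequence[int] = range(1, 8)
) -> list[IncrementalResults]:
    """Run both arms and return incremental outcomes at each horizon."""
    horizons = list(horizons)
    h_max = max(horizons)
    surg = run_arm(params, params.surgery_arm(), h_max)
    ns = run_arm(params, params.no_surgery_arm(), h_max)
    return incremental_outcomes(surg, ns, params, horizons)


def added_life_years(params: ModelParameters, horizon: int) -> float:
    """Discounted added life-years of surgery vs. no surgery at one horizon."""
    return base_case_results(params, [horizon])[0].added_life_years


def results_to_frame(results: Sequence[IncrementalResults]) -> pd.DataFrame:
    """Tabulate incremental results, one row per horizon."""
    rows = []
    for inc in results:
        ratio = icer(inc)
        rows.append(
            {
                "horizon": inc.horizon,
                "medical_cost_savings": -inc.cumulative_savings,  # sign as published
                "incremental_cost": inc.incremental_cost,
                "added_life_years": inc.added_life_years,
                "added_qalys": inc.added_qalys,
                "cost_per_qaly": ratio if isinstance(ratio, float) else math.nan,
                "icer_status": ratio if isinstance(ratio, str) else "ratio",
                "nmb_at_wtp": inc.nmb,
            }
        )
    return pd.DataFrame(rows)


def calibrate_baseline_utility(
    params: ModelParameters,
    qaly_target_y1: float,
    *,
    boundary_tol: float = 5e-4,
) -> float:
    """Baseline utility u_base such that year-1 added QALYs hit the target.

    Year-1 added QALYs are affine and strictly increasing in u_base (slope =
    discounted survival gap), so the root is solved exactly.  If the root
    falls above the admissible ceiling u_base = 1 by less than
    ``boundary_tol`` in target units — i.e. within the resolution at which
    the target is reported — the ceiling is returned; otherwise a
    :class:`CalibrationError` reports the residuals at both endpoints.
    """
    if qaly_target_y1 <= 0:
        raise CalibrationError(f"target must be positive, got {qaly_target_y1}")

    def qaly_y1(u: float) -> float:
        p = params.replace(u_base=u)
        return base_case_results(p, [1])[0].added_qalys

    eps = 1e-12
    f_lo, f_hi = qaly_y1(eps), qaly_y1(1.0)
    slope = f_hi - f_lo  # affine in u_base
    if slope <= 0:
        raise CalibrationError(
            "year-1 added QALYs do not depend on u_base (no survival gap); "
            f"residuals: f(0)-target={f_lo - qaly_target_y1:.6g}, "
            f"f(1)-target={f_hi - qaly_target_y1:.6g}"
        )
    u = eps + (qaly_target_y1 - f_lo) / slope * (1.0 - eps)
    if eps <= u <= 1.0:
        return float(u)
    if u > 1.0 and qaly_target_y1 - f_hi <= boundary_tol:
        return 1.0
    raise CalibrationError(
        f"no root for u_base in (0, 1]: residuals f(0+)-target={f_lo - qaly_target_y1:.6g}, "
        f"f(1)-target={f_hi - qaly_target_y1:.6g}"
    )


def calibrate_parameters(
    params: ModelParameters | None = None,
    targets: CalibrationTargets | None = None,
) -> ModelParameters:
    """Calibrate the mortality link and baseline utility to published outputs.

    Returns a new parameter set with (g, beta) matching the year-1/year-7
    added-life-year targets and u_base matching the year-1 added-QALY target.
    """
    from .mortality import calibrate_mortality

    params = params or ModelParameters()
    targets = targets or CalibrationTargets()
    mort = calibrate_mortality(
        params, targets.added_life_years_y1, targets.added_life_years_y7
    )
    params = params.with_mortality(mort)
    u = calibrate_baseline_utility(params, targets.added_qalys_y1)
    return params.replace(u_base=u)


def threshold_crossing_year(
    results: Sequence[IncrementalResults], wtp: float
) -> int | None:
    """Smallest horizon at which surgery is cost-effective at `wtp`.

    Cost-effective means a positive QALY gain with ICER <= wtp (equivalently
    NMB >= 0), including dominance.  Returns None if no horizon qualifies.
    """
    for inc in sorted(results, key=lambda x: x.horizon):
        if inc.added_qalys > 0 and wtp * inc.added_qalys - inc.incremental_cost >= 0:
            return inc.horizon
    return None
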