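"""Probabilistic and one-way sensitivity analysis.

The PSA propagates parameter uncertainty by parametric Monte-Carlo: each
replicate draws the four uncertain inputs independently from
moment-matched gamma distributions (intervention cost, annual savings per
BMI unit, BMI reduction) and a beta distribution (HRQL gain per BMI unit),
re-runs the deterministic cohort model, and records incremental outcomes per
horizon.  The mortality calibration and baseline utility are held fixed at
their calibrated values.

Cohort-derived quantities (intervention cost, BMI reduction) are sampled at
the uncertainty of their *means* — SD/sqrt(n) for the n-patient cohort —
while the savings and HRQL slopes use their regression standard errors as
published.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import base_case_results, threshold_crossing_year
from .params import ModelParameters
from .trajectory import RegainSchedule

__all__ = [
    "ParameterDistributions",
    "PSAResult",
    "gamma_from_moments",
    "beta_from_moments",
    "run_psa",
    "ceac",
    "percentile_interval",
    "one_way",
    "ONE_WAY_PARAMETERS",
    "default_wtp_grid",
]


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the requested mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError(f"mean and sd must be positive, got ({mean}, {sd})")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the requested mean and SD."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if sd <= 0 or sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"sd^2 must be in (0, mean*(1-mean)) = (0, {mean * (1 - mean):.6g}), got sd={sd}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class ParameterDistributions:
    """(mean, sd) pairs for the four sampled inputs."""

    intervention_cost: tuple[float, float]
    savings_per_bmi: tuple[float, float]
    bmi_reduction: tuple[float, float]
    hrql_gain_per_bmi: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("intervention_cost", "savings_per_bmi", "bmi_reduction"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd <= 0:
                raise ValueError(f"{name}: mean and sd must be positive, got ({mean}, {sd})")
        mean, sd = self.hrql_gain_per_bmi
        if not 0.0 < mean < 1.0 or sd <= 0:
            raise ValueError(f"hrql_gain_per_bmi: need 0 < mean < 1 and sd > 0")

    @classmethod
    def from_parameters(cls, params: ModelParameters) -> "ParameterDistributions":
        """Base-case uncertainty distributions.

        The intervention-cost and weight-loss SDs are patient-level spreads
        across the surgical cohort, so the corresponding parameter (a cohort
        mean) is sampled at SD/sqrt(n_patients).  Weight-loss uncertainty is
        mapped to BMI units by scaling with bmi_reduction/weight_loss_kg.
        """
        root_n = math.sqrt(params.n_patients)
        bmi_sd = (
            params.bmi_reduction * (params.weight_loss_kg_sd / params.weight_loss_kg) / root_n
        )
        return cls(
            intervention_cost=(
                params.cost_params.intervention_cost,
                params.cost_params.intervention_cost_sd / root_n,
            ),
            savings_per_bmi=(params.savings_per_bmi, params.savings_per_bmi_se),
            bmi_reduction=(params.bmi_reduction, bmi_sd),
            hrql_gain_per_bmi=(params.hrql_gain_per_bmi, params.hrql_gain_per_bmi_se),
        )


@dataclass(frozen=True)
class PSAResult:
    """Replicate draws and per-replicate incremental outcomes."""

    seed: int
    horizons: tuple[int, ...]
    draws: pd.DataFrame  # n rows x 4 sampled parameters
    incremental_cost: np.ndarray  # (n, len(horizons))
    added_qalys: np.ndarray  # (n, len(horizons))
    n_rejected: int

    @property
    def n_replicates(self) -> int:
        return len(self.draws)

    def _h_index(self, horizon: int) -> int:
        try:
            return self.horizons.index(horizon)
        except ValueError:
            raise ValueError(f"horizon {horizon} not in result horizons {self.horizons}")

    def icers(self, horizon: int) -> np.ndarray:
        """Per-replicate ICERs at `horizon` (NaN where the QALY gain is <= 0)."""
        j = self._h_index(horizon)
        q = self.added_qalys[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(q > 0, self.incremental_cost[:, j] / q, np.nan)
        return out

    def outcomes_frame(self) -> pd.DataFrame:
        """Long-format per-replicate outcomes (replicate, horizon, cost, QALYs)."""
        n, m = self.incremental_cost.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(n), m),
                "horizon": np.tile(self.horizons, n),
                "incremental_cost": self.incremental_cost.ravel(),
                "added_qalys": self.added_qalys.ravel(),
            }
        )


def default_wtp_grid() -> np.ndarray:
    """$0-$200,000 in $5,000 steps."""
    return np.arange(0, 200_001, 5_000, dtype=float)


def run_psa(
    params: ModelParameters,
    dists: ParameterDistributions | None = None,
    n: int = 1000,
    seed: int = 0,
    horizons: Sequence[int] = range(1, 8),
    max_rejections: int = 100_000,
) -> PSAResult:
    """Monte-Carlo parameter uncertainty analysis with `n` replicates.

    Draws are independent across parameters; any draw with an infeasible
    BMI reduction (>= pre-operative BMI) is rejected and redrawn, and the
    rejection count is recorded on the result.  Reproducible for fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    dists = dists or ParameterDistributions.from_parameters(params)
    horizons = tuple(int(h) for h in horizons)
    rng = np.random.default_rng(seed)
    shp_c, scl_c = gamma_from_moments(*dists.intervention_cost)
    shp_s, scl_s = gamma_from_moments(*dists.savings_per_bmi)
    shp_b, scl_b = gamma_from_moments(*dists.bmi_reduction)
    a_h, b_h = beta_from_moments(*dists.hrql_gain_per_bmi)

    rows = np.empty((n, 4))
    inc_cost = np.empty((n, len(horizons)))
    qalys = np.empty((n, len(horizons)))
    n_rejected = 0
    for i in range(n):
        while True:
            draw = (
                rng.gamma(shp_c, scl_c),
                rng.gamma(shp_s, scl_s),
                rng.gamma(shp_b, scl_b),
                rng.beta(a_h, b_h),
            )
            if 0.0 < draw[2] < params.bmi_pre:
                break
            n_rejected += 1
            if n_rejected > max_rejections:
                raise RuntimeError("too many infeasible draws; check distributions")
        rows[i] = draw
        p_i = params.replace(
            cost_params=dataclasses.replace(
                params.cost_params,
                total_charges=draw[0] / params.cost_params.cost_to_charge_ratio,
                intervention_cost=draw[0],
            ),
            savings_per_bmi=draw[1],
            bmi_reduction=draw[2],
            hrql_gain_per_bmi=draw[3],
        )
        for j, inc in enumerate(base_case_results(p_i, horizons)):
            inc_cost[i, j] = inc.incremental_cost
            qalys[i, j] = inc.added_qalys
    draws = pd.DataFrame(
        rows,
        columns=["intervention_cost", "savings_per_bmi", "bmi_reduction", "hrql_gain_per_bmi"],
    )
    return PSAResult(
        seed=seed,
        horizons=horizons,
        draws=draws,
        incremental_cost=inc_cost,
        added_qalys=qalys,
        n_rejected=n_rejected,
    )


def ceac(
    result: PSAResult, horizon: int, wtp_grid: Sequence[float] | np.ndarray
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve at one horizon.

    For each willingness-to-pay value, the probability is the fraction of
    replicates with non-negative net monetary benefit.  Non-decreasing in WTP.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    j = result._h_index(horizon)
    cost = result.incremental_cost[:, j]
    q = result.added_qalys[:, j]
    nmb = wtp_grid[:, None] * q[None, :] - cost[None, :]
    prob = (nmb >= 0).mean(axis=1)
    return pd.DataFrame({"horizon": horizon, "wtp": wtp_grid, "probability": prob})


def percentile_interval(
    result: PSAResult, horizon: int, level: float = 0.95
) -> tuple[float, float]:
    """Percentile interval of the per-replicate ICER distribution.

    Replicates with non-positive QALY gain are excluded (they have no
    meaningful ratio; they still enter the CEAC through NMB).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    icers = result.icers(horizon)
    valid = icers[~np.isnan(icers)]
    if valid.size < 40:
        raise ValueError(
            f"only {valid.size} replicates with positive QALY gain; "
            "percentiles are unstable below 40"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(valid, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


ONE_WAY_PARAMETERS = (
    "hrql_gain_per_bmi",
    "intervention_cost",
    "savings_per_bmi",
    "discount_rate",
    "regain_annual_fraction",
)

# Regain accrues for five years post-surgery; sweeping the annual fraction
# scales the plateau accordingly (base case: 5 x 0.05 = 0.25) so that 20%/yr
# means complete regain after year five.
_REGAIN_YEARS = 5


def _with_value(params: ModelParameters, name: str, value: float) -> ModelParameters:
    if name == "intervention_cost":
        return params.replace(
            cost_params=dataclasses.replace(
                params.cost_params,
                total_charges=value / params.cost_params.cost_to_charge_ratio,
                intervention_cost=value,
            )
        )
    if name == "regain_annual_fraction":
        return params.replace(
            regain=RegainSchedule(
                annual_fraction=value,
                first_regain_cycle=params.regain.first_regain_cycle,
                plateau_fraction=min(1.0, _REGAIN_YEARS * value),
            )
        )
    return params.replace(**{name: value})


def one_way(
    params: ModelParameters,
    name: str,
    values: Sequence[float],
    horizon: int,
) -> pd.DataFrame:
    """Deterministic one-way sweep: ICER at `horizon` for each value of `name`.

    All other inputs, including the calibrated mortality link and baseline
    utility, stay at their base-case values.  Also reports the first year at
    which surgery is cost-effective at the model's WTP threshold (NaN if it
    never is within `horizon` years).
    """
    if name not in ONE_WAY_PARAMETERS:
        raise ValueError(f"unknown parameter {name!r}; valid names: {list(ONE_WAY_PARAMETERS)}")
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    rows = []
    for value in values:
        p = _with_value(params, name, float(value))
        results = base_case_results(p, range(1, horizon + 1))
        inc = results[-1]
        ratio = inc.incremental_cost / inc.added_qalys if inc.added_qalys > 0 else math.nan
        crossing = threshold_crossing_year(results, p.wtp_threshold)
        rows.append(
            {
                "parameter": name,
                "value": value,
                "horizon": horizon,
                "incremental_cost": inc.incremental_cost,
                "added_qalys": inc.added_qalys,
                "icer": ratio,
                "crossing_year": math.nan if crossing is None else crossing,
            }
        )
    return pd.DataFrame(rows)
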