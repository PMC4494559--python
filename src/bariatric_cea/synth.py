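"""Synthetic stand-ins for the study's three data sources.

* an adolescent surgical cohort (anthropometrics + per-category billing
  charges) matching the published means/SDs;
* a MEPS-like cross-sectional survey of severely obese respondents
  (BMI >= 34) relating an EQ-5D-style utility and annual medical
  expenditure to BMI, with known generating slopes;
* a parametric life table (see :mod:`bariatric_cea.mortality`).

Everything is deterministic for a fixed seed.  BMI is derived from the
generated weight and height rather than drawn independently, so the
weight-height-BMI triangle is internally consistent (at the cost of not
exactly matching the published BMI SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import truncnorm

from .params import ChargeLine, bundled_charge_lines

__all__ = [
    "PatientRecord",
    "SurveyRecord",
    "SlopeEstimates",
    "CohortMoments",
    "gen_cohort",
    "summarize_cohort",
    "cohort_to_frame",
    "gen_survey",
    "survey_to_frame",
    "recover_slopes",
]


@dataclass(frozen=True)
class CohortMoments:
    """Published marginal moments of the surgical cohort."""

    p_female: float = 10 / 11
    age_mean: float = 17.3
    age_sd: float = 1.7
    age_range: tuple[float, float] = (14.0, 20.0)
    height_cm_mean: float = 169.3
    height_cm_sd: float = 8.8
    weight_kg_mean: float = 138.2
    weight_kg_sd: float = 16.9
    weight_loss_kg_mean: float = 37.5
    weight_loss_kg_sd: float = 13.5


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic surgical patient."""

    id: int
    sex: str  # "F" / "M"
    age_at_surgery: float
    height_cm: float
    weight_kg: float
    bmi_pre: float
    weight_loss_12m_kg: float
    charges: dict[str, float] = field(default_factory=dict)

    @property
    def bmi_post(self) -> float:
        """12-month post-surgical BMI from weight, loss and height."""
        return (self.weight_kg - self.weight_loss_12m_kg) / (self.height_cm / 100.0) ** 2

    @property
    def total_charges(self) -> float:
        return sum(self.charges.values())


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_cohort(
    n: int,
    seed: int,
    moments: CohortMoments | None = None,
    charge_lines: Sequence[ChargeLine] | None = None,
) -> list[PatientRecord]:
    """Generate `n` synthetic surgical patients.

    Anthropometrics are truncated normals at the published moments; billing
    charges are one non-negative truncated-normal value per charge line.
    Weight loss is truncated to (0, weight) record by record so losses are
    always physically possible.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    m = moments or CohortMoments()
    lines = list(charge_lines) if charge_lines is not None else bundled_charge_lines()
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    female = rng.random(n) < m.p_female
    age = _truncated_normal(rng, m.age_mean, m.age_sd, *m.age_range, size=n)
    height = _truncated_normal(rng, m.height_cm_mean, m.height_cm_sd, 120.0, 220.0, size=n)
    weight = _truncated_normal(rng, m.weight_kg_mean, m.weight_kg_sd, 40.0, np.inf, size=n)
    records = []
    for i in range(n):
        loss = float(
            _truncated_normal(
                rng, m.weight_loss_kg_mean, m.weight_loss_kg_sd, 0.0, weight[i], size=1
            )[0]
        )
        charges = {
            f"{line.phase}:{line.category}": (
                float(
                    _truncated_normal(
                        rng, line.mean_charge, line.sd_charge, 0.0, np.inf, size=1
                    )[0]
                )
                if line.sd_charge > 0
                else line.mean_charge
            )
            for line in lines
        }
        h_m = height[i] / 100.0
        records.append(
            PatientRecord(
                id=i,
                sex="F" if female[i] else "M",
                age_at_surgery=float(age[i]),
                height_cm=float(height[i]),
                weight_kg=float(weight[i]),
                bmi_pre=float(weight[i] / h_m**2),
                weight_loss_12m_kg=loss,
                charges=charges,
            )
        )
    return records


_COHORT_BASE_COLUMNS = [
    "id",
    "sex",
    "age_at_surgery",
    "height_cm",
    "weight_kg",
    "bmi_pre",
    "weight_loss_12m_kg",
    "bmi_post",
]


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a flat table, one charge column per billing line."""
    if not records:
        return pd.DataFrame(columns=_COHORT_BASE_COLUMNS)
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "sex": rec.sex,
            "age_at_surgery": rec.age_at_surgery,
            "height_cm": rec.height_cm,
            "weight_kg": rec.weight_kg,
            "bmi_pre": rec.bmi_pre,
            "weight_loss_12m_kg": rec.weight_loss_12m_kg,
            "bmi_post": rec.bmi_post,
        }
        row.update({f"charge:{k}": v for k, v in rec.charges.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort summary: count, mean, SD, median, min, max per numeric field.

    Mirrors the published descriptive table, reporting both mean/SD and
    median/range forms, plus derived post-surgical BMI and total charges.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    frame = cohort_to_frame(records)
    fields = [
        "age_at_surgery",
        "height_cm",
        "weight_kg",
        "bmi_pre",
        "weight_loss_12m_kg",
        "bmi_post",
    ]
    frame["total_charges"] = [rec.total_charges for rec in records]
    fields.append("total_charges")
    rows = []
    for name in fields:
        col = frame[name]
        rows.append(
            {
                "variable": name,
                "n": int(col.count()),
                "mean": col.mean(),
                "sd": col.std(ddof=1) if len(col) > 1 else 0.0,
                "median": col.median(),
                "min": col.min(),
                "max": col.max(),
            }
        )
    rows.append(
        {
            "variable": "female_fraction",
            "n": len(records),
            "mean": sum(rec.sex == "F" for rec in records) / len(records),
            "sd": np.nan,
            "median": np.nan,
            "min": np.nan,
            "max": np.nan,
        }
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SurveyRecord:
    """One synthetic survey respondent (severe obesity, BMI >= 34)."""

    id: int
    age: float
    sex: str
    bmi: float
    hrql: float
    annual_expenditure: float


@dataclass(frozen=True)
class SlopeEstimates:
    """OLS slopes per unit of BMI *reduction* (positive = gain from reduction)."""

    hrql_per_bmi: float
    hrql_per_bmi_se: float
    cost_per_bmi: float
    cost_per_bmi_se: float


# Generator anchors for the survey (not published; chosen as plausible for a
# severely obese US adult subgroup and documented in docs/methods.md).
_HRQL_AT_BMI34 = 0.75
_EXPENDITURE_AT_BMI34 = 2500.0
_HRQL_AGE_SLOPE = -0.002  # per year of age, centred at 45
_COST_AGE_SLOPE = 30.0
_HRQL_SEX_SHIFT = 0.01  # female minus male
_COST_SEX_SHIFT = 150.0
_EXPENDITURE_GAMMA_SHAPE = 2.0  # right-skewed expenditures with linear mean


def gen_survey(
    n: int,
    seed: int,
    slope_hrql: float = 0.0042,
    slope_cost: float = 157.0,
    noise_sds: tuple[float, float | None] = (0.08, None),
    bmi_sd: float = 5.0,
) -> list[SurveyRecord]:
    """Generate a MEPS-like survey restricted to BMI >= 34.

    hrql falls by `slope_hrql` and expenditure rises by `slope_cost` per BMI
    unit above 34, with age and sex covariate effects.  ``noise_sds`` holds
    (hrql additive noise SD, expenditure noise SD); an expenditure noise of
    ``None`` (the default) draws expenditures from a gamma distribution
    around the linear mean — right-skewed and non-negative, with the mean
    exactly linear so slope recovery stays unbiased.  With both noise terms
    zero the generated fields are exactly linear in BMI.  BMI itself is
    right-skewed (gamma) and truncated at 34.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    shape = 2.0
    if bmi_sd > 0:
        bmi = 34.0 + rng.gamma(shape, bmi_sd / np.sqrt(shape), size=n)
    else:
        bmi = np.full(n, 34.0)
    age = rng.uniform(18.0, 70.0, size=n)
    female = rng.random(n) < 0.5
    hrql_noise_sd, cost_noise_sd = noise_sds
    hrql_mean = (
        _HRQL_AT_BMI34
        - slope_hrql * (bmi - 34.0)
        + _HRQL_AGE_SLOPE * (age - 45.0)
        + _HRQL_SEX_SHIFT * female
    )
    hrql = hrql_mean + (rng.normal(0.0, hrql_noise_sd, size=n) if hrql_noise_sd > 0 else 0.0)
    hrql = np.clip(hrql, 0.0, 1.0)
    exp_mean = np.maximum(
        _EXPENDITURE_AT_BMI34
        + slope_cost * (bmi - 34.0)
        + _COST_AGE_SLOPE * (age - 45.0)
        + _COST_SEX_SHIFT * female,
        1.0,
    )
    if cost_noise_sd is None:
        k = _EXPENDITURE_GAMMA_SHAPE
        expenditure = rng.gamma(k, exp_mean / k, size=n)
    elif cost_noise_sd > 0:
        expenditure = np.clip(exp_mean + rng.normal(0.0, cost_noise_sd, size=n), 0.0, None)
    else:
        expenditure = exp_mean
    return [
        SurveyRecord(
            id=i,
            age=float(age[i]),
            sex="F" if female[i] else "M",
            bmi=float(bmi[i]),
            hrql=float(hrql[i]),
            annual_expenditure=float(expenditure[i]),
        )
        for i in range(n)
    ]


def survey_to_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "bmi": [r.bmi for r in records],
            "hrql": [r.hrql for r in records],
            "annual_expenditure": [r.annual_expenditure for r in records],
        }
    )


def recover_slopes(survey: Sequence[SurveyRecord]) -> SlopeEstimates:
    """Age- and sex-adjusted OLS slopes of HRQL and expenditure on BMI.

    Sign convention: returns the gain per unit of BMI *reduction* as a
    positive number (HRQL rises, expenditure falls, when BMI falls).
    """
    if len(survey) < 3:
        raise ValueError(f"need at least 3 records, got {len(survey)}")
    frame = survey_to_frame(survey)
    if frame["bmi"].var(ddof=1) == 0:
        raise ValueError("BMI has zero variance; slope is unidentifiable")
    design = sm.add_constant(
        pd.DataFrame(
            {
                "bmi": frame["bmi"],
                "age": frame["age"],
                "female": (frame["sex"] == "F").astype(float),
            }
        )
    )
    fit_hrql = sm.OLS(frame["hrql"], design).fit()
    fit_cost = sm.OLS(frame["annual_expenditure"], design).fit()
    return SlopeEstimates(
        hrql_per_bmi=-float(fit_hrql.params["bmi"]),
        hrql_per_bmi_se=float(fit_hrql.bse["bmi"]),
        cost_per_bmi=float(fit_cost.params["bmi"]),
        cost_per_bmi_se=float(fit_cost.bse["bmi"]),
    )
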