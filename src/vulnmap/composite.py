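"""Layered physical/financial vulnerability inside selected areas.

Residents of the selected (vulnerable) areas are flagged along two 2-of-3
rules:

* **physical** — at least two of: high blood pressure, age >= 45 years,
  body-mass index above 26.93 kg/m²;
* **financial** — at least two of: difficulty paying rent *or* buying food
  (any frequency above "never"; the two hardships count as one combined
  indicator), household income below 200% of the Federal Poverty Level, and
  participation in at least one public assistance program.

Missing components count as absent (conservative: fewer respondents are
flagged).  The survey-weighted cross-tabulation of the two flags yields the
four-group vulnerability spectrum (both, physical only, financial only,
neither).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SurveyTable

__all__ = ["SpectrumTable", "physical_flag", "financial_flag", "spectrum"]

#: body-mass index cut inherited from the tree models (strict inequality)
BMI_CUT = 26.93
AGE_CUT = 45.0
#: Federal Poverty Level categories counting as "below 200%"
LOW_FPL = ("<100%", "100-199.9%")
#: hardship frequencies above "never"
HARDSHIP = ("Rarely/sometimes", "Often")


def physical_flag(df: pd.DataFrame) -> np.ndarray:
    """2-of-3 physical vulnerability per respondent row."""
    hbp = (df["high_blood_pressure"] == "Yes").to_numpy()
    age = df["age"].to_numpy(dtype=float)
    age45 = np.where(np.isnan(age), False, age >= AGE_CUT)
    bmi = df["bmi"].to_numpy(dtype=float)
    high_bmi = np.where(np.isnan(bmi), False, bmi > BMI_CUT)
    return (hbp.astype(int) + age45.astype(int) + high_bmi.astype(int)) >= 2


def financial_flag(df: pd.DataFrame) -> np.ndarray:
    """2-of-3 financial vulnerability per respondent row."""
    rent = df["difficulty_paying_rent"].isin(HARDSHIP).to_numpy()
    food = df["difficulty_buying_food"].isin(HARDSHIP).to_numpy()
    hardship = rent | food  # one combined rent-or-food indicator
    low_fpl = df["fpl_category"].isin(LOW_FPL).to_numpy()
    assistance = (df["public_programs"] == "1+").to_numpy()
    return (hardship.astype(int) + low_fpl.astype(int) + assistance.astype(int)) >= 2


@dataclass
class SpectrumTable:
    """Four-group weighted vulnerability spectrum of selected-area residents."""

    proportions: dict[str, float]  # both / physical_only / financial_only / neither
    flags: pd.DataFrame  # respondent_id, physical, financial
    selected_areas: tuple[str, ...]

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions)


def spectrum(table: SurveyTable, selected_areas: list[str] | tuple[str, ...]) -> SpectrumTable:
    """Survey-weighted cross-tabulation of the two flags in selected areas."""
    if not selected_areas:
        raise ValueError("selected area set is empty")
    df = table.data.loc[table.data["area"].isin(list(selected_areas))]
    if df.empty:
        raise ValueError("no respondents live in the selected areas")
    phys = physical_flag(df)
    fin = financial_flag(df)
    w = df["weight"].to_numpy(dtype=float)
    total = w.sum()
    props = {
        "both": float(w[phys & fin].sum() / total),
        "physical_only": float(w[phys & ~fin].sum() / total),
        "financial_only": float(w[~phys & fin].sum() / total),
        "neither": float(w[~phys & ~fin].sum() / total),
    }
    flags = pd.DataFrame(
        {
            "respondent_id": df["respondent_id"].to_numpy(),
            "physical": phys,
            "financial": fin,
        }
    )
    return SpectrumTable(props, flags, tuple(selected_areas))
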