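"""Survey schema, table container, and survey-weighted statistics primitives.

Respondent-level microdata are held in a :class:`SurveyTable`: one row per
adult respondent carrying a positive survey weight (population expansion
factor), an opaque area code, a type-2-diabetes diagnosis flag, and a set of
schema-declared indicator values.  Indicators are nominal, ordinal, or
continuous; ordinal variables carry their category order in the schema but no
numeric scores are ever imputed to categories — every downstream stage treats
them nonmetrically.

The missing-data convention is a dedicated sentinel token (``"NA"``) in files;
missingness is never a category.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: sentinel for missing values in delimited files and in-memory object columns
MISSING = "NA"

#: reserved structural column names (not schema variables)
STRUCTURAL_COLUMNS = ("respondent_id", "weight", "area", "diabetes")

VALID_SCALES = ("nominal", "ordinal", "continuous")


class SchemaError(ValueError):
    """Raised when a file or table does not conform to the declared schema."""


class ValidationError(ValueError):
    """Raised when record-level invariants are violated (names the row)."""


@dataclass(frozen=True)
class Variable:
    """A single survey indicator.

    Parameters
    ----------
    name:
        Unique identifier, used as the column name.
    scale:
        ``"nominal"``, ``"ordinal"`` (categories carry an order), or
        ``"continuous"``.
    categories:
        Ordered category labels for non-continuous variables; ``None`` for
        continuous variables.
    """

    name: str
    scale: str
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise SchemaError(f"variable {self.name!r}: unknown scale {self.scale!r}")
        if self.scale == "continuous":
            if self.categories is not None:
                raise SchemaError(f"continuous variable {self.name!r} must not list categories")
        else:
            if not self.categories or len(self.categories) < 2:
                raise SchemaError(f"variable {self.name!r} needs >=2 categories")
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"variable {self.name!r} has duplicate categories")
            if MISSING in self.categories:
                raise SchemaError(f"variable {self.name!r}: {MISSING!r} is reserved for missing")

    @property
    def is_categorical(self) -> bool:
        return self.scale != "continuous"


@dataclass(frozen=True)
class IndicatorSchema:
    """Ordered collection of survey variables."""

    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("variable names must be unique")
        clash = set(names) & set(STRUCTURAL_COLUMNS)
        if clash:
            raise SchemaError(f"variable names clash with structural columns: {sorted(clash)}")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def categorical_names(self) -> list[str]:
        return [v.name for v in self.variables if v.is_categorical]

    def subset(self, names: Sequence[str]) -> "IndicatorSchema":
        return IndicatorSchema(tuple(self[n] for n in names))


# --------------------------------------------------------------------------
# default schema: 35 candidate socioeconomic/behavioral indicators plus the
# biometric variables and structural fields used by the later stages.
# --------------------------------------------------------------------------

#: the 11 indicators that define the diabetic cluster profiles in the
#: reference analysis (also the generator's planted informative set)
PROFILE_INDICATORS = [
    "health_insurance",
    "age_group",
    "public_programs",
    "employment",
    "fpl_category",
    "difficulty_buying_food",
    "days_poor_health",
    "race_ethnicity",
    "general_health",
    "social_support",
    "physical_activity",
]

AGE_BINS = ("20-44", "45-54", "55-64", "65+")


def _age_bin(age: float) -> str:
    if age < 45:
        return "20-44"
    if age < 55:
        return "45-54"
    if age < 65:
        return "55-64"
    return "65+"


def default_schema() -> IndicatorSchema:
    """The default survey schema: 35 candidate indicators, biometrics.

    The candidate list holds the socioeconomic and behavioral screening
    indicators; ``high_blood_pressure``, ``bmi`` and ``age`` are the biometric
    predictors used by the tree models and the physical-vulnerability layer.
    """
    v = []
    # -- profile indicators (informative set in the reference analysis)
    v.append(Variable("health_insurance", "nominal", ("Private", "Public", "None")))
    v.append(Variable("age_group", "ordinal", AGE_BINS))
    v.append(Variable("public_programs", "nominal", ("None", "1+")))
    v.append(Variable("employment", "nominal", ("Employed", "Unemployed")))
    v.append(Variable("fpl_category", "ordinal", ("<100%", "100-199.9%", "200-399.9%", ">=400%")))
    v.append(Variable("difficulty_buying_food", "ordinal", ("Never", "Rarely/sometimes", "Often")))
    v.append(Variable("days_poor_health", "ordinal", ("0", "1-7", "8+")))
    v.append(Variable("race_ethnicity", "nominal", ("White NH", "Black NH", "Hispanic", "Other NH")))
    v.append(Variable("general_health", "ordinal", ("Excellent/very good", "Good", "Fair/poor")))
    v.append(Variable("social_support", "ordinal", ("Low", "Medium", "High")))
    v.append(Variable("physical_activity", "ordinal", ("Inactive", "Somewhat active", "Active/highly active")))
    # -- remaining candidate indicators
    v.append(Variable("sex", "nominal", ("Female", "Male")))
    v.append(Variable("education", "ordinal", ("Less than HS", "HS diploma", "Some college", "College degree+")))
    v.append(Variable("marital_status", "nominal", ("Married", "Never married", "Divorced/separated", "Widowed")))
    v.append(Variable("household_size", "ordinal", ("1", "2", "3-4", "5+")))
    v.append(Variable("housing_tenure", "nominal", ("Own", "Rent", "Other")))
    v.append(Variable("difficulty_paying_rent", "ordinal", ("Never", "Rarely/sometimes", "Often")))
    v.append(Variable("smoking_status", "nominal", ("Never", "Former", "Current")))
    v.append(Variable("alcohol_use", "ordinal", ("None", "Moderate", "Heavy")))
    v.append(Variable("internet_access", "nominal", ("Yes", "No")))
    v.append(Variable("vehicle_access", "nominal", ("Yes", "No")))
    v.append(Variable("language_at_home", "nominal", ("English", "Spanish", "Other")))
    v.append(Variable("nativity", "nominal", ("US born", "Foreign born")))
    v.append(Variable("years_in_neighborhood", "ordinal", ("<2", "2-5", "6-10", ">10")))
    v.append(Variable("commute_mode", "nominal", ("Car", "Transit", "Other")))
    v.append(Variable("work_hours", "ordinal", ("None", "Part time", "Full time", "Overtime")))
    v.append(Variable("religious_attendance", "ordinal", ("Never", "Occasional", "Weekly")))
    v.append(Variable("volunteer_activity", "nominal", ("Yes", "No")))
    v.append(Variable("neighborhood_safety", "ordinal", ("Low", "Medium", "High")))
    v.append(Variable("park_access", "nominal", ("Yes", "No")))
    v.append(Variable("grocery_access", "nominal", ("Yes", "No")))
    v.append(Variable("dental_visit", "nominal", ("Yes", "No")))
    v.append(Variable("flu_shot", "nominal", ("Yes", "No")))
    v.append(Variable("sleep_hours", "ordinal", ("<6", "6-8", ">8")))
    v.append(Variable("fast_food_frequency", "ordinal", ("Rarely", "Weekly", "Daily")))
    # -- biometrics
    v.append(Variable("high_blood_pressure", "nominal", ("No", "Yes")))
    v.append(Variable("bmi", "continuous"))
    v.append(Variable("age", "continuous"))
    return IndicatorSchema(tuple(v))


def candidate_indicators(schema: IndicatorSchema) -> list[str]:
    """The 35 candidate clustering indicators (everything but biometrics)."""
    biometric = {"high_blood_pressure", "bmi", "age"}
    return [n for n in schema.names if n not in biometric]


# --------------------------------------------------------------------------
# table container
# --------------------------------------------------------------------------


@dataclass
class SurveyTable:
    """Validated respondent-level survey microdata.

    ``data`` holds one row per respondent with the structural columns
    ``respondent_id`` (str), ``weight`` (positive float), ``area`` (str),
    ``diabetes`` (bool) followed by one column per schema variable.
    Categorical columns are object dtype with ``None`` for missing;
    continuous columns are float with ``NaN`` for missing.
    """

    schema: IndicatorSchema
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in STRUCTURAL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing structural column {col!r}")
        for name in self.schema.names:
            if name not in df.columns:
                raise SchemaError(f"missing variable column {name!r}")
        if df["respondent_id"].duplicated().any():
            dup = df.loc[df["respondent_id"].duplicated(), "respondent_id"].iloc[0]
            raise ValidationError(f"duplicate respondent_id {dup!r}")
        bad_w = ~(df["weight"] > 0)
        if bad_w.any():
            row = int(np.flatnonzero(bad_w.to_numpy())[0])
            raise ValidationError(f"non-positive weight in row {row + 1}")
        for var in self.schema.variables:
            if not var.is_categorical:
                continue
            col = df[var.name]
            ok = col.isna() | col.isin(var.categories)
            if not ok.all():
                row = int(np.flatnonzero(~ok.to_numpy())[0])
                val = col.iloc[row]
                raise ValidationError(
                    f"unknown category {val!r} for variable {var.name!r} in row {row + 1}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    @property
    def population_size(self) -> float:
        """Represented population size: the sum of survey weights."""
        return float(self.weights.sum())

    @property
    def areas(self) -> list[str]:
        return sorted(self.data["area"].unique())

    def diabetic(self) -> pd.DataFrame:
        return self.data.loc[self.data["diabetes"]]

    def undiagnosed(self) -> pd.DataFrame:
        return self.data.loc[~self.data["diabetes"]]


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


def _parse_diabetes(raw: pd.Series) -> pd.Series:
    low = raw.astype(str).str.strip().str.lower()
    ok = low.isin(_TRUE_TOKENS | _FALSE_TOKENS)
    if not ok.all():
        row = int(np.flatnonzero(~ok.to_numpy())[0])
        raise ValidationError(f"unparseable diabetes flag {raw.iloc[row]!r} in row {row + 1}")
    return low.isin(_TRUE_TOKENS)


def read_survey(path: str | Path | io.TextIOBase, schema: IndicatorSchema) -> SurveyTable:
    """Read a UTF-8 CSV survey file against a schema.

    Expected columns: ``respondent_id, weight, area, diabetes`` then one
    column per schema variable.  The token ``"NA"`` denotes missing.  Rows
    violating category membership or the positive-weight invariant are
    rejected with a row-numbered error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = list(STRUCTURAL_COLUMNS) + schema.names
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    out = pd.DataFrame(index=df.index)
    out["respondent_id"] = df["respondent_id"].astype(str)
    try:
        out["weight"] = df["weight"].astype(float)
    except ValueError as exc:
        raise ValidationError(f"unparseable weight: {exc}") from exc
    out["area"] = df["area"].astype(str)
    out["diabetes"] = _parse_diabetes(df["diabetes"])
    for var in schema.variables:
        raw = df[var.name]
        if var.is_categorical:
            col = raw.where(raw != MISSING, None)
            out[var.name] = col
        else:
            col = raw.replace(MISSING, "nan")
            try:
                out[var.name] = col.astype(float)
            except ValueError as exc:
                raise ValidationError(f"unparseable value for {var.name!r}: {exc}") from exc
    return SurveyTable(schema, out.reset_index(drop=True))


def write_survey(table: SurveyTable, path: str | Path | io.TextIOBase) -> None:
    """Write a survey CSV that round-trips exactly through :func:`read_survey`.

    Weights and continuous values are written with ``repr`` so float values
    survive to full precision.
    """
    df = table.data
    out = pd.DataFrame(index=df.index)
    out["respondent_id"] = df["respondent_id"]
    out["weight"] = df["weight"].map(repr)
    out["area"] = df["area"]
    out["diabetes"] = df["diabetes"].map({True: "1", False: "0"})
    for var in table.schema.variables:
        col = df[var.name]
        if var.is_categorical:
            out[var.name] = col.where(col.notna(), MISSING)
        else:
            out[var.name] = col.map(lambda x: MISSING if pd.isna(x) else repr(float(x)))
    out.to_csv(path, index=False)


def read_schema(path: str | Path | io.TextIOBase) -> IndicatorSchema:
    """Read a schema from a YAML file (list of name/scale/categories maps)."""
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(path)
    variables = []
    for entry in raw["variables"]:
        cats = entry.get("categories")
        variables.append(
            Variable(entry["name"], entry["scale"], tuple(cats) if cats else None)
        )
    return IndicatorSchema(tuple(variables))


def write_schema(schema: IndicatorSchema, path: str | Path | io.TextIOBase) -> None:
    payload = {
        "variables": [
            {
                "name": v.name,
                "scale": v.scale,
                **({"categories": list(v.categories)} if v.categories else {}),
            }
            for v in schema.variables
        ]
    }
    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    else:
        yaml.safe_dump(payload, path, sort_keys=False)


# --------------------------------------------------------------------------
# weighted statistics
# --------------------------------------------------------------------------


class UndefinedProportionError(ValueError):
    """Raised when a weighted proportion is requested over an empty subset."""


def weighted_proportion(
    weights: np.ndarray | Sequence[float],
    flags: np.ndarray | Sequence[bool] | Callable,
    records: pd.DataFrame | None = None,
) -> float:
    """Population-weighted proportion Σ w·1[flag] / Σ w.

    ``flags`` may be a boolean array aligned with ``weights``, or a predicate
    applied row-wise to ``records``.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise UndefinedProportionError("empty subset")
    if callable(flags):
        if records is None:
            raise ValueError("predicate form requires records")
        f = np.fromiter((bool(flags(row)) for _, row in records.iterrows()), dtype=bool, count=len(records))
    else:
        f = np.asarray(flags, dtype=bool)
    if f.shape != w.shape:
        raise ValueError("weights and flags must align")
    if not (w > 0).all():
        raise ValidationError("weights must be positive")
    return float(w[f].sum() / w.sum())


def weighted_percentile(
    values: np.ndarray | Sequence[float],
    weights: np.ndarray | Sequence[float],
    q: float,
) -> float:
    """Left-continuous inverse of the weighted empirical CDF.

    Returns the smallest value ``v`` such that the weighted fraction of
    observations with value <= v is >= q/100.
    """
    if not 0 < q < 100:
        raise ValueError(f"percentile q must lie in (0, 100), got {q}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or v.shape != w.shape:
        raise ValueError("values and weights must be non-empty and aligned")
    if not (w > 0).all():
        raise ValidationError("weights must be positive")
    order = np.argsort(v, kind="stable")
    vs = v[order]
    cw = np.cumsum(w[order])
    frac = cw / cw[-1]
    # smallest index whose cumulative fraction reaches q/100; float-tolerant
    idx = int(np.searchsorted(frac, q / 100.0 - 1e-12, side="left"))
    idx = min(idx, v.size - 1)
    return float(vs[idx])
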