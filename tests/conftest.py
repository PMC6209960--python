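"""Shared fixtures: toy schemas/tables and the (expensive) default synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vulnmap.data_model import (
    IndicatorSchema,
    SurveyTable,
    Variable,
    candidate_indicators,
)
from vulnmap.synthetic import generate
from vulnmap.twostep import TwoStepConfig, eliminate_variables

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_schema() -> IndicatorSchema:
    return IndicatorSchema(
        (
            Variable("color", "nominal", ("Red", "Green", "Blue")),
            Variable("size", "ordinal", ("Small", "Medium", "Large")),
            Variable("score", "continuous"),
        )
    )


def build_table(schema: IndicatorSchema, rows: list[dict]) -> SurveyTable:
    """Assemble a SurveyTable from plain dict rows (structural defaults filled)."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "respondent_id": row.get("respondent_id", f"R{i + 1:03d}"),
            "weight": row.get("weight", 1.0),
            "area": row.get("area", "A01"),
            "diabetes": row.get("diabetes", False),
        }
        for var in schema.variables:
            rec[var.name] = row.get(var.name, np.nan if not var.is_categorical else None)
        records.append(rec)
    return SurveyTable(schema, pd.DataFrame(records))


@pytest.fixture()
def toy_table(toy_schema) -> SurveyTable:
    return build_table(
        toy_schema,
        [
            {"color": "Red", "size": "Small", "score": 1.25, "weight": 1.0},
            {"color": "Green", "size": "Medium", "score": 2.5, "weight": 2.0},
            {"color": "Blue", "size": "Large", "score": 3.75, "weight": 3.0, "diabetes": True},
        ],
    )


# ---- the default synthetic study, shared across recovery tests -------------


@pytest.fixture(scope="session")
def default_run():
    """Default-condition synthetic survey (n = 4749, three segments, seed 1)."""
    return generate(seed=1)


@pytest.fixture(scope="session")
def default_table(default_run):
    return default_run[0]


@pytest.fixture(scope="session")
def default_truth(default_run):
    return default_run[1]


@pytest.fixture(scope="session")
def eliminated_solution(default_table):
    """Variable-elimination clustering of the diabetic subset (shared)."""
    table = default_table
    return eliminate_variables(
        table.diabetic(), table.schema, candidate_indicators(table.schema), TwoStepConfig()
    )
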