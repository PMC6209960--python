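"""Importance-weighted profile-match screening of the undiagnosed population.

Every undiagnosed respondent is scored against each diabetic cluster's modal
profile: the score is the sum, over the solution's active indicators, of the
indicator's importance weight when the respondent's value equals the
cluster's modal category (missing values contribute nothing).  Respondents
scoring at or above the 75th survey-weighted percentile of a cluster's score
distribution are *matchers* for that cluster; a respondent exceeding several
thresholds is assigned to the best (highest-scoring) cluster so area tallies
never double-count.

Match credit is binary by default — no ordinal partial credit — with an
optional graded mode giving half credit to categories adjacent to the modal
category of an ordinal indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    IndicatorSchema,
    SurveyTable,
    UndefinedProportionError,
    weighted_percentile,
    weighted_proportion,
)
from .twostep import ClusterSolution

logger = logging.getLogger(__name__)

__all__ = ["MatchConfig", "MatchResult", "score", "score_matrix", "flag_matchers", "compare_predictors"]


@dataclass(frozen=True)
class MatchConfig:
    percentile: float = 75.0
    weighted_threshold: bool = True  # survey-weighted percentile of scores
    graded_ordinal: bool = False  # adjacent ordinal category = half credit


@dataclass
class MatchResult:
    """Per-respondent, per-cluster screening outcome for the undiagnosed."""

    scores: pd.DataFrame  # index respondent_id, one column per cluster index
    thresholds: dict[int, float]
    matcher: pd.Series  # bool, index respondent_id
    best_cluster: pd.Series  # nullable Int64, defined for matchers only
    percentile: float
    degenerate: bool = False

    @property
    def matcher_ids(self) -> pd.Index:
        return self.matcher.index[self.matcher]


def score(
    record: pd.Series,
    modal_profile: dict[str, str],
    importance: dict[str, float],
    schema: IndicatorSchema | None = None,
    graded_ordinal: bool = False,
) -> float:
    """Importance-weighted match score of one record against one profile."""
    total = 0.0
    for var, modal in modal_profile.items():
        w = importance.get(var, 0.0)
        val = record.get(var)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        if val == modal:
            total += w
        elif graded_ordinal and schema is not None:
            v = schema[var]
            if v.scale == "ordinal":
                cats = list(v.categories)
                if abs(cats.index(val) - cats.index(modal)) == 1:
                    total += 0.5 * w
    return total


def score_matrix(
    table: SurveyTable, solution: ClusterSolution, config: MatchConfig | None = None
) -> pd.DataFrame:
    """Scores of every *undiagnosed* respondent against every cluster profile."""
    config = config or MatchConfig()
    undiag = table.undiagnosed()
    out = pd.DataFrame(index=pd.Index(undiag["respondent_id"], name="respondent_id"))
    schema = table.schema
    for c, profile in sorted(solution.modal_profile.items()):
        s = np.zeros(len(undiag))
        for var, modal in profile.items():
            w = solution.importance.get(var, 0.0)
            col = undiag[var]
            s += np.where(col.to_numpy() == modal, w, 0.0)
            if config.graded_ordinal and schema[var].scale == "ordinal":
                cats = list(schema[var].categories)
                mi = cats.index(modal)
                adjacent = [cats[j] for j in (mi - 1, mi + 1) if 0 <= j < len(cats)]
                s += np.where(col.isin(adjacent).to_numpy(), 0.5 * w, 0.0)
        out[c] = s
    return out


def flag_matchers(
    scores: pd.DataFrame,
    weights: np.ndarray,
    config: MatchConfig | None = None,
) -> MatchResult:
    """Apply the per-cluster percentile screen to a score matrix.

    The threshold for each cluster is the survey-weighted percentile of that
    cluster's score distribution over the pooled undiagnosed population.  A
    respondent is a matcher when any cluster score reaches its threshold;
    ``best_cluster`` is the argmax over qualifying clusters (ties to the
    lower cluster index).
    """
    config = config or MatchConfig()
    w = np.ones(len(scores)) if not config.weighted_threshold else np.asarray(weights, float)
    thresholds: dict[int, float] = {}
    qualifies = pd.DataFrame(index=scores.index)
    degenerate = False
    for c in scores.columns:
        col = scores[c].to_numpy(dtype=float)
        thr = weighted_percentile(col, w, config.percentile)
        thresholds[int(c)] = thr
        qualifies[c] = col >= thr - 1e-12
        if np.all(col == col[0]):
            degenerate = True
            logger.warning("cluster %s: degenerate all-equal score distribution", c)
    matcher = qualifies.any(axis=1)
    best = pd.Series(pd.NA, index=scores.index, dtype="Int64")
    if matcher.any():
        masked = scores.where(qualifies, -np.inf)
        # idxmax returns the first (lowest) column on ties
        best.loc[matcher] = masked.loc[matcher].idxmax(axis=1).astype("Int64")
    return MatchResult(
        scores=scores,
        thresholds=thresholds,
        matcher=matcher,
        best_cluster=best,
        percentile=config.percentile,
        degenerate=degenerate,
    )


#: biological predictor definitions used in matcher/non-matcher comparisons
_PREDICTOR_FLAGS = {
    "high_blood_pressure": lambda df: (df["high_blood_pressure"] == "Yes").to_numpy(),
    "age_over_44": lambda df: (df["age"].to_numpy(dtype=float) >= 45.0),
    "high_bmi": lambda df: (df["bmi"].to_numpy(dtype=float) > 26.93),
}


def compare_predictors(table: SurveyTable, result: MatchResult) -> pd.DataFrame:
    """Matchers vs non-matchers on the three biological diabetes predictors.

    Returns population-weighted and unweighted prevalences of high blood
    pressure, age over 44 (>= 45 years), and body-mass index above
    26.93 kg/m² within each group of undiagnosed respondents.
    """
    undiag = table.undiagnosed().set_index("respondent_id")
    undiag = undiag.loc[result.matcher.index]
    if not result.matcher.any():
        raise UndefinedProportionError("no matchers to compare")
    rows = []
    for name, fn in _PREDICTOR_FLAGS.items():
        flags = fn(undiag)
        w = undiag["weight"].to_numpy(dtype=float)
        m = result.matcher.to_numpy()
        rows.append(
            {
                "predictor": name,
                "matcher_weighted": weighted_proportion(w[m], flags[m]),
                "non_matcher_weighted": weighted_proportion(w[~m], flags[~m]),
                "matcher_unweighted": float(flags[m].mean()),
                "non_matcher_unweighted": float(flags[~m].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
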