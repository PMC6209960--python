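"""Small-area aggregation of matcher flags and vulnerable-area selection.

Two concentration dimensions are tallied per area and cluster, both with
survey weights:

* **share** — the percentage of all matchers of a cluster (countywide) who
  reside in the area; shares over areas sum to 100 per cluster;
* **concentration** — the percentage of the area's own population made up of
  matchers of that cluster.

An area is selected for a cluster when it falls in the top quartile of both
dimensions; the final vulnerable set is the union over clusters, ranked by
concentration.  Areas are opaque codes — no geography is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SurveyTable, weighted_percentile
from .matching import MatchResult

logger = logging.getLogger(__name__)

__all__ = ["AreaSummary", "summarize_areas", "select_vulnerable"]


@dataclass
class AreaSummary:
    """Per-area, per-cluster share and concentration percentages."""

    table: pd.DataFrame  # columns: area, cluster, share_pct, concentration_pct
    areas: tuple[str, ...]
    clusters: tuple[int, ...]
    zero_population_areas: tuple[str, ...] = ()


def summarize_areas(
    table: SurveyTable, match: MatchResult, areas: list[str] | None = None
) -> AreaSummary:
    """Weighted per-area, per-cluster matcher tallies.

    Matchers are attributed to their ``best_cluster`` only, so no respondent
    is counted toward more than one cluster.
    """
    df = table.data.set_index("respondent_id")
    areas = sorted(areas) if areas is not None else sorted(df["area"].unique())
    if not set(df["area"]).issubset(areas):
        raise ValueError("records reference areas outside the configured area set")
    clusters = tuple(int(c) for c in match.scores.columns)

    pop_w = df.groupby("area")["weight"].sum().reindex(areas, fill_value=0.0)
    zero_pop = tuple(a for a in areas if pop_w[a] <= 0)
    for a in zero_pop:
        logger.warning("area %s has zero weighted population; concentration undefined", a)

    mdf = df.loc[match.matcher_ids, ["area", "weight"]].copy()
    mdf["cluster"] = match.best_cluster.loc[match.matcher_ids].astype(int).to_numpy()
    rows = []
    for c in clusters:
        sub = mdf.loc[mdf["cluster"] == c]
        by_area = sub.groupby("area")["weight"].sum().reindex(areas, fill_value=0.0)
        total = by_area.sum()
        for a in areas:
            share = 100.0 * by_area[a] / total if total > 0 else 0.0
            conc = 100.0 * by_area[a] / pop_w[a] if pop_w[a] > 0 else np.nan
            rows.append(
                {"area": a, "cluster": c, "share_pct": share, "concentration_pct": conc}
            )
    return AreaSummary(pd.DataFrame(rows), tuple(areas), clusters, zero_pop)


@dataclass
class SelectionResult:
    selected: tuple[str, ...]  # ranked by concentration, descending
    per_cluster: dict[int, tuple[str, ...]]
    tie_warning: bool = False


def select_vulnerable(
    summary: AreaSummary, quartile: float = 75.0, cap: int | None = None
) -> SelectionResult:
    """Quartile rule: per cluster, candidate areas sit in the top quartile of
    share *and* of concentration; the final set is the union over clusters
    ranked by concentration (area-code order breaks exact ties), optionally
    capped."""
    if len(summary.areas) < 4:
        raise ValueError("need at least 4 areas for a quartile rule")
    per_cluster: dict[int, tuple[str, ...]] = {}
    ranking: dict[str, float] = {}
    tie_warning = False
    ones = np.ones(len(summary.areas))
    for c in summary.clusters:
        sub = summary.table.loc[summary.table["cluster"] == c].set_index("area")
        share = sub["share_pct"].reindex(list(summary.areas)).to_numpy(dtype=float)
        conc = sub["concentration_pct"].reindex(list(summary.areas)).to_numpy(dtype=float)
        conc_f = np.where(np.isnan(conc), -np.inf, conc)
        share_thr = weighted_percentile(share, ones, quartile)
        conc_thr = weighted_percentile(conc_f[np.isfinite(conc_f)], ones[: np.isfinite(conc_f).sum()], quartile)
        # an area with no matchers of the cluster is never vulnerable for it,
        # even when a mostly-zero distribution drags the quartile cut to zero
        hit = (share >= share_thr - 1e-12) & (conc_f >= conc_thr - 1e-12) & (conc_f > 0)
        if np.all(share == share[0]) or np.all(conc_f == conc_f[0]):
            tie_warning = True
            logger.warning("cluster %s: tied area distribution; selection by area order", c)
        chosen = tuple(a for a, h in zip(summary.areas, hit) if h)
        per_cluster[c] = chosen
        for a, cv in zip(summary.areas, conc_f):
            if a in chosen:
                ranking[a] = max(ranking.get(a, -np.inf), cv)
    ranked = sorted(ranking, key=lambda a: (-ranking[a], a))
    if cap is not None:
        ranked = ranked[:cap]
    return SelectionResult(tuple(ranked), per_cluster, tie_warning)
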