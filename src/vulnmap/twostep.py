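"""Two-step clustering of categorical survey profiles.

Implements the standard two-step procedure for nonmetric (categorical /
ordinal) data: a sequential pre-clustering leader pass compresses the cases
into at most ``max_subclusters`` sub-clusters, which are then merged
agglomeratively under the log-likelihood (entropy) distance.  The number of
clusters is selected automatically from the BIC trace refined by the ratio of
merge distances.  Predictor importance is a chi-square association rescaled
so the strongest indicator scores exactly 1.0, and solution quality is an
average silhouette computed in the same entropy distance.

All categorical variables — ordinal included — are treated multinomially:
the procedure is nonmetric and never scores categories numerically.
Clustering is unweighted; survey weights play no role here.

The top-level :func:`eliminate_variables` drives the variable-elimination
loop: starting from the full candidate set, the lowest-importance indicator
is dropped until (1) the cases-per-variable ratio is acceptable, (2) the
quality band is fair or good, and (3) the largest/smallest cluster size
ratio is below 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data_model import IndicatorSchema, SurveyTable

__all__ = [
    "ClusterFeature",
    "ClusterSolution",
    "Dendrogram",
    "TwoStepConfig",
    "entropy_cost",
    "merge_distance",
    "precluster",
    "agglomerate",
    "select_k",
    "predictor_importance",
    "silhouette_quality",
    "cluster",
    "eliminate_variables",
]


# --------------------------------------------------------------------------
# encoding and cluster features
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Encoding:
    """Integer coding of complete cases on the active categorical variables."""

    variables: tuple[str, ...]
    cat_sizes: tuple[int, ...]
    offsets: tuple[int, ...]  # start of each variable's block in the cell vector
    codes: np.ndarray  # (n_cases, n_vars) int
    case_ids: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return self.offsets[-1] + self.cat_sizes[-1]

    def onehot(self) -> np.ndarray:
        """(n_cases, n_cells) 0/1 count matrix."""
        n, v = self.codes.shape
        out = np.zeros((n, self.n_cells), dtype=float)
        rows = np.repeat(np.arange(n), v)
        cols = (self.codes + np.asarray(self.offsets)).ravel()
        out[rows, cols] = 1.0
        return out


def encode_cases(
    frame: pd.DataFrame, schema: IndicatorSchema, variables: Sequence[str]
) -> Encoding:
    """Encode the complete cases of ``frame`` on ``variables``.

    Cases missing any active variable are excluded (listwise within the
    current variable set).
    """
    for v in variables:
        if not schema[v].is_categorical:
            raise ValueError(f"clustering variable {v!r} must be categorical")
    sub = frame[list(variables)]
    complete = sub.notna().all(axis=1).to_numpy()
    sub = sub.loc[complete]
    codes = np.empty((len(sub), len(variables)), dtype=np.int64)
    sizes = []
    for j, v in enumerate(variables):
        cats = list(schema[v].categories)
        sizes.append(len(cats))
        codes[:, j] = pd.Categorical(sub[v], categories=cats).codes
    offsets = tuple(int(x) for x in np.concatenate(([0], np.cumsum(sizes)[:-1])))
    ids = tuple(frame.loc[complete, "respondent_id"].astype(str))
    return Encoding(tuple(variables), tuple(sizes), offsets, codes, ids)


@dataclass
class ClusterFeature:
    """Sufficient statistics of a cluster: case count and per-category counts.

    Mergeable by component-wise addition.  Continuous variables would carry
    sums and sums of squares; the default pipeline clusters categorical
    variables only.
    """

    n: int
    counts: np.ndarray  # concatenated per-variable category counts
    n_vars: int

    @classmethod
    def from_cases(cls, enc: Encoding, indices: Sequence[int]) -> "ClusterFeature":
        idx = np.asarray(indices, dtype=int)
        counts = np.zeros(enc.n_cells, dtype=float)
        flat = (enc.codes[idx] + np.asarray(enc.offsets)).ravel()
        np.add.at(counts, flat, 1.0)
        return cls(int(idx.size), counts, len(enc.variables))

    def merge(self, other: "ClusterFeature") -> "ClusterFeature":
        return ClusterFeature(self.n + other.n, self.counts + other.counts, self.n_vars)


def _xlogx(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a, dtype=float)
    pos = a > 0
    out[pos] = a[pos] * np.log(a[pos])
    return out


def entropy_cost(cf: ClusterFeature, schema: IndicatorSchema | None = None) -> float:
    """ξ(cf) = Σ_v n·H_v with H_v the within-cluster category entropy (nats).

    Equal to n_vars·n·ln n − Σ_cells n_vl·ln n_vl; a pure (single-category)
    variable contributes zero.
    """
    if cf.n < 1:
        raise ValueError("cluster feature must hold at least one case")
    return float(cf.n_vars * cf.n * math.log(cf.n) - _xlogx(cf.counts).sum())


def merge_distance(
    a: ClusterFeature, b: ClusterFeature, schema: IndicatorSchema | None = None
) -> float:
    """Log-likelihood distance ξ(a⊕b) − ξ(a) − ξ(b); symmetric, >= 0."""
    return entropy_cost(a.merge(b)) - entropy_cost(a) - entropy_cost(b)


def _xi_rows(counts: np.ndarray, ns: np.ndarray, n_vars: int) -> np.ndarray:
    """Vectorized ξ for a stack of cluster features (rows)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        nlogn = np.where(ns > 0, ns * np.log(np.maximum(ns, 1e-300)), 0.0)
    return n_vars * nlogn - _xlogx(counts).sum(axis=1)


def _distances_to_case(
    case_cells: np.ndarray, counts: np.ndarray, ns: np.ndarray, n_vars: int
) -> np.ndarray:
    """merge_distance of one singleton case against each row cluster."""
    merged = counts + case_cells[None, :]
    xi_merged = _xi_rows(merged, ns + 1.0, n_vars)
    xi_own = _xi_rows(counts, ns, n_vars)
    return xi_merged - xi_own  # singleton ξ is 0


# --------------------------------------------------------------------------
# pre-clustering
# --------------------------------------------------------------------------


def _sample_threshold(enc: Encoding, sample: int = 100, q: float = 10.0) -> float:
    """10th percentile of pairwise singleton distances on a leading sample."""
    m = min(sample, enc.codes.shape[0])
    onehot = np.zeros((m, enc.n_cells))
    rows = np.repeat(np.arange(m), len(enc.variables))
    cols = (enc.codes[:m] + np.asarray(enc.offsets)).ravel()
    onehot[rows, cols] = 1.0
    dists = []
    for i in range(m - 1):
        merged = onehot[i + 1 :] + onehot[i]
        xi = _xi_rows(merged, np.full(m - 1 - i, 2.0), len(enc.variables))
        dists.append(xi)
    if not dists:
        return 0.0
    pooled = np.concatenate(dists)
    return float(np.percentile(pooled, q))


def _leader_pass(enc: Encoding, threshold: float, max_subclusters: int):
    """Single sequential leader pass; returns (counts, ns, assign) or None on overflow."""
    n, v = enc.codes.shape
    offsets = np.asarray(enc.offsets)
    counts = np.zeros((max_subclusters + 1, enc.n_cells))
    ns = np.zeros(max_subclusters + 1)
    k = 0
    assign = np.empty(n, dtype=int)
    cell = np.zeros(enc.n_cells)
    for i in range(n):
        cell[:] = 0.0
        cell[enc.codes[i] + offsets] = 1.0
        if k > 0:
            d = _distances_to_case(cell, counts[:k], ns[:k], v)
            j = int(np.argmin(d))
            if d[j] <= threshold + 1e-12:
                counts[j] += cell
                ns[j] += 1.0
                assign[i] = j
                continue
        if k >= max_subclusters:
            return None
        counts[k] = cell
        ns[k] = 1.0
        assign[i] = k
        k += 1
    return counts[:k].copy(), ns[:k].copy(), assign


def precluster(
    enc: Encoding, max_subclusters: int = 50
) -> tuple[list[ClusterFeature], np.ndarray]:
    """Compress cases into at most ``max_subclusters`` sub-clusters.

    The first leader pass merges only exact duplicates (zero distance), which
    leaves hierarchical results untouched; when the sub-cluster count would
    exceed capacity the distance threshold is raised to a sampled pairwise
    percentile and doubled until the pass fits, restarting deterministically
    each time.
    """
    if enc.codes.shape[0] == 0:
        raise ValueError("cannot pre-cluster an empty case set")
    threshold = 0.0
    for _ in range(200):
        result = _leader_pass(enc, threshold, max_subclusters)
        if result is not None:
            counts, ns, assign = result
            cfs = [
                ClusterFeature(int(ns[j]), counts[j].copy(), len(enc.variables))
                for j in range(len(ns))
            ]
            return cfs, assign
        if threshold == 0.0:
            threshold = _sample_threshold(enc)
            if threshold <= 0.0:
                threshold = 1e-6
        else:
            threshold *= 2.0
    raise RuntimeError("pre-clustering failed to converge")  # pragma: no cover


# --------------------------------------------------------------------------
# agglomeration
# --------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Greedy agglomeration record over sub-clusters.

    ``partitions[k]`` is the partition into ``k`` clusters, each cluster a
    tuple of sub-cluster indices.  ``merge_dist[k]`` is the distance of the
    merge that reduces ``k`` clusters to ``k − 1``; ``bic[k]`` the BIC at
    level ``k``.  Keys run from the initial sub-cluster count down to 1.
    """

    partitions: dict[int, tuple[tuple[int, ...], ...]]
    merge_dist: dict[int, float]
    bic: dict[int, float]

    @property
    def k_max(self) -> int:
        return max(self.partitions)

    def cut(self, k: int) -> tuple[tuple[int, ...], ...]:
        return self.partitions[k]


def _pairwise(cfs: list[ClusterFeature]) -> np.ndarray:
    k = len(cfs)
    xi = np.array([entropy_cost(c) for c in cfs])
    d = np.full((k, k), np.inf)
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = entropy_cost(cfs[i].merge(cfs[j])) - xi[i] - xi[j]
    return d


def agglomerate(
    cfs: list[ClusterFeature],
    cat_sizes: Sequence[int],
    n_cases: int | None = None,
) -> Dendrogram:
    """Greedy pairwise merging by minimum log-likelihood distance down to 1.

    Records BIC(k) = 2·Σ_clusters ξ + r·k·ln N with r = Σ_v (L_v − 1) free
    category parameters per cluster.  Distance ties break on the lowest
    current (i, j) index pair.
    """
    if len(cfs) < 1:
        raise ValueError("need at least one sub-cluster")
    active = list(range(len(cfs)))
    feats = {i: cfs[i] for i in active}
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in active}
    N = n_cases if n_cases is not None else sum(c.n for c in cfs)
    r = sum(L - 1 for L in cat_sizes)
    logN = math.log(max(N, 2))

    d = _pairwise(cfs)
    partitions: dict[int, tuple[tuple[int, ...], ...]] = {}
    merge_dist: dict[int, float] = {}
    bic: dict[int, float] = {}

    def record(level: int) -> None:
        partitions[level] = tuple(members[i] for i in active)
        bic[level] = 2.0 * sum(entropy_cost(feats[i]) for i in active) + r * level * logN

    record(len(active))
    while len(active) > 1:
        best = (np.inf, None)
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                dij = d[min(active[ai], active[aj]), max(active[ai], active[aj])]
                # tolerance absorbs float summation-order noise so distance
                # ties break identically to a pooled-case recomputation
                if dij < best[0] - 1e-9:
                    best = (dij, (active[ai], active[aj]))
        dist, (i, j) = best
        feats[i] = feats[i].merge(feats[j])
        members[i] = members[i] + members[j]
        active.remove(j)
        # refresh distances involving i
        for o in active:
            if o == i:
                continue
            a, b = min(i, o), max(i, o)
            d[a, b] = merge_distance(feats[i], feats[o])
        level = len(active)
        merge_dist[level + 1] = float(dist)  # cost of leaving level+1 clusters
        record(level)
    return Dendrogram(partitions, merge_dist, bic)


def select_k(
    dendrogram: Dendrogram,
    bic_ratio: float = 0.04,
    dist_ratio: float = 1.15,
    k_cap: int | None = 15,
) -> int:
    """Automatic cluster-number selection from the BIC trace.

    Stage 1 (coarse): with d(k) = BIC(k) − BIC(k+1), the candidate is the
    smallest k whose ratio d(k)/d(1) drops below ``bic_ratio`` (the global
    BIC minimum if no such k; k = 1 immediately if adding a second cluster
    does not lower BIC).  Stage 2 (refine): among 2 <= k <= candidate, the
    ratio of merge distances R(k) = dist(k)/dist(k+1) — dist(k) being the
    cost of merging k clusters into k − 1 — is maximized; the winner is
    accepted only when it exceeds ``dist_ratio`` times the runner-up,
    otherwise the larger of the two k values is returned.
    """
    bic = dendrogram.bic
    K = dendrogram.k_max
    if k_cap is not None:
        K = min(K, k_cap)
    ks = list(range(1, K + 1))
    if K < 3:
        return min(bic, key=lambda k: (bic[k], k))
    d = {k: bic[k] - bic[k + 1] for k in ks[:-1]}
    if d[1] <= 0:
        return 1
    coarse = None
    for k in ks[:-1]:
        if d[k] / d[1] < bic_ratio:
            coarse = k
            break
    if coarse is None:
        coarse = min(ks, key=lambda k: (bic[k], k))
    if coarse < 3:
        return coarse
    md = dendrogram.merge_dist

    def ratio(k: int) -> float:
        lo = md.get(k + 1, 0.0)
        hi = md.get(k, 0.0)
        if lo <= 0:
            return math.inf if hi > 0 else 1.0
        return hi / lo

    cands = list(range(2, coarse + 1))
    ranked = sorted(cands, key=lambda k: (-ratio(k), k))
    k1, k2 = ranked[0], ranked[1]
    if ratio(k1) > dist_ratio * ratio(k2):
        return k1
    return max(k1, k2)


# --------------------------------------------------------------------------
# solution statistics
# --------------------------------------------------------------------------


def predictor_importance(
    enc: Encoding, labels: np.ndarray, p_floor: float = 1e-300
) -> dict[str, float]:
    """Chi-square association of each variable with cluster membership.

    score_v = −log10 p_v (p floored); importance_v = score_v / max score, so
    the top variable scores exactly 1.0.  A variable constant across the
    assigned cases scores 0 by convention.
    """
    if len(np.unique(labels)) < 2:
        raise ValueError("importance requires at least two clusters")
    scores = {}
    for j, v in enumerate(enc.variables):
        col = enc.codes[:, j]
        tab = pd.crosstab(col, labels).to_numpy()
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            scores[v] = 0.0
            continue
        p = chi2_contingency(tab, correction=False).pvalue
        scores[v] = -math.log10(max(float(p), p_floor))
    top = max(scores.values())
    if top <= 0:
        return {v: 0.0 for v in scores}
    return {v: s / top for v, s in scores.items()}


def silhouette_quality(enc: Encoding, labels: np.ndarray) -> tuple[float, str]:
    """Average silhouette under the log-likelihood distance, with band.

    Per-case cohesion a(i) is the merge distance of the singleton against its
    own cluster's feature (case removed); separation b(i) the minimum such
    distance to any other cluster.  Bands: poor < 0.2 <= fair <= 0.5 < good.
    """
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    v = len(enc.variables)
    offsets = np.asarray(enc.offsets)
    counts = np.zeros((uniq.size, enc.n_cells))
    ns = np.zeros(uniq.size)
    lab_index = {c: i for i, c in enumerate(uniq)}
    for i, c in enumerate(uniq):
        idx = np.flatnonzero(labels == c)
        cf = ClusterFeature.from_cases(enc, idx)
        counts[i] = cf.counts
        ns[i] = cf.n
    s_vals = np.zeros(len(labels))
    cell = np.zeros(enc.n_cells)
    for i in range(len(labels)):
        cell[:] = 0.0
        cell[enc.codes[i] + offsets] = 1.0
        ci = lab_index[labels[i]]
        if ns[ci] <= 1:
            s_vals[i] = 0.0  # singleton cluster convention
            continue
        own_counts = counts[ci] - cell
        own_n = ns[ci] - 1.0
        a = float(
            (
                _xi_rows((own_counts + cell)[None, :], np.array([own_n + 1.0]), v)
                - _xi_rows(own_counts[None, :], np.array([own_n]), v)
            )[0]
        )
        others = np.array([j for j in range(uniq.size) if j != ci])
        b = float(_distances_to_case(cell, counts[others], ns[others], v).min())
        denom = max(a, b)
        s_vals[i] = 0.0 if denom <= 0 else (b - a) / denom
    avg = float(s_vals.mean())
    band = "poor" if avg < 0.2 else ("fair" if avg <= 0.5 else "good")
    return avg, band


# --------------------------------------------------------------------------
# full clustering and variable elimination
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoStepConfig:
    max_subclusters: int = 50
    bic_ratio: float = 0.04
    dist_ratio: float = 1.15
    k_cap: int | None = 15
    k_fixed: int | None = None  # bypass automatic selection when set
    cases_per_variable: float = 10.0
    min_variables: int = 8
    size_ratio_limit: float = 2.0


@dataclass
class ClusterSolution:
    """A fitted clustering of the diabetic subset.

    Cluster indices are 1..k ordered by descending size.  ``assignments``
    maps respondent id -> cluster index for every classified (complete) case.
    """

    k: int
    assignments: dict[str, int]
    sizes: dict[int, int]
    modal_profile: dict[int, dict[str, str]]
    importance: dict[str, float]
    silhouette: float
    quality_band: str
    bic_trace: dict[int, float]
    active_variables: tuple[str, ...]
    n_classified: int
    converged: bool = True
    eliminated: tuple[str, ...] = ()

    @property
    def size_ratio(self) -> float:
        s = list(self.sizes.values())
        return max(s) / min(s)


def _modal_profiles(
    enc: Encoding, labels: np.ndarray, schema: IndicatorSchema
) -> dict[int, dict[str, str]]:
    out: dict[int, dict[str, str]] = {}
    for c in np.unique(labels):
        idx = labels == c
        prof = {}
        for j, v in enumerate(enc.variables):
            cnt = np.bincount(enc.codes[idx, j], minlength=len(schema[v].categories))
            prof[v] = schema[v].categories[int(np.argmax(cnt))]
        out[int(c)] = prof
    return out


def cluster(
    frame: pd.DataFrame,
    schema: IndicatorSchema,
    variables: Sequence[str],
    config: TwoStepConfig | None = None,
) -> ClusterSolution:
    """Run the full two-step procedure on one variable set."""
    config = config or TwoStepConfig()
    enc = encode_cases(frame, schema, variables)
    if enc.codes.shape[0] == 0:
        raise ValueError("no complete cases on the active variables")
    cfs, pre_assign = precluster(enc, config.max_subclusters)
    dendro = agglomerate(cfs, enc.cat_sizes, n_cases=enc.codes.shape[0])
    if config.k_fixed is not None:
        k = min(config.k_fixed, dendro.k_max)
    else:
        k = select_k(dendro, config.bic_ratio, config.dist_ratio, config.k_cap)
    part = dendro.cut(k)
    sub_to_cluster = np.empty(len(cfs), dtype=int)
    for ci, group in enumerate(part):
        for s in group:
            sub_to_cluster[s] = ci
    raw_labels = sub_to_cluster[pre_assign]
    # relabel clusters 1..k by descending size (ties: original order)
    sizes = np.bincount(raw_labels, minlength=len(part))
    order = sorted(range(len(part)), key=lambda c: (-sizes[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.asarray([relabel[c] for c in raw_labels])

    if k >= 2:
        importance = predictor_importance(enc, labels)
        sil, band = silhouette_quality(enc, labels)
    else:
        importance = {v: 0.0 for v in enc.variables}
        sil, band = 0.0, "poor"
    return ClusterSolution(
        k=k,
        assignments={rid: int(c) for rid, c in zip(enc.case_ids, labels)},
        sizes=_ordered_sizes(relabel, sizes),
        modal_profile=_modal_profiles(enc, labels, schema),
        importance=importance,
        silhouette=sil,
        quality_band=band,
        bic_trace=dict(dendro.bic),
        active_variables=tuple(variables),
        n_classified=int(enc.codes.shape[0]),
    )


def _ordered_sizes(relabel: dict[int, int], sizes: np.ndarray) -> dict[int, int]:
    out = {relabel[c]: int(sizes[c]) for c in range(len(relabel))}
    return {k: out[k] for k in sorted(out)}


_BAND_RANK = {"poor": 0, "fair": 1, "good": 2}


def eliminate_variables(
    frame: pd.DataFrame,
    schema: IndicatorSchema,
    candidates: Sequence[str],
    config: TwoStepConfig | None = None,
) -> ClusterSolution:
    """Iteratively drop the lowest-importance indicator until the halting
    criteria hold.

    Halting requires all of: complete cases per active variable at or above
    ``cases_per_variable``; quality band fair or good; largest/smallest
    cluster ratio under ``size_ratio_limit``.  Importance ties drop the
    variable later in schema order.  If the candidate set shrinks to
    ``min_variables`` without satisfaction, the best-quality iteration is
    returned flagged as non-converged.
    """
    config = config or TwoStepConfig()
    active = [v for v in schema.names if v in set(candidates)]
    if not active:
        raise ValueError("no candidate variables")
    if len(frame) / config.min_variables < config.cases_per_variable:
        raise ValueError(
            "fewer cases than the cases-per-variable floor permits at the "
            f"minimum variable count ({len(frame)} cases, floor "
            f"{config.cases_per_variable} x {config.min_variables} variables)"
        )
    eliminated: list[str] = []
    best: ClusterSolution | None = None
    while True:
        sol = cluster(frame, schema, active, config)
        sol.eliminated = tuple(eliminated)
        ok_ratio_vars = sol.n_classified / len(active) >= config.cases_per_variable
        ok_quality = sol.quality_band in ("fair", "good")
        ok_sizes = sol.k >= 2 and sol.size_ratio < config.size_ratio_limit
        if ok_ratio_vars and ok_quality and ok_sizes:
            sol.converged = True
            return sol
        if best is None or (_BAND_RANK[sol.quality_band], sol.silhouette) > (
            _BAND_RANK[best.quality_band],
            best.silhouette,
        ):
            best = sol
        if len(active) <= config.min_variables:
            best.converged = False
            return best
        # drop the lowest-importance variable; ties drop the later in schema order
        ranked = sorted(
            active, key=lambda v: (sol.importance.get(v, 0.0), -schema.names.index(v))
        )
        drop = ranked[0]
        active.remove(drop)
        eliminated.append(drop)
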