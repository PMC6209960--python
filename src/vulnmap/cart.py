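"""Classification trees for unbalanced survey outcomes.

Binary CART with Gini-impurity splitting under *equal class priors*: with a
rare outcome (about 9% diagnosed diabetes) the class probabilities inside a
node are reweighted by the root class totals, p̃_c ∝ π_c·n_c(t)/N_c with
π = (½, ½), so a terminal node predicts the outcome exactly when its event
rate meets or exceeds the baseline event rate of the root node.  This is the
decision-boundary consequence of "weighting by the baseline event rate" for
unbalanced data.

The module is deliberately unweighted: survey weights are not used in tree
construction or evaluation (recursive partitioning accommodates only
unweighted data); weighted reporting happens downstream.

Split search is exhaustive — threshold midpoints for continuous and ordinal
predictors, category-subset enumeration for nominal predictors (up to 12
categories, event-rate-ordered scan beyond).  Each internal node retains up
to five surrogate splits ranked by predictive association, used for
importance attribution and for routing cases with missing predictor values.
Model selection is minimal cost-complexity pruning with the subtree chosen by
seeded, outcome-stratified 10-fold cross-validation of the priors-weighted
misclassification rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import IndicatorSchema, SurveyTable

__all__ = [
    "CartParams",
    "Split",
    "Surrogate",
    "TreeNode",
    "Tree",
    "CvResult",
    "ModelResult",
    "gini",
    "best_split",
    "grow",
    "prune_sequence",
    "cross_validate",
    "predict_node",
    "node_rate",
    "importance",
    "model_suite",
    "prepare_matrix",
]

_EPS = 1e-12


# --------------------------------------------------------------------------
# parameters and data preparation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CartParams:
    min_node: int = 20  # minimum cases to attempt a split
    min_child: int = 7
    max_depth: int = 10
    n_surrogates: int = 5
    max_exhaustive_categories: int = 12
    n_folds: int = 10
    #: standard-error multiplier for subtree selection; 0 = strict minimum
    #: CV error, 1 = the conventional one-standard-error rule
    se_rule: float = 0.0


@dataclass
class PredictorColumn:
    """A predictor in split-search form.

    ``values``: float array; category codes for categorical predictors
    (NaN = missing).  ``categories`` is set for nominal predictors only —
    ordinal predictors are scanned as ordered codes (threshold rules), which
    respects but never scores their category order.
    """

    name: str
    values: np.ndarray
    categories: tuple[str, ...] | None = None  # nominal only

    @property
    def is_nominal(self) -> bool:
        return self.categories is not None


def prepare_matrix(
    table: SurveyTable, predictors: Sequence[str], outcome: str = "diabetes"
) -> tuple[list[PredictorColumn], np.ndarray]:
    """Extract predictor columns and the boolean outcome from a survey table."""
    schema = table.schema
    df = table.data
    cols: list[PredictorColumn] = []
    for name in predictors:
        var = schema[name]
        if var.is_categorical:
            codes = pd.Categorical(df[name], categories=list(var.categories)).codes
            vals = codes.astype(float)
            vals[codes < 0] = np.nan
            if var.scale == "nominal":
                cols.append(PredictorColumn(name, vals, tuple(var.categories)))
            else:
                cols.append(PredictorColumn(name, vals))
        else:
            cols.append(PredictorColumn(name, df[name].to_numpy(dtype=float)))
    if outcome == "diabetes":
        y = df["diabetes"].to_numpy(dtype=bool)
    else:
        var = table.schema[outcome]
        if not (var.is_categorical and len(var.categories) == 2):
            raise ValueError("outcome must be binary")
        y = (df[outcome] == var.categories[1]).to_numpy()
    return cols, y


# --------------------------------------------------------------------------
# priors-adjusted impurity
# --------------------------------------------------------------------------


def _mass(n0, n1, N0: float, N1: float):
    return 0.5 * np.asarray(n0, dtype=float) / N0 + 0.5 * np.asarray(n1, dtype=float) / N1


def gini(
    n_negative: float,
    n_positive: float,
    root_negative: float,
    root_positive: float,
) -> float:
    """Priors-adjusted Gini impurity 2·p̃₁·(1−p̃₁) of a node.

    p̃₁ = π₁·(n₁/N₁) / Σ_c π_c·(n_c/N_c) with equal priors π = (½, ½) and
    root class totals (N₀, N₁).
    """
    if n_negative + n_positive < 1:
        raise ValueError("node must hold at least one case")
    m = _mass(n_negative, n_positive, root_negative, root_positive)
    p1 = (0.5 * n_positive / root_positive) / m
    return float(2.0 * p1 * (1.0 - p1))


def _gini_vec(n0: np.ndarray, n1: np.ndarray, N0: float, N1: float) -> np.ndarray:
    m = _mass(n0, n1, N0, N1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(m > 0, (0.5 * n1 / N1) / np.where(m > 0, m, 1.0), 0.0)
    return 2.0 * p1 * (1.0 - p1)


# --------------------------------------------------------------------------
# splits and nodes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    """A binary routing rule.

    Threshold rules send ``value <= threshold`` left (right when ``flipped``,
    used by surrogate orientation).  Subset rules send values whose category
    code is in ``left_codes`` left.
    """

    variable: str
    threshold: float | None = None
    left_codes: frozenset[int] | None = None
    left_labels: tuple[str, ...] | None = None
    flipped: bool = False

    def goes_left(self, value: float) -> bool | None:
        if np.isnan(value):
            return None
        if self.threshold is not None:
            left = value <= self.threshold
            return (not left) if self.flipped else left
        return int(value) in self.left_codes


@dataclass(frozen=True)
class Surrogate:
    split: Split
    association: float
    gini_decrease: float  # the surrogate split's own mass-weighted decrease


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n_total: int
    n_positive: int
    event_rate: float
    split: Split | None = None
    surrogates: tuple[Surrogate, ...] = ()
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    predicted_positive: bool = False
    gini_decrease: float = 0.0  # mass-weighted impurity decrease of the split
    majority_left: bool = True

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        if self.split is not None:
            yield from self.left.walk()
            yield from self.right.walk()


@dataclass
class Tree:
    root: TreeNode
    root_totals: tuple[int, int]  # (n_negative, n_positive)
    predictors: tuple[str, ...]
    params: CartParams

    @property
    def baseline_rate(self) -> float:
        return self.root.event_rate

    def nodes(self) -> list[TreeNode]:
        return list(self.root.walk())

    def n_leaves(self, pruned: frozenset[int] = frozenset()) -> int:
        return sum(1 for _ in _iter_leaves(self.root, pruned))


def _iter_leaves(node: TreeNode, pruned: frozenset[int]) -> Iterable[TreeNode]:
    if node.is_leaf or node.node_id in pruned:
        yield node
    else:
        yield from _iter_leaves(node.left, pruned)
        yield from _iter_leaves(node.right, pruned)


# --------------------------------------------------------------------------
# split search
# --------------------------------------------------------------------------


def _split_candidates_threshold(
    x: np.ndarray, y: np.ndarray, N0: float, N1: float, min_child: int
):
    """Vectorized gain over all midpoint thresholds; returns (thr, gain, left_counts)."""
    ok = ~np.isnan(x)
    xs, ys = x[ok], y[ok]
    if xs.size < 2 * min_child:
        return None
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]
    # candidate boundaries between distinct consecutive values
    boundary = np.flatnonzero(np.diff(xs) > 0)
    if boundary.size == 0:
        return None
    cum1 = np.cumsum(ys)
    nL = boundary + 1
    nL1 = cum1[boundary]
    nL0 = nL - nL1
    n = xs.size
    n1 = int(cum1[-1])
    n0 = n - n1
    nR0, nR1 = n0 - nL0, n1 - nL1
    feasible = (nL >= min_child) & ((n - nL) >= min_child)
    if not feasible.any():
        return None
    mP = _mass(n0, n1, N0, N1)
    mL = _mass(nL0, nL1, N0, N1)
    mR = _mass(nR0, nR1, N0, N1)
    gains = (
        _gini_vec(np.array([n0]), np.array([n1]), N0, N1)[0]
        - (mL / mP) * _gini_vec(nL0, nL1, N0, N1)
        - (mR / mP) * _gini_vec(nR0, nR1, N0, N1)
    )
    gains[~feasible] = -np.inf
    j = int(np.argmax(gains))
    thr = 0.5 * (xs[boundary[j]] + xs[boundary[j] + 1])
    return float(thr), float(gains[j]), float(mP)


def _subset_masks(n_cats: int) -> list[tuple[int, ...]]:
    """Canonical proper-subset enumeration: bitmasks excluding the last
    category (avoids complements), ascending order."""
    out = []
    for mask in range(1, 1 << (n_cats - 1)):
        out.append(tuple(i for i in range(n_cats) if mask >> i & 1))
    return out


def _split_candidates_subset(
    x: np.ndarray,
    y: np.ndarray,
    n_cats: int,
    N0: float,
    N1: float,
    min_child: int,
    max_exhaustive: int,
):
    ok = ~np.isnan(x)
    xs = x[ok].astype(int)
    ys = y[ok]
    if xs.size < 2 * min_child:
        return None
    c1 = np.bincount(xs, weights=ys.astype(float), minlength=n_cats)
    ct = np.bincount(xs, minlength=n_cats)
    c0 = ct - c1
    present = np.flatnonzero(ct > 0)
    if present.size < 2:
        return None
    n0, n1 = float(c0.sum()), float(c1.sum())
    mP = _mass(n0, n1, N0, N1)
    parent_g = _gini_vec(np.array([n0]), np.array([n1]), N0, N1)[0]

    if present.size <= max_exhaustive:
        subsets = [tuple(present[list(s)]) for s in _subset_masks(present.size)]
    else:  # order categories by priors-adjusted event rate, scan ordered cuts
        rate = (0.5 * c1[present] / N1) / _mass(c0[present], c1[present], N0, N1)
        order = present[np.argsort(rate, kind="stable")]
        subsets = [tuple(order[: i + 1]) for i in range(order.size - 1)]

    best = None
    for cats in subsets:
        sel = list(cats)
        nL0, nL1 = float(c0[sel].sum()), float(c1[sel].sum())
        nR0, nR1 = n0 - nL0, n1 - nL1
        if (nL0 + nL1) < min_child or (nR0 + nR1) < min_child:
            continue
        mL = _mass(nL0, nL1, N0, N1)
        mR = _mass(nR0, nR1, N0, N1)
        gain = (
            parent_g
            - (mL / mP) * _gini_vec(np.array([nL0]), np.array([nL1]), N0, N1)[0]
            - (mR / mP) * _gini_vec(np.array([nR0]), np.array([nR1]), N0, N1)[0]
        )
        if best is None or gain > best[1] + _EPS:
            best = (frozenset(int(c) for c in cats), gain)
    if best is None:
        return None
    return best[0], float(best[1]), float(mP)


def best_split(
    columns: Sequence[PredictorColumn],
    y: np.ndarray,
    idx: np.ndarray,
    root_totals: tuple[int, int],
    params: CartParams,
) -> tuple[Split, float, float] | None:
    """Exhaustive best split at a node.

    Returns ``(split, gain, mass_weighted_decrease)`` maximizing the
    priors-weighted impurity decrease, or ``None`` when no admissible split
    improves impurity.  Ties break on predictor order, then on the lower
    threshold / earlier subset in the canonical enumeration.
    """
    N0, N1 = float(root_totals[0]), float(root_totals[1])
    if N0 <= 0 or N1 <= 0:
        return None  # degenerate priors: a constant outcome admits no split
    yy = y[idx]
    best: tuple[Split, float, float] | None = None
    for col in columns:
        x = col.values[idx]
        if col.is_nominal:
            res = _split_candidates_subset(
                x, yy, len(col.categories), N0, N1, params.min_child,
                params.max_exhaustive_categories,
            )
            if res is None:
                continue
            left_codes, gain, mP = res
            labels = tuple(col.categories[c] for c in sorted(left_codes))
            split = Split(col.name, left_codes=left_codes, left_labels=labels)
        else:
            res = _split_candidates_threshold(x, yy, N0, N1, params.min_child)
            if res is None:
                continue
            thr, gain, mP = res
            split = Split(col.name, threshold=thr)
        if gain > _EPS and (best is None or gain > best[1] + _EPS):
            best = (split, gain, mP * gain)
    return best


# --------------------------------------------------------------------------
# surrogates
# --------------------------------------------------------------------------


def _surrogate_for_column(
    col: PredictorColumn,
    x: np.ndarray,
    went_left: np.ndarray,
    N0: float,
    N1: float,
    y: np.ndarray,
) -> tuple[Split, float, float] | None:
    """Best agreement split of one column against the primary direction."""
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        return None
    xs, d = x[ok], went_left[ok]
    n = xs.size
    nL = int(d.sum())
    nR = n - nL
    if nL == 0 or nR == 0:
        return None
    if col.is_nominal:
        n_cats = len(col.categories)
        codes = xs.astype(int)
        left_by_cat = np.bincount(codes, weights=d.astype(float), minlength=n_cats)
        tot_by_cat = np.bincount(codes, minlength=n_cats)
        present = np.flatnonzero(tot_by_cat > 0)
        # each category to its majority primary direction (ties go left)
        left_cats = [int(c) for c in present if left_by_cat[c] * 2 >= tot_by_cat[c]]
        if not left_cats or len(left_cats) == len(present):
            return None
        right_cats = [int(c) for c in present if c not in set(left_cats)]
        agree = int(
            left_by_cat[left_cats].sum()
            + (tot_by_cat[right_cats] - left_by_cat[right_cats]).sum()
        )
        split = Split(
            col.name,
            left_codes=frozenset(left_cats),
            left_labels=tuple(col.categories[c] for c in sorted(left_cats)),
        )
    else:
        order = np.argsort(xs, kind="stable")
        xo, do = xs[order], d[order]
        boundary = np.flatnonzero(np.diff(xo) > 0)
        if boundary.size == 0:
            return None
        cumL = np.cumsum(do)
        agreeL = cumL[boundary] + (nR - (boundary + 1 - cumL[boundary]))  # x<=c -> L
        agreeR = n - agreeL  # flipped orientation
        j_l, j_r = int(np.argmax(agreeL)), int(np.argmax(agreeR))
        if agreeL[j_l] >= agreeR[j_r]:
            j, agree, flip = j_l, int(agreeL[j_l]), False
        else:
            j, agree, flip = j_r, int(agreeR[j_r]), True
        thr = 0.5 * (xo[boundary[j]] + xo[boundary[j] + 1])
        split = Split(col.name, threshold=float(thr), flipped=flip)
    p_miss = 1.0 - agree / n
    min_side = min(nL, nR) / n
    assoc = (min_side - p_miss) / min_side
    if assoc <= 0:
        return None
    # the surrogate split's own impurity decrease (for importance attribution)
    go = np.array([split.goes_left(v) for v in xs])
    yy = y[ok]
    nL0 = int(np.sum(go & ~yy)); nL1 = int(np.sum(go & yy))
    nR0 = int(np.sum(~go & ~yy)); nR1 = int(np.sum(~go & yy))
    decrease = 0.0
    if (nL0 + nL1) > 0 and (nR0 + nR1) > 0:
        n0, n1 = nL0 + nR0, nL1 + nR1
        mP = _mass(n0, n1, N0, N1)
        mL = _mass(nL0, nL1, N0, N1)
        mR = _mass(nR0, nR1, N0, N1)
        gain = (
            _gini_vec(np.array([n0]), np.array([n1]), N0, N1)[0]
            - (mL / mP) * _gini_vec(np.array([nL0]), np.array([nL1]), N0, N1)[0]
            - (mR / mP) * _gini_vec(np.array([nR0]), np.array([nR1]), N0, N1)[0]
        )
        decrease = float(mP * max(gain, 0.0))
    return split, float(assoc), decrease


def _find_surrogates(
    columns: Sequence[PredictorColumn],
    y: np.ndarray,
    idx: np.ndarray,
    primary: Split,
    root_totals: tuple[int, int],
    top: int,
) -> tuple[Surrogate, ...]:
    N0, N1 = float(root_totals[0]), float(root_totals[1])
    primary_col = next(c for c in columns if c.name == primary.variable)
    xprim = primary_col.values[idx]
    routed = np.array([primary.goes_left(v) for v in xprim], dtype=object)
    usable = routed != None  # noqa: E711 — None marks missing-on-primary
    if usable.sum() == 0:
        return ()
    went_left = routed[usable].astype(bool)
    sub_idx = idx[usable]
    out = []
    for col in columns:
        if col.name == primary.variable:
            continue
        res = _surrogate_for_column(
            col, col.values[sub_idx], went_left, N0, N1, y[sub_idx]
        )
        if res is not None:
            out.append(Surrogate(res[0], res[1], res[2]))
    out.sort(key=lambda s: -s.association)
    return tuple(out[:top])


# --------------------------------------------------------------------------
# growing
# --------------------------------------------------------------------------


def grow(
    columns: Sequence[PredictorColumn],
    y: np.ndarray,
    params: CartParams | None = None,
    root_totals: tuple[int, int] | None = None,
    idx: np.ndarray | None = None,
    with_surrogates: bool = True,
) -> Tree:
    """Grow the maximal tree by recursive partitioning.

    Splitting stops at purity, ``min_node``, ``max_depth``, or when no
    admissible split improves impurity.  A constant outcome yields a
    single-node tree.
    """
    params = params or CartParams()
    if idx is None:
        idx = np.arange(y.size)
    n1_root = int(y[idx].sum())
    n0_root = int(idx.size - n1_root)
    if root_totals is None:
        root_totals = (n0_root, n1_root)
    baseline = n1_root / idx.size
    counter = [0]

    def build(sub: np.ndarray, depth: int) -> TreeNode:
        node_id = counter[0]
        counter[0] += 1
        n1 = int(y[sub].sum())
        n = int(sub.size)
        node = TreeNode(
            node_id=node_id,
            depth=depth,
            n_total=n,
            n_positive=n1,
            event_rate=n1 / n,
        )
        node.predicted_positive = node.event_rate >= baseline
        if depth >= params.max_depth or n < params.min_node or n1 == 0 or n1 == n:
            return node
        found = best_split(columns, y, sub, root_totals, params)
        if found is None:
            return node
        split, gain, decrease = found
        col = next(c for c in columns if c.name == split.variable)
        routed = np.array([split.goes_left(v) for v in col.values[sub]], dtype=object)
        left_mask = routed == True  # noqa: E712
        right_mask = routed == False  # noqa: E712
        miss_mask = ~(left_mask | right_mask)
        node.majority_left = int(left_mask.sum()) >= int(right_mask.sum())
        if with_surrogates:
            node.surrogates = _find_surrogates(
                columns, y, sub, split, root_totals, params.n_surrogates
            )
        if miss_mask.any():
            # route missing-on-primary via surrogates, then majority direction
            for i in np.flatnonzero(miss_mask):
                case = sub[i]
                side = _route_case(columns, case, split, node.surrogates, node.majority_left)
                if side:
                    left_mask[i] = True
                else:
                    right_mask[i] = True
        left_idx, right_idx = sub[left_mask], sub[right_mask]
        if left_idx.size < params.min_child or right_idx.size < params.min_child:
            return node
        node.split = split
        node.gini_decrease = decrease
        node.left = build(left_idx, depth + 1)
        node.right = build(right_idx, depth + 1)
        return node

    root = build(np.asarray(idx), 0)
    names = tuple(c.name for c in columns)
    return Tree(root, root_totals, names, params)


def _route_case(
    columns: Sequence[PredictorColumn],
    case: int,
    split: Split,
    surrogates: tuple[Surrogate, ...],
    majority_left: bool,
) -> bool:
    col = next(c for c in columns if c.name == split.variable)
    side = split.goes_left(col.values[case])
    if side is not None:
        return side
    for s in surrogates:
        scol = next(c for c in columns if c.name == s.split.variable)
        side = s.split.goes_left(scol.values[case])
        if side is not None:
            return side
    return majority_left


def predict(
    tree: Tree,
    columns: Sequence[PredictorColumn],
    idx: np.ndarray,
    pruned: frozenset[int] = frozenset(),
) -> np.ndarray:
    """Predicted outcome for each case, routing missing values by surrogates."""
    out = np.empty(idx.size, dtype=bool)
    for i, case in enumerate(np.asarray(idx)):
        node = tree.root
        while node.split is not None and node.node_id not in pruned:
            side = _route_case(columns, case, node.split, node.surrogates, node.majority_left)
            node = node.left if side else node.right
        out[i] = predict_node(node, tree.root)
    return out


def predict_node(node: TreeNode, root: TreeNode) -> bool:
    """Terminal prediction: positive iff the node event rate reaches the
    baseline (root) event rate — the equal-priors decision boundary."""
    return node.event_rate >= root.event_rate


def node_rate(n_positive: int, n_total: int) -> float:
    """Percentage 100·n_positive/n_total, half-up to one decimal.

    Computed in double precision before rounding, matching how node
    statistics are conventionally reported.
    """
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    value = 100.0 * n_positive / n_total
    return float(Decimal(value).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# cost-complexity pruning
# --------------------------------------------------------------------------


def _node_risk(node: TreeNode, root_totals: tuple[int, int]) -> float:
    """Priors-weighted resubstitution risk of the node as a leaf."""
    N0, N1 = float(root_totals[0]), float(root_totals[1])
    n1 = node.n_positive
    n0 = node.n_total - n1
    m = _mass(n0, n1, N0, N1)
    p1 = (0.5 * n1 / N1) / m if m > 0 else 0.0
    return float(m * min(p1, 1.0 - p1))


def prune_sequence(tree: Tree) -> list[tuple[float, frozenset[int]]]:
    """Minimal cost-complexity pruning: the nested weakest-link sequence.

    Returns ``[(alpha_0 = 0, pruned_0), …, (alpha_M, prune-to-root)]`` with
    non-decreasing complexity parameters; each ``pruned`` is the set of node
    ids collapsed into leaves.  All nodes attaining the minimal link strength
    collapse together.
    """
    risks = {n.node_id: _node_risk(n, tree.root_totals) for n in tree.root.walk()}
    ancestors: dict[int, set[int]] = {}

    def index(node: TreeNode, anc: set[int]) -> None:
        ancestors[node.node_id] = set(anc)
        if node.split is not None:
            index(node.left, anc | {node.node_id})
            index(node.right, anc | {node.node_id})

    index(tree.root, set())
    seq: list[tuple[float, frozenset[int]]] = [(0.0, frozenset())]
    pruned: set[int] = set()

    def subtree_stats(node: TreeNode) -> tuple[float, int]:
        if node.is_leaf or node.node_id in pruned:
            return risks[node.node_id], 1
        rl, ll = subtree_stats(node.left)
        rr, lr = subtree_stats(node.right)
        return rl + rr, ll + lr

    while True:
        internal = [
            n
            for n in tree.root.walk()
            if n.split is not None
            and n.node_id not in pruned
            and not (ancestors[n.node_id] & pruned)
        ]
        if not internal:
            break
        links = []
        for n in internal:
            r_sub, leaves = subtree_stats(n)
            g = (risks[n.node_id] - r_sub) / max(leaves - 1, 1)
            links.append((g, n.node_id))
        g_min = min(g for g, _ in links)
        collapse = {nid for g, nid in links if g <= g_min + 1e-12}
        pruned |= collapse
        canonical = {nid for nid in pruned if not (ancestors[nid] & pruned)}
        seq.append((max(g_min, 0.0), frozenset(canonical)))
    return seq


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------


@dataclass
class CvResult:
    alphas: tuple[float, ...]
    cv_error: tuple[float, ...]
    selected: int  # index into the pruning sequence
    seed: int

    @property
    def selected_alpha(self) -> float:
        return self.alphas[self.selected]

    @property
    def selected_error(self) -> float:
        return self.cv_error[self.selected]


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Outcome-stratified fold labels, near-equal sizes."""
    if y.size < n_folds:
        raise ValueError(f"need at least {n_folds} cases for {n_folds}-fold CV")
    fold = np.empty(y.size, dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % n_folds
    return fold


def _weighted_misclass(
    y_true: np.ndarray, y_pred: np.ndarray, root_totals_val: tuple[int, int]
) -> float:
    """Equal-priors misclassification: the mean of the two class error rates."""
    n0, n1 = root_totals_val
    err0 = np.sum(~y_true & y_pred) / n0 if n0 else 0.0
    err1 = np.sum(y_true & ~y_pred) / n1 if n1 else 0.0
    return float(0.5 * err0 + 0.5 * err1)


def cross_validate(
    columns: Sequence[PredictorColumn],
    y: np.ndarray,
    params: CartParams | None = None,
    seed: int = 0,
) -> tuple[Tree, list[tuple[float, frozenset[int]]], CvResult]:
    """Grow, prune, and select the subtree by 10-fold cross-validation.

    The data are divided into outcome-stratified folds (seeded); for each
    complexity value (geometric midpoints of the main sequence's alphas) the
    priors-weighted misclassification is averaged over held-out folds; the
    subtree with minimal CV error is selected, ties resolved toward the
    smaller tree.  Deterministic for a fixed seed.
    """
    params = params or CartParams()
    if y.size < 2 * params.n_folds:
        raise ValueError("too few cases for cross-validation")
    tree = grow(columns, y, params)
    seq = prune_sequence(tree)
    alphas = [a for a, _ in seq]
    # geometric-midpoint evaluation points
    evals = []
    for m in range(len(alphas)):
        if m + 1 < len(alphas):
            evals.append(math.sqrt(max(alphas[m], 0.0) * max(alphas[m + 1], 0.0)))
        else:
            evals.append(math.inf)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, params.n_folds, rng)
    errors = np.zeros((params.n_folds, len(seq)))
    for f in range(params.n_folds):
        train = np.flatnonzero(fold != f)
        val = np.flatnonzero(fold == f)
        ft = grow(columns, y, params, idx=train, with_surrogates=True)
        fseq = prune_sequence(ft)
        n0v = int(np.sum(~y[val]))
        n1v = int(np.sum(y[val]))
        for m, a_eval in enumerate(evals):
            # subtree of the fold sequence whose alpha interval covers a_eval
            choice = fseq[0][1]
            for a_f, pruned_f in fseq:
                if a_f <= a_eval or math.isclose(a_f, a_eval, rel_tol=1e-9):
                    choice = pruned_f
                else:
                    break
            pred = predict(ft, columns, val, choice)
            errors[f, m] = _weighted_misclass(y[val], pred, (n0v, n1v))
    cv_err = errors.mean(axis=0)
    # minimal error; ties toward the smaller tree (later sequence index)
    best_m = 0
    for m in range(len(seq)):
        if cv_err[m] < cv_err[best_m] - 1e-12 or (
            abs(cv_err[m] - cv_err[best_m]) <= 1e-12 and m > best_m
        ):
            best_m = m
    if params.se_rule > 0:
        se = float(errors[:, best_m].std(ddof=1) / math.sqrt(params.n_folds))
        limit = cv_err[best_m] + params.se_rule * se
        for m in range(len(seq) - 1, best_m, -1):
            if cv_err[m] <= limit + 1e-12:
                best_m = m
                break
    result = CvResult(tuple(alphas), tuple(float(e) for e in cv_err), best_m, seed)
    return tree, seq, result


# --------------------------------------------------------------------------
# importance and the model suite
# --------------------------------------------------------------------------


def importance(
    tree: Tree, pruned: frozenset[int] = frozenset()
) -> dict[str, dict[str, float]]:
    """Variable importance over the (pruned) tree.

    Raw score: summed mass-weighted Gini decreases where the variable is the
    primary splitter, plus the surrogate split's own decrease where it acts
    as a surrogate.  Rescaled so the top predictor scores exactly 100.
    """
    raw: dict[str, float] = {v: 0.0 for v in tree.predictors}

    def visit(node: TreeNode) -> None:
        if node.split is None or node.node_id in pruned:
            return
        raw[node.split.variable] += node.gini_decrease
        for s in node.surrogates:
            raw[s.split.variable] += s.gini_decrease
        visit(node.left)
        visit(node.right)

    visit(tree.root)
    top = max(raw.values(), default=0.0)
    if top <= 0:
        return {"raw": raw, "rescaled": {v: 0.0 for v in raw}}
    # r/top first so the maximum rescales to exactly 100.0
    return {"raw": raw, "rescaled": {v: 100.0 * (r / top) for v, r in raw.items()}}


@dataclass
class ModelResult:
    label: str
    excluded: tuple[str, ...]
    tree: Tree
    sequence: list[tuple[float, frozenset[int]]]
    cv: CvResult
    accuracy: float  # 1 − selected CV misclassification
    importance: dict[str, dict[str, float]]

    @property
    def selected_pruned(self) -> frozenset[int]:
        return self.sequence[self.cv.selected][1]


def model_suite(
    table: SurveyTable,
    predictors: Sequence[str],
    exclusions: Sequence[tuple[str, Sequence[str]]],
    params: CartParams | None = None,
    seed: int = 0,
    outcome: str = "diabetes",
) -> list[ModelResult]:
    """Run the grow/prune/CV pipeline once per exclusion set.

    ``exclusions`` is a list of (label, variables-to-exclude); an empty
    exclusion reproduces the single-model run.  Per-model seeds derive from
    one seed sequence so models are independently reproducible.
    """
    params = params or CartParams()
    seeds = np.random.SeedSequence(seed).spawn(len(exclusions))
    out = []
    for (label, excl), sub_ss in zip(exclusions, seeds):
        excl = tuple(excl)
        preds = [p for p in predictors if p not in set(excl)]
        if not preds:
            raise ValueError(f"model {label!r}: no predictors left after exclusion")
        cols, y = prepare_matrix(table, preds, outcome)
        sub_seed = int(sub_ss.generate_state(1)[0] % (2**31 - 1))
        tree, seq, cv = cross_validate(cols, y, params, seed=sub_seed)
        imp = importance(tree, seq[cv.selected][1])
        out.append(
            ModelResult(
                label=label,
                excluded=excl,
                tree=tree,
                sequence=seq,
                cv=cv,
                accuracy=1.0 - cv.selected_error,
                importance=imp,
            )
        )
    return out
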