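"""Top-down induction of predictive clustering trees (PCTs) for HMC.

A predictive clustering tree recursively partitions the training set; each
leaf predicts the mean of the ancestor-closed label vectors of its training
examples (a per-class membership score vector).  The quality of a candidate
binary split of a node ``U`` into children ``U1``, ``U2`` is

    h = alpha * ( Var'(U) - (|U1| Var'(U1) + |U2| Var'(U2)) / |U| )
      + (1 - alpha) * ( |U1| A_Y(U1) + |U2| A_Y(U2) ) / |U|

where ``Var'`` is the min-max normalisation of the hierarchy-weighted
class-vector variance over all candidate tests at the node, and ``A_Y`` is
the network autocorrelation statistic of each child over the training-time
example-linkage network.  With ``alpha = 1`` the heuristic degenerates to
pure (normalised) variance reduction — the classic CLUS-HMC behaviour — and
with ``alpha = 0`` to pure autocorrelation.  The network never influences
prediction: it enters only through ``A_Y`` during training.

Candidate tests are ``X <= beta`` with ``beta`` a midpoint of consecutive
distinct observed values (continuous attributes) and ``X in B`` with ``B``
grown greedily one value at a time (discrete attributes).  Splitting stops
when no candidate passes an F-test on the variance reduction, a child would
fall below the minimum leaf size, or the node is label-pure.

The module exposes two sklearn-style estimators: :class:`NetworkHMCClassifier`
(the network-aware learner) and :class:`HMCTreeClassifier` (the variance-only
baseline, which scores splits by raw variance reduction and never consults a
network).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.base import BaseEstimator

from .data import HMCDataset
from .hierarchy import ClassHierarchy
from .network import Network
from .split_stats import NEUTRAL_AUTOCORRELATION, PartitionStats, move_example

__all__ = [
    "SplitTest",
    "Leaf",
    "Split",
    "PCTModel",
    "CandidateStats",
    "TreeBuilder",
    "NetworkHMCClassifier",
    "HMCTreeClassifier",
    "build_tree",
    "f_test_accept",
    "candidate_thresholds",
    "enumerate_discrete_subsets",
]

_VAR_EPS = 1e-12


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


# ----------------------------------------------------------------------
# Split tests and tree nodes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SplitTest:
    """A binary test on one attribute.

    Continuous: route left iff ``value <= threshold``.  Discrete: route left
    iff ``value in subset`` (a non-empty proper subset of the attribute's
    active domain).  Missing values follow ``missing_left``, which records
    the child that received more non-missing training examples.
    """

    attribute: int
    name: str
    kind: str  # "continuous" | "discrete"
    threshold: Optional[float] = None
    subset: Optional[frozenset] = None
    missing_left: bool = False

    def route_left(self, value) -> bool:
        if _is_missing(value):
            return self.missing_left
        if self.kind == "continuous":
            return float(value) <= self.threshold
        return str(value) in self.subset

    def describe(self) -> str:
        if self.kind == "continuous":
            return f"{self.name} <= {self.threshold:g}"
        return f"{self.name} in {{{', '.join(sorted(self.subset))}}}"


@dataclass
class Leaf:
    prototype: np.ndarray
    n_examples: int


@dataclass
class Split:
    test: SplitTest
    left: object = None
    right: object = None


# ----------------------------------------------------------------------
# Candidate enumeration primitives
# ----------------------------------------------------------------------

def candidate_thresholds(values: Sequence[float]) -> list[float]:
    """Midpoints between consecutive distinct observed values.

    ``b`` distinct non-missing values yield ``b - 1`` thresholds, in
    ascending order.  All-identical or all-missing columns yield none.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    distinct = np.unique(arr)
    return [float((lo + hi) / 2.0) for lo, hi in zip(distinct[:-1], distinct[1:])]


def enumerate_discrete_subsets(values, score_fn) -> list[frozenset]:
    """Greedy chain of candidate value subsets for a discrete attribute.

    Starting from the single value whose split scores best under
    ``score_fn(subset) -> float | None`` (None marks an invalid split),
    values are added one at a time while the score keeps improving; the
    chain never reaches the full active domain (tests must be proper
    subsets).  Returns the recorded chain, possibly empty.
    """
    domain = []
    for v in values:
        if not _is_missing(v) and v not in domain:
            domain.append(v)
    if len(domain) < 2:
        return []
    chain: list[frozenset] = []
    current: list = []
    current_score = -np.inf
    remaining = list(domain)
    while len(remaining) > 1:
        best_v, best_s = None, None
        for v in remaining:
            s = score_fn(frozenset(current + [v]))
            if s is None:
                continue
            if best_s is None or s > best_s:
                best_v, best_s = v, s
        if best_v is None or (chain and best_s <= current_score):
            break
        current.append(best_v)
        remaining.remove(best_v)
        current_score = best_s
        chain.append(frozenset(current))
    return chain


def f_test_accept(
    var_parent: float, var_children_pooled: float, n: int, significance: float
) -> bool:
    """Accept a split iff it significantly reduces class-vector variance.

    Uses the regression-style convention of the reference PCT systems: the
    statistic ``F = (n - 2) * (Var(U) - pooled) / pooled`` (the pooled child
    variance is ``(|U1| Var(U1) + |U2| Var(U2)) / |U|``) is compared to the
    upper critical value of the F distribution with ``(1, n - 2)`` degrees
    of freedom — one parameter gained by the split, ``n - 2`` residual.  A
    zero pooled variance with a positive parent variance is a perfect split
    and is always accepted; ``n < 3`` (no residual df) rejects.  No
    reduction (``F = 0``) is rejected at every level, and acceptance is
    monotone in the significance level.
    """
    if not 0.0 < significance < 1.0:
        raise ValueError(f"significance must lie in (0, 1), got {significance}")
    if n < 2:
        raise ValueError("F-test requires at least 2 examples")
    if var_children_pooled <= _VAR_EPS:
        return var_parent > _VAR_EPS
    if n < 3:
        return False
    statistic = (n - 2) * (var_parent - var_children_pooled) / var_children_pooled
    critical = float(scipy_stats.f.isf(significance, 1, n - 2))
    return statistic > critical


# ----------------------------------------------------------------------
# The model object
# ----------------------------------------------------------------------

class PCTModel:
    """A fitted predictive clustering tree plus everything needed to apply it.

    Self-contained: holds the class hierarchy (and its declaration order),
    the training column schema, the induction parameters, and the tree.
    Serialises to/from a plain JSON document; a save → load round trip is
    bit-identical in predicted scores.
    """

    def __init__(
        self,
        hierarchy: ClassHierarchy,
        columns: list[dict],
        root,
        params: dict,
        train_log: Optional[list[dict]] = None,
    ) -> None:
        self.hierarchy = hierarchy
        self.columns = columns
        self.root = root
        self.params = dict(params)
        self.train_log = train_log or []

    # -- application ---------------------------------------------------
    def predict_row(self, values: Sequence) -> np.ndarray:
        node = self.root
        while isinstance(node, Split):
            node = node.left if node.test.route_left(values[node.test.attribute]) else node.right
        return node.prototype

    def _column_matrix(self, X) -> list[Sequence]:
        names = [c["name"] for c in self.columns]
        if isinstance(X, pd.DataFrame):
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise ValueError(f"schema mismatch: missing columns {missing}")
            return [X[n].to_numpy() for n in names]
        arr = np.asarray(X, dtype=object)
        if arr.ndim != 2 or arr.shape[1] != len(names):
            raise ValueError(
                f"schema mismatch: expected {len(names)} columns, got {arr.shape}"
            )
        return [arr[:, j] for j in range(arr.shape[1])]

    def predict(self, X) -> np.ndarray:
        """Per-class membership scores, one row per example."""
        cols = self._column_matrix(X)
        n = len(cols[0])
        out = np.empty((n, self.hierarchy.n_classes), dtype=float)
        for i in range(n):
            out[i] = self.predict_row([col[i] for col in cols])
        return out

    # -- structure -----------------------------------------------------
    @property
    def n_leaves(self) -> int:
        def count(node):
            return 1 if isinstance(node, Leaf) else count(node.left) + count(node.right)
        return count(self.root)

    @property
    def depth(self) -> int:
        def d(node):
            return 0 if isinstance(node, Leaf) else 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def structure(self) -> list[str]:
        """Deterministic textual description of the tree (tests + leaf sizes)."""
        lines: list[str] = []

        def walk(node, indent):
            if isinstance(node, Leaf):
                lines.append(f"{indent}leaf n={node.n_examples}")
            else:
                lines.append(f"{indent}{node.test.describe()}")
                walk(node.left, indent + "  ")
                walk(node.right, indent + "  ")

        walk(self.root, "")
        return lines

    # -- serialisation -------------------------------------------------
    def _node_to_dict(self, node) -> dict:
        if isinstance(node, Leaf):
            return {
                "leaf": True,
                "prototype": [float(v) for v in node.prototype],
                "n": int(node.n_examples),
            }
        t = node.test
        d = {
            "leaf": False,
            "attribute": t.attribute,
            "name": t.name,
            "kind": t.kind,
            "missing_left": t.missing_left,
            "left": self._node_to_dict(node.left),
            "right": self._node_to_dict(node.right),
        }
        if t.kind == "continuous":
            d["threshold"] = float(t.threshold)
        else:
            d["subset"] = sorted(t.subset)
        return d

    @staticmethod
    def _node_from_dict(d) -> object:
        if d["leaf"]:
            return Leaf(np.array(d["prototype"], dtype=float), d["n"])
        test = SplitTest(
            attribute=d["attribute"],
            name=d["name"],
            kind=d["kind"],
            threshold=d.get("threshold"),
            subset=frozenset(d["subset"]) if "subset" in d else None,
            missing_left=d["missing_left"],
        )
        return Split(test, PCTModel._node_from_dict(d["left"]), PCTModel._node_from_dict(d["right"]))

    def to_dict(self) -> dict:
        return {
            "format": "nhmc-pct",
            "version": 1,
            "hierarchy": self.hierarchy.to_dict(),
            "columns": self.columns,
            "params": self.params,
            "tree": self._node_to_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCTModel":
        if d.get("format") != "nhmc-pct":
            raise ValueError("not a serialized PCT model")
        return cls(
            hierarchy=ClassHierarchy.from_dict(d["hierarchy"]),
            columns=d["columns"],
            root=cls._node_from_dict(d["tree"]),
            params=d.get("params", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, separators=(",", ":"))
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PCTModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
# The builder
# ----------------------------------------------------------------------

@dataclass
class CandidateStats:
    """Raw per-candidate statistics collected before normalisation."""

    attribute: int
    kind: str
    threshold: Optional[float]
    subset: Optional[frozenset]
    n1: int
    n2: int
    var1: float
    var2: float
    a1: float = NEUTRAL_AUTOCORRELATION
    a2: float = NEUTRAL_AUTOCORRELATION


@dataclass
class _Column:
    name: str
    kind: str  # "continuous" | "discrete"
    data: np.ndarray  # float for continuous, object (str / None) for discrete
    categories: Optional[list[str]] = None


class TreeBuilder:
    """Induces one tree.  Not part of the stable API; the estimators wrap it.

    ``heuristic`` is ``"combined"`` (normalised variance reduction mixed with
    autocorrelation by ``alpha``) or ``"variance"`` (raw variance reduction
    only — the baseline scoring path, independent of the normalisation).
    """

    def __init__(
        self,
        columns: list[_Column],
        Y: np.ndarray,
        weights: np.ndarray,
        adjacency: Optional[list[list[tuple[int, float, float]]]],
        *,
        alpha: float = 0.5,
        min_leaf: int = 5,
        significance: float = 0.05,
        max_depth: Optional[int] = None,
        heuristic: str = "combined",
    ) -> None:
        self.columns = columns
        self.Y = np.asarray(Y, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        self.adjacency = adjacency
        self.alpha = float(alpha)
        self.min_leaf = int(min_leaf)
        self.significance = float(significance)
        self.max_depth = max_depth
        self.heuristic = heuristic
        self.train_log: list[dict] = []
        # A_Y is only needed when the combined heuristic gives it weight
        self._need_autocorr = heuristic == "combined" and self.alpha < 1.0

    # -- helpers -------------------------------------------------------
    def _leaf(self, idx: np.ndarray) -> Leaf:
        return Leaf(self.Y[idx].mean(axis=0), len(idx))

    def _node_partition(self, idx: np.ndarray):
        """Local adjacency (restricted to the node) and the node's stats."""
        local = {g: i for i, g in enumerate(idx)}
        adj_local: list[list[tuple[int, float, float]]] = [[] for _ in idx]
        if self.adjacency is not None and self._need_autocorr:
            for i, g in enumerate(idx):
                for j_g, w, d2 in self.adjacency[g]:
                    j = local.get(j_g)
                    if j is not None:
                        adj_local[i].append((j, w, d2))
        stats = PartitionStats(self.weights)
        stats.n = len(idx)
        stats.sum_bits = self.Y[idx].sum(axis=0)
        stats.w_sum = sum(w for nbrs in adj_local for _, w, _ in nbrs)
        stats.wd_sum = sum(w * d2 for nbrs in adj_local for _, w, d2 in nbrs)
        stats.n_edge_terms = sum(len(nbrs) for nbrs in adj_local)
        return adj_local, stats

    def _record(self, records, attribute, kind, threshold, subset, left, right):
        if left.n < self.min_leaf or right.n < self.min_leaf:
            return
        rec = CandidateStats(
            attribute=attribute,
            kind=kind,
            threshold=threshold,
            subset=subset,
            n1=left.n,
            n2=right.n,
            var1=left.variance(),
            var2=right.variance(),
        )
        if self._need_autocorr:
            rec.a1 = left.autocorrelation()
            rec.a2 = right.autocorrelation()
        records.append(rec)

    def _sweep_move(self, p, side, left, right, Yl, adj_local):
        """Move local example ``p`` from the right child to the left."""
        edges_from = []
        edges_to = []
        for j, w, d2 in adj_local[p]:
            (edges_to if side[j] else edges_from).append((w, d2))
        move_example(right, left, Yl[p], edges_from, edges_to)
        side[p] = True

    def _sweep_unmove(self, p, side, left, right, Yl, adj_local):
        edges_from = []
        edges_to = []
        for j, w, d2 in adj_local[p]:
            (edges_from if side[j] else edges_to).append((w, d2))
        move_example(left, right, Yl[p], edges_from, edges_to)
        side[p] = False

    # -- candidate enumeration ----------------------------------------
    def enumerate_candidates(self, idx: np.ndarray) -> list[CandidateStats]:
        """All candidate tests of a node with their raw child statistics.

        Continuous attributes are swept in sorted order, moving one example
        at a time from the right child to the left, so each successive
        threshold costs only the incremental update.  During scoring,
        examples with a missing value on the tested attribute sit in the
        right child; the final routing is decided by majority when the
        chosen test is applied.
        """
        idx = np.asarray(idx)
        adj_local, node_stats = self._node_partition(idx)
        Yl = self.Y[idx]
        records: list[CandidateStats] = []
        for a, col in enumerate(self.columns):
            if col.kind == "continuous":
                self._continuous_candidates(a, idx, Yl, adj_local, node_stats, records)
            else:
                self._discrete_candidates(a, idx, Yl, adj_local, node_stats, records)
        return records

    def _continuous_candidates(self, a, idx, Yl, adj_local, node_stats, records):
        vals = self.columns[a].data[idx].astype(float)
        present = np.flatnonzero(~np.isnan(vals))
        if present.size < 2:
            return
        order = present[np.argsort(vals[present], kind="stable")]
        sv = vals[order]
        if sv[0] == sv[-1]:
            return
        left = PartitionStats(self.weights)
        right = node_stats.copy()
        side = np.zeros(len(idx), dtype=bool)
        for i, p in enumerate(order):
            self._sweep_move(p, side, left, right, Yl, adj_local)
            if i + 1 < len(order) and sv[i + 1] > sv[i]:
                self._record(
                    records, a, "continuous", float((sv[i] + sv[i + 1]) / 2.0), None,
                    left, right,
                )

    def _surrogate_score(self, node_var, n, left, right):
        """Greedy criterion for discrete subset growth.

        The min-max range of the two-pass normalisation is unknown until all
        candidates exist, so subset growth uses raw variance reduction scaled
        by the node variance in place of ``Var'`` (the autocorrelation term
        is exact).
        """
        if left.n < 1 or right.n < 1:
            return None
        vr = node_var - (left.n * left.variance() + right.n * right.variance()) / n
        if self.heuristic == "variance":
            return vr
        scaled_vr = vr / node_var if node_var > _VAR_EPS else 0.0
        if not self._need_autocorr:
            return scaled_vr
        at = (left.n * left.autocorrelation() + right.n * right.autocorrelation()) / n
        return self.alpha * scaled_vr + (1.0 - self.alpha) * at

    def _discrete_candidates(self, a, idx, Yl, adj_local, node_stats, records):
        col = self.columns[a]
        vals = col.data[idx]
        groups: dict[str, list[int]] = {}
        for p, v in enumerate(vals):
            if not _is_missing(v):
                groups.setdefault(str(v), []).append(p)
        # active domain in declared category order, for determinism
        active = [c for c in col.categories if c in groups]
        if len(active) < 2:
            return
        n = len(idx)
        node_var = node_stats.variance()
        left = PartitionStats(self.weights)
        right = node_stats.copy()
        side = np.zeros(n, dtype=bool)

        def move_group(v):
            for p in groups[v]:
                self._sweep_move(p, side, left, right, Yl, adj_local)

        def unmove_group(v):
            for p in groups[v]:
                self._sweep_unmove(p, side, left, right, Yl, adj_local)

        current: list[str] = []
        current_score = -np.inf
        remaining = list(active)
        while len(remaining) > 1:
            best_v, best_s = None, None
            for v in remaining:
                move_group(v)
                s = self._surrogate_score(node_var, n, left, right)
                unmove_group(v)
                if s is not None and (best_s is None or s > best_s):
                    best_v, best_s = v, s
            if best_v is None or (current and best_s <= current_score):
                break
            move_group(best_v)
            current.append(best_v)
            remaining.remove(best_v)
            current_score = best_s
            self._record(records, a, "discrete", None, frozenset(current), left, right)

    # -- scoring -------------------------------------------------------
    def score_candidates(
        self, records: list[CandidateStats], node_var: float, n: int
    ) -> tuple[np.ndarray, float, float]:
        """Final heuristic value of every candidate (two-pass normalisation).

        Returns ``(scores, delta_min, delta_max)``; the normalisation range
        is taken over the node variance together with every candidate child
        variance, so ``Var'`` is well defined before any test is scored.
        """
        if self.heuristic == "variance":
            scores = np.array(
                [node_var - (r.n1 * r.var1 + r.n2 * r.var2) / n for r in records]
            )
            return scores, float("nan"), float("nan")
        pool = [node_var]
        for r in records:
            pool.extend((r.var1, r.var2))
        lo, hi = min(pool), max(pool)
        rng = hi - lo

        def norm(v):
            return (v - lo) / rng if rng > 0 else 0.0

        scores = np.empty(len(records))
        for i, r in enumerate(records):
            vr = norm(node_var) - (r.n1 * norm(r.var1) + r.n2 * norm(r.var2)) / n
            at = (r.n1 * r.a1 + r.n2 * r.a2) / n
            scores[i] = self.alpha * vr + (1.0 - self.alpha) * at
        return scores, lo, hi

    # -- recursion -----------------------------------------------------
    def build(self, idx: Optional[np.ndarray] = None):
        if idx is None:
            idx = np.arange(self.Y.shape[0])
        return self._node(np.asarray(idx), depth=0)

    def _split_indices(self, idx: np.ndarray, rec: CandidateStats):
        """Apply a candidate test, routing missing values to the majority child."""
        col = self.columns[rec.attribute]
        vals = col.data[idx]
        if rec.kind == "continuous":
            fv = vals.astype(float)
            miss = np.isnan(fv)
            go_left = ~miss & (fv <= rec.threshold)
        else:
            miss = np.array([_is_missing(v) for v in vals])
            go_left = ~miss & np.array([str(v) in rec.subset for v in vals])
        go_right = ~miss & ~go_left
        missing_left = int(go_left.sum()) > int(go_right.sum())
        if missing_left:
            go_left |= miss
        else:
            go_right |= miss
        return idx[go_left], idx[go_right], missing_left

    def _node(self, idx: np.ndarray, depth: int):
        n = len(idx)
        S = self.Y[idx].sum(axis=0)
        ssd = float(np.dot(self.weights, S - S**2 / n))
        node_var = ssd / n
        if (
            n < 2 * self.min_leaf
            or ssd <= _VAR_EPS
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return self._leaf(idx)
        records = self.enumerate_candidates(idx)
        if not records:
            return self._leaf(idx)
        # stopping rule: each candidate's variance reduction is F-tested and
        # failing candidates become ineligible; a leaf is made iff no test
        # significantly reduces variance.  The autocorrelation term thus
        # steers the choice *among* statistically supported splits without
        # coupling tree size to the network
        eligible = [
            i for i, r in enumerate(records)
            if f_test_accept(node_var, (r.n1 * r.var1 + r.n2 * r.var2) / n,
                             n, self.significance)
        ]
        if not eligible:
            return self._leaf(idx)
        scores, dmin, dmax = self.score_candidates(records, node_var, n)
        best = eligible[int(np.argmax(scores[eligible]))]  # ties: earliest wins
        rec = records[best]
        left_idx, right_idx, missing_left = self._split_indices(idx, rec)
        if len(left_idx) < self.min_leaf or len(right_idx) < self.min_leaf:
            return self._leaf(idx)
        col = self.columns[rec.attribute]
        test = SplitTest(
            attribute=rec.attribute,
            name=col.name,
            kind=rec.kind,
            threshold=rec.threshold,
            subset=rec.subset,
            missing_left=missing_left,
        )
        self.train_log.append(
            {
                "depth": depth,
                "n": int(n),
                "test": test.describe(),
                "h": float(scores[best]),
                "var": node_var,
                "delta_min": dmin,
                "delta_max": dmax,
                "a_left": rec.a1,
                "a_right": rec.a2,
                "n_candidates": len(records),
            }
        )
        return Split(
            test,
            self._node(left_idx, depth + 1),
            self._node(right_idx, depth + 1),
        )


# ----------------------------------------------------------------------
# Estimators
# ----------------------------------------------------------------------

def _prepare_columns(X: pd.DataFrame) -> list[_Column]:
    cols: list[_Column] = []
    for name in X.columns:
        s = X[name]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(_Column(str(name), "continuous", s.to_numpy(dtype=float)))
        else:
            vals = s.to_numpy(dtype=object)
            cats = sorted({str(v) for v in vals if not _is_missing(v)})
            norm = np.array(
                [None if _is_missing(v) else str(v) for v in vals], dtype=object
            )
            cols.append(_Column(str(name), "discrete", norm, cats))
    return cols


class NetworkHMCClassifier(BaseEstimator):
    """Network-aware predictive clustering tree for hierarchical multi-label
    classification.

    Parameters
    ----------
    alpha : float in [0, 1], default 0.5
        Mixing coefficient of the split heuristic: 1 = variance reduction
        only (the classic hierarchy-only tree learner), 0 = network
        autocorrelation only, 0.5 = equal weight.
    w0 : float in (0, 1), default 0.75
        Hierarchy weight decay used when the hierarchy is given as label
        sets (ignored when a prebuilt hierarchy object is supplied).
    min_leaf : int, default 5
        Minimum number of training examples per leaf.
    significance : float or sequence of float, default 0.05
        F-test level for the stopping rule.  A sequence triggers internal
        3-fold cross-validation that picks the level with the highest
        average AUPRC (ties go to the smaller level).
    tau : float, default 0.5
        Default binarisation threshold for :meth:`predict`.
    max_depth : int or None
        Optional hard depth cap (None = unbounded).
    random_state : int, default 0
        Seed for the internal cross-validation folds (the induction itself
        is deterministic).

    Attributes
    ----------
    model_ : PCTModel
        The fitted tree with hierarchy, schema and parameters.
    hierarchy_ : ClassHierarchy
    classes_ : list of str
        Class identifiers in declaration order.
    significance_ : float
        The F-test level actually used (after internal selection).
    train_log_ : list of dict
        Node-by-node record of chosen tests, heuristic values and the
        min-max normalisation range.
    """

    _heuristic = "combined"

    def __init__(
        self,
        alpha: float = 0.5,
        w0: float = 0.75,
        min_leaf: int = 5,
        significance=0.05,
        tau: float = 0.5,
        max_depth: Optional[int] = None,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.w0 = w0
        self.min_leaf = min_leaf
        self.significance = significance
        self.tau = tau
        self.max_depth = max_depth
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params_(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 < self.w0 < 1.0:
            raise ValueError(f"w0 must lie in (0, 1), got {self.w0}")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")

    def _coerce_labels(self, y, n, hierarchy: Optional[ClassHierarchy]):
        if hierarchy is None:
            raise ValueError("a ClassHierarchy must be supplied via hierarchy=")
        as_sets = isinstance(y, list) and (
            len(y) == 0
            or isinstance(y[0], (set, frozenset))
            or (isinstance(y[0], (list, tuple)) and all(isinstance(v, str) for v in y[0]))
        )
        if not as_sets:
            Y = np.asarray(y).astype(np.uint8)
            if Y.ndim != 2:
                raise ValueError("y must be a (n, K) bit matrix or a list of label sets")
            if Y.shape != (n, hierarchy.n_classes):
                raise ValueError(
                    f"label matrix shape {Y.shape} does not match "
                    f"({n}, {hierarchy.n_classes})"
                )
            closed = hierarchy.close_bits(Y)
            if not np.array_equal(closed, Y):
                raise ValueError("labels must be ancestor-closed (hierarchical constraint)")
            return Y
        # list of label sets
        Y = np.zeros((n, hierarchy.n_classes), dtype=np.uint8)
        for i, labels in enumerate(y):
            Y[i] = hierarchy.close(labels)
        return Y

    def fit(self, X, y, *, hierarchy: Optional[ClassHierarchy] = None,
            network: Optional[Network] = None, ids: Optional[Sequence[str]] = None):
        """Fit the tree.

        ``X`` is a DataFrame (mixed continuous/discrete, NaN = missing) or a
        2-D array; ``y`` an ancestor-closed (n, K) bit matrix or a list of
        label sets; ``hierarchy`` the class hierarchy; ``network`` the
        training-time example linkage (required when ``alpha < 1``); ``ids``
        the example identifiers the network refers to (default: row order).
        """
        self._validate_params_()
        if not isinstance(X, pd.DataFrame):
            arr = np.asarray(X)
            X = pd.DataFrame(arr, columns=[f"x{j + 1}" for j in range(arr.shape[1])])
        n = len(X)
        if n == 0:
            raise ValueError("cannot fit on an empty dataset")
        Y = self._coerce_labels(y, n, hierarchy)
        if ids is None:
            ids = [str(i) for i in range(n)]
        ids = [str(i) for i in ids]
        if self.alpha < 1.0 and self._heuristic == "combined" and network is None:
            raise ValueError(
                "a training network is required when alpha < 1; "
                "pass network=... or set alpha=1 for the variance-only learner"
            )
        columns = _prepare_columns(X)
        adjacency = None
        if network is not None and self._heuristic == "combined" and self.alpha < 1.0:
            restricted = network.restrict(ids)
            adjacency = [[] for _ in range(n)]
            Yf = Y.astype(float)
            for i, j, w in restricted.edges():
                diff = Yf[i] - Yf[j]
                d2 = float(np.dot(hierarchy.weights, diff * diff))
                adjacency[i].append((j, w, d2))
                adjacency[j].append((i, w, d2))

        significance = self.significance
        if isinstance(significance, (list, tuple, np.ndarray)):
            levels = [float(s) for s in significance]
            if len(levels) == 1:
                significance = levels[0]
            else:
                from .evaluation import select_significance

                significance = select_significance(
                    X, Y, hierarchy, levels,
                    network=network, ids=ids,
                    params=self._induction_params(),
                    seed=self.random_state,
                )
        significance = float(significance)

        builder = TreeBuilder(
            columns, Y, hierarchy.weights, adjacency,
            alpha=float(self.alpha), min_leaf=int(self.min_leaf),
            significance=significance, max_depth=self.max_depth,
            heuristic=self._heuristic,
        )
        root = builder.build()
        col_meta = [
            {"name": c.name, "kind": c.kind, "categories": c.categories}
            for c in columns
        ]
        params = dict(self._induction_params(), significance=significance,
                      heuristic=self._heuristic)
        self.model_ = PCTModel(hierarchy, col_meta, root, params, builder.train_log)
        self.hierarchy_ = hierarchy
        self.classes_ = list(hierarchy.classes)
        self.significance_ = significance
        self.train_log_ = builder.train_log
        self.n_features_in_ = len(columns)
        self.feature_names_in_ = np.array([c.name for c in columns], dtype=object)
        return self

    def _induction_params(self) -> dict:
        return {
            "alpha": float(self.alpha),
            "w0": float(self.w0),
            "min_leaf": int(self.min_leaf),
            "max_depth": self.max_depth,
        }

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise AttributeError("this estimator is not fitted yet; call fit first")

    def predict_proba(self, X) -> np.ndarray:
        """Per-class membership scores in [0, 1], shape (n, K).

        Scores are the mean label vectors of the reached leaves; along every
        hierarchy edge score(ancestor) >= score(descendant).
        """
        self._check_fitted()
        return self.model_.predict(X)

    def predict(self, X, tau: Optional[float] = None) -> np.ndarray:
        """Binary predictions at threshold ``tau`` (default ``self.tau``).

        A class is predicted iff its score exceeds ``tau``; the output is
        ancestor-closed for any scalar threshold.
        """
        from .evaluation import binarize

        scores = self.predict_proba(X)
        return binarize(scores, self.tau if tau is None else tau)

    def score(self, X, y) -> float:
        """Average per-class AUPRC (uniform weights) on (X, y)."""
        from .evaluation import evaluate

        self._check_fitted()
        Y = self._coerce_labels(y, len(X), self.hierarchy_)
        return evaluate(self.predict_proba(X), Y).average


class HMCTreeClassifier(NetworkHMCClassifier):
    """Variance-only predictive clustering tree (the network-oblivious
    baseline).

    Scores each candidate split by raw variance reduction of the
    hierarchy-weighted class vectors — no normalisation and no
    autocorrelation term — and never consults a network.  Serves as the
    independent reference the network-aware learner must reproduce at
    ``alpha = 1``.
    """

    _heuristic = "variance"

    def __init__(
        self,
        w0: float = 0.75,
        min_leaf: int = 5,
        significance=0.05,
        tau: float = 0.5,
        max_depth: Optional[int] = None,
        random_state: int = 0,
    ) -> None:
        super().__init__(
            alpha=1.0, w0=w0, min_leaf=min_leaf, significance=significance,
            tau=tau, max_depth=max_depth, random_state=random_state,
        )

    def fit(self, X, y, *, hierarchy=None, network=None, ids=None):  # noqa: D102
        return super().fit(X, y, hierarchy=hierarchy, network=None, ids=ids)


def build_tree(
    dataset: HMCDataset, network: Optional[Network], params: Optional[dict] = None
) -> PCTModel:
    """Induce a PCT from a dataset + training network; thin estimator wrapper."""
    params = dict(params or {})
    est = NetworkHMCClassifier(**params)
    est.fit(dataset.X, dataset.Y, hierarchy=dataset.hierarchy, network=network,
            ids=dataset.ids)
    return est.model_
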