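"""Class hierarchies for hierarchical multi-label classification (HMC).

Gene-function catalogues such as MIPS FunCat (a tree) and the Gene Ontology
(a DAG) organise functional classes under a subsumption partial order: an
annotation with a class implies annotation with all of its ancestors (the
*hierarchical constraint*).  This module represents such a hierarchy, encodes
per-example annotations as ancestor-closed binary label vectors, and defines
the hierarchy-weighted Euclidean distance between label vectors that all
split-quality statistics are built on.

Each class ``c`` carries a weight ``w(c) = w0 * mean_j w(parent_j(c))`` with
``w(c) = w0`` for top-level classes and ``0 < w0 < 1``, so classes deeper in
the hierarchy contribute less to the distance.  The virtual root (named
``"root"``) is not a component of label vectors: it is 1 for every example
and would carry no information.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ClassHierarchy",
    "HierarchyError",
    "parse_hierarchy",
    "weighted_squared_distance",
    "weighted_distance",
]

#: Name of the implicit virtual root in parent/child declarations.
ROOT = "root"


class HierarchyError(ValueError):
    """Raised for malformed hierarchy declarations or unknown classes."""


def weighted_squared_distance(weights: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Squared hierarchy-weighted Euclidean distance ``sum_k w_k (a_k - b_k)^2``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape != np.shape(weights):
        raise HierarchyError(
            f"label vector length mismatch: {np.shape(a)} vs {np.shape(b)} "
            f"vs {np.shape(weights)} weights"
        )
    diff = a - b
    return float(np.dot(np.asarray(weights, dtype=float), diff * diff))


def weighted_distance(weights: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Hierarchy-weighted Euclidean distance between two label vectors."""
    return float(np.sqrt(weighted_squared_distance(weights, a, b)))


class ClassHierarchy:
    """A partially ordered set of K classes with per-class weights.

    Parameters
    ----------
    classes : sequence of str
        Class identifiers in declaration order.  The order is part of the
        model contract: label vectors, prototypes and serialized models are
        all aligned with it.
    parents : mapping of str -> iterable of str
        Parents of each class.  An empty set marks a top-level class (child
        of the implicit virtual root).  DAGs (multiple parents) are allowed;
        cycles are rejected.
    w0 : float, default 0.75
        Per-level weight decay in (0, 1).  Top-level classes receive weight
        ``w0``; every other class ``w0`` times the mean of its parents'
        weights.

    Attributes
    ----------
    weights : ndarray of shape (K,)
        ``w(c)`` aligned with ``classes``.
    """

    def __init__(
        self,
        classes: Sequence[str],
        parents: Mapping[str, Iterable[str]],
        w0: float = 0.75,
    ) -> None:
        if not 0.0 < w0 < 1.0:
            raise HierarchyError(f"w0 must lie in (0, 1), got {w0!r}")
        self.classes: list[str] = [str(c) for c in classes]
        if not self.classes:
            raise HierarchyError("hierarchy must declare at least one class")
        if len(set(self.classes)) != len(self.classes):
            dup = sorted({c for c in self.classes if self.classes.count(c) > 1})
            raise HierarchyError(f"duplicate class identifiers: {dup}")
        self.index: dict[str, int] = {c: k for k, c in enumerate(self.classes)}
        self.w0 = float(w0)

        self.parents: dict[str, tuple[str, ...]] = {}
        for c in self.classes:
            ps = tuple(dict.fromkeys(str(p) for p in parents.get(c, ())))
            for p in ps:
                if p == c:
                    raise HierarchyError(f"class {c!r} declared as its own parent")
                if p not in self.index:
                    raise HierarchyError(f"undeclared parent {p!r} of class {c!r}")
            self.parents[c] = ps

        order = self._topological_order()
        self.weights = np.empty(len(self.classes), dtype=float)
        for c in order:
            ps = self.parents[c]
            if not ps:
                self.weights[self.index[c]] = self.w0
            else:
                pw = [self.weights[self.index[p]] for p in ps]
                self.weights[self.index[c]] = self.w0 * float(np.mean(pw))

        # anc[k, a] == True iff class a is an ancestor of class k (or k itself)
        K = len(self.classes)
        anc = np.eye(K, dtype=bool)
        for c in order:
            k = self.index[c]
            for p in self.parents[c]:
                anc[k] |= anc[self.index[p]]
        self._ancestor_matrix = anc
        self._children: dict[str, list[str]] = {c: [] for c in self.classes}
        for c in self.classes:
            for p in self.parents[c]:
                self._children[p].append(c)

    # ------------------------------------------------------------------
    def _topological_order(self) -> list[str]:
        indeg = {c: len(self.parents[c]) for c in self.classes}
        queue = [c for c in self.classes if indeg[c] == 0]
        order: list[str] = []
        while queue:
            c = queue.pop(0)
            order.append(c)
            for child in self.classes:
                if c in self.parents[child]:
                    indeg[child] -= 1
                    if indeg[child] == 0:
                        queue.append(child)
        if len(order) != len(self.classes):
            stuck = sorted(c for c in self.classes if c not in set(order))
            raise HierarchyError(f"cycle detected in hierarchy involving {stuck}")
        return order

    # ------------------------------------------------------------------
    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def children(self, c: str) -> list[str]:
        return list(self._children[c])

    @property
    def ancestor_matrix(self) -> np.ndarray:
        """Boolean (K, K) matrix; row k marks the ancestor-or-self set of class k."""
        return self._ancestor_matrix

    def ancestors(self, c: str) -> set[str]:
        """Strict ancestors of ``c`` (excluding ``c`` itself and the virtual root)."""
        k = self.index[c]
        return {self.classes[a] for a in np.flatnonzero(self._ancestor_matrix[k]) if a != k}

    # ------------------------------------------------------------------
    def close(self, most_specific: Iterable[str]) -> np.ndarray:
        """Ancestor closure of a set of class identifiers as a 0/1 vector.

        Idempotent: closing an already-closed set returns the same vector.
        Unknown identifiers are rejected by name.
        """
        bits = np.zeros(self.n_classes, dtype=np.uint8)
        for name in most_specific:
            k = self.index.get(str(name))
            if k is None:
                raise HierarchyError(f"unknown class identifier {name!r}")
            bits |= self._ancestor_matrix[k].astype(np.uint8)
        return bits

    def close_bits(self, bits: np.ndarray) -> np.ndarray:
        """Ancestor closure of a (possibly inconsistent) 0/1 vector or matrix."""
        bits = np.asarray(bits)
        closed = (bits.astype(bool) @ self._ancestor_matrix).astype(np.uint8)
        return closed

    def is_closed(self, bits: np.ndarray) -> bool:
        bits = np.asarray(bits, dtype=np.uint8)
        return bool(np.array_equal(self.close_bits(bits), bits))

    def most_specific(self, bits: np.ndarray) -> set[str]:
        """Classes with bit 1 none of whose children have bit 1."""
        bits = np.asarray(bits).astype(bool)
        out = set()
        for k in np.flatnonzero(bits):
            c = self.classes[k]
            if not any(bits[self.index[ch]] for ch in self._children[c]):
                out.add(c)
        return out

    # ------------------------------------------------------------------
    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Hierarchy-weighted Euclidean distance between two label vectors."""
        return weighted_distance(self.weights, a, b)

    def squared_distance(self, a: np.ndarray, b: np.ndarray) -> float:
        return weighted_squared_distance(self.weights, a, b)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "parents": {c: list(ps) for c, ps in self.parents.items() if ps},
            "w0": self.w0,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassHierarchy":
        return cls(d["classes"], dict(d.get("parents", {})), w0=float(d.get("w0", 0.75)))

    @classmethod
    def from_paths(cls, paths: Iterable[str], w0: float = 0.75) -> "ClassHierarchy":
        """Build a tree hierarchy from slash-delimited paths.

        Each path names a class by its final segment; every prefix must be
        declared by its own path (``"B/B1"`` requires ``"B"``).  Declaration
        order is the order of the paths.  DAGs cannot be expressed this way;
        use parent/child pairs instead.
        """
        classes: list[str] = []
        parents: dict[str, list[str]] = {}
        declared: set[str] = set()
        for path in paths:
            segs = [s for s in str(path).strip().split("/") if s]
            if not segs:
                raise HierarchyError(f"empty hierarchy path {path!r}")
            name = segs[-1]
            if name in declared:
                raise HierarchyError(f"class {name!r} declared twice")
            if len(segs) > 1:
                parent = segs[-2]
                if parent not in declared:
                    raise HierarchyError(
                        f"undeclared parent {parent!r} in path {path!r}"
                    )
                parents[name] = [parent]
            classes.append(name)
            declared.add(name)
        return cls(classes, parents, w0=w0)

    @classmethod
    def from_parent_child(
        cls, pairs: Iterable[tuple[str, str]], w0: float = 0.75
    ) -> "ClassHierarchy":
        """Build a hierarchy (tree or DAG) from (parent, child) pairs.

        ``"root"`` names the virtual root; its children are top-level classes.
        Declaration order is the order of first appearance as a child.
        """
        classes: list[str] = []
        parents: dict[str, list[str]] = {}
        seen: set[str] = set()
        for parent, child in pairs:
            parent, child = str(parent), str(child)
            if child == ROOT:
                raise HierarchyError('"root" cannot appear as a child')
            if child not in seen:
                classes.append(child)
                seen.add(child)
                parents[child] = []
            if parent != ROOT:
                if parent not in parents[child]:
                    parents[child].append(parent)
        for child, ps in parents.items():
            for p in ps:
                if p not in seen:
                    raise HierarchyError(f"undeclared parent {p!r} of class {child!r}")
        return cls(classes, parents, w0=w0)


def parse_hierarchy(spec, w0: float = 0.75) -> ClassHierarchy:
    """Parse a hierarchy declaration.

    ``spec`` is either an iterable of slash-delimited path strings
    (tree hierarchies, CLUS ARFF style) or an iterable of
    ``(parent, child)`` pairs with ``"root"`` as the virtual root
    (trees or DAGs).
    """
    items = list(spec)
    if not items:
        raise HierarchyError("empty hierarchy declaration")
    if all(isinstance(it, str) for it in items):
        return ClassHierarchy.from_paths(items, w0=w0)
    return ClassHierarchy.from_parent_child(items, w0=w0)
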