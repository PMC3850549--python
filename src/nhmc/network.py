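"""Example-linkage networks (protein–protein interaction surrogates).

The learner treats an undirected, weighted graph over example identifiers as
background knowledge: edges enter the split heuristic during training and are
never consulted at prediction time.  Edge lists use the de-facto interchange
format of PPI exports — whitespace-delimited ``u v [w]`` lines with ``#``
comments — and can be read either with their weights or binarised (all
weights forced to 1), the setting used for the main experiments.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = ["Network", "RestrictedNetwork", "load_edgelist"]

log = logging.getLogger(__name__)


class Network:
    """Undirected weighted graph over example identifiers.

    Backed by a :class:`networkx.Graph`; weights are strictly positive, an
    absent pair means weight zero, self-loops are dropped and duplicate edges
    are merged keeping the maximum weight.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # ------------------------------------------------------------------
    def add_edge(self, u: str, v: str, w: float = 1.0) -> None:
        u, v = str(u), str(v)
        if u == v:
            log.warning("dropping self-loop on node %r", u)
            return
        w = float(w)
        if w <= 0:
            raise ValueError(f"edge weight must be positive, got {w} for ({u}, {v})")
        if self.graph.has_edge(u, v):
            self.graph[u][v]["weight"] = max(self.graph[u][v]["weight"], w)
        else:
            self.graph.add_edge(u, v, weight=w)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        d = self.graph.get_edge_data(str(u), str(v))
        return float(d["weight"]) if d else 0.0

    def degree(self, u: str) -> int:
        u = str(u)
        return int(self.graph.degree[u]) if u in self.graph else 0

    # ------------------------------------------------------------------
    @classmethod
    def from_edgelist(cls, source, mode: str = "binary") -> "Network":
        """Read a whitespace-delimited edge list.

        Parameters
        ----------
        source : path or iterable of str
            Lines of the form ``u v [w]``; ``#`` starts a comment; a missing
            third column means weight 1.
        mode : {"binary", "weighted"}
            ``"binary"`` forces every weight to 1 (the default experimental
            setting); ``"weighted"`` keeps the declared weights.
        """
        if mode not in ("binary", "weighted"):
            raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")
        if isinstance(source, (str, Path)):
            lines = Path(source).read_text().splitlines()
        else:
            lines = list(source)
        net = cls()
        for lineno, raw in enumerate(lines, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"malformed edge line {lineno}: {raw!r}")
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(f"malformed weight on line {lineno}: {raw!r}") from None
            else:
                w = 1.0
            if w <= 0:
                raise ValueError(f"non-positive weight on line {lineno}: {raw!r}")
            if mode == "binary":
                w = 1.0
            if u == v:
                log.warning("line %d: dropping self-loop on node %r", lineno, u)
                continue
            net.add_edge(u, v, w)
        return net

    def to_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, w in sorted(self.edges()):
                fh.write(f"{u}\t{v}\t{w:g}\n")

    # ------------------------------------------------------------------
    def restrict(self, ids: Sequence[str]) -> "RestrictedNetwork":
        """Restrict the network to an ordered id list, re-indexed by position.

        Edges with either endpoint outside ``ids`` contribute nothing; the
        returned lookup is symmetric with a zero diagonal.
        """
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise ValueError("ids passed to restrict must be unique")
        pos = {u: i for i, u in enumerate(ids)}
        adj: list[list[tuple[int, float]]] = [[] for _ in ids]
        dropped = 0
        for u, v, w in self.edges():
            iu, iv = pos.get(u), pos.get(v)
            if iu is None or iv is None:
                dropped += 1
                continue
            adj[iu].append((iv, w))
            adj[iv].append((iu, w))
        if dropped:
            log.info("restrict: %d edges fall outside the %d given ids", dropped, len(ids))
        return RestrictedNetwork(len(ids), adj)

    def degree_filter(self, ids: Iterable[str], min_degree: int = 15) -> list[str]:
        """Ids with at least ``min_degree`` incident edges (highly connected).

        The default threshold of 15 interactions mirrors the standard
        highly-connected-gene setting; the complement of the returned subset
        is the weakly connected part.
        """
        if min_degree < 0:
            raise ValueError("min_degree must be >= 0")
        return [str(i) for i in ids if self.degree(str(i)) >= min_degree]

    # ------------------------------------------------------------------
    def stats(self, labels: Mapping[str, np.ndarray]) -> dict[str, float]:
        """Coverage descriptors of the network relative to a labelled dataset.

        Returns ``pct_connected`` (% of dataset ids with degree >= 1),
        ``pct_function_relevant`` (% of intra-dataset edges whose endpoints
        share at least one annotated class — the virtual root, being shared
        trivially, is not a component of the label vectors) and
        ``avg_degree`` (mean degree over dataset ids).
        """
        if not labels:
            raise ValueError("empty dataset: no labelled ids")
        ids = list(labels)
        degrees = np.array([self.degree(i) for i in ids], dtype=float)
        inside = 0
        relevant = 0
        for u, v, _w in self.edges():
            if u in labels and v in labels:
                inside += 1
                if np.any(np.asarray(labels[u], bool) & np.asarray(labels[v], bool)):
                    relevant += 1
        extra = len(self.nodes - set(ids))
        if extra:
            log.info("stats: %d network nodes are absent from the dataset", extra)
        return {
            "pct_connected": 100.0 * float(np.mean(degrees >= 1)),
            "pct_function_relevant": 100.0 * relevant / inside if inside else 0.0,
            "avg_degree": float(np.mean(degrees)),
            "n_edges_in_dataset": float(inside),
        }


class RestrictedNetwork:
    """Adjacency over positional indices of an id partition.

    ``adj[i]`` lists ``(j, w)`` neighbours of index ``i``; ``weight(i, j)``
    is symmetric and zero on the diagonal and for absent pairs.
    """

    def __init__(self, n: int, adj: list[list[tuple[int, float]]]) -> None:
        self.n = n
        self.adj = adj

    def weight(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        for k, w in self.adj[i]:
            if k == j:
                return w
        return 0.0

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        return self.adj[i]

    def edges(self):
        """Unordered edges (i, j, w) with i < j."""
        for i, nbrs in enumerate(self.adj):
            for j, w in nbrs:
                if i < j:
                    yield i, j, w


def load_edgelist(path, mode: str = "binary") -> Network:
    """Module-level convenience wrapper over :meth:`Network.from_edgelist`."""
    return Network.from_edgelist(path, mode=mode)
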