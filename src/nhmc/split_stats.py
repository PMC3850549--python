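"""Split-quality statistics: class-vector variance and network autocorrelation.

Two quantities score a candidate partition of training examples:

* the **variance** of the hierarchy-weighted label vectors,
  ``Var(U) = (1/|U|) * sum_i d(L_i, Lbar)^2``, which a tree learner reduces
  to obtain homogeneous leaves; and
* the **network autocorrelation** ``A_Y(U)``, an HMC adaptation of Geary's C
  over the example-linkage network,

  ``A_Y(U) = 1 - ((N-1) * sum_ij w_ij d(L_i,L_j)^2)
                 / (4 * sum_ij w_ij * sum_i d(L_i, Lbar)^2)``,

  which lives on [0, 1] with 1 = strong positive autocorrelation
  (linked examples share labels), 0.5 = none, 0 = strong negative.

Both are maintained incrementally while candidate splits sweep examples from
one child to the other, via :class:`PartitionStats`.  Because label vectors
are binary, the within-partition scatter has the exact closed form
``ssd = sum_k w_k * S_k * (1 - S_k/n)`` in terms of the per-class bit sums
``S_k``, so one-example moves cost O(K + degree).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np

from .hierarchy import weighted_squared_distance

__all__ = [
    "PartitionStats",
    "move_example",
    "minmax_normalize",
    "network_autocorrelation",
    "NEUTRAL_AUTOCORRELATION",
]

log = logging.getLogger(__name__)

#: A_Y value reported for unsupported partitions (no intra-partition edges,
#: fewer than two examples, or zero label scatter): the "no autocorrelation"
#: point of the statistic, so the heuristic neither rewards nor punishes them.
NEUTRAL_AUTOCORRELATION = 0.5

_SSD_EPS = 1e-12


class PartitionStats:
    """Sufficient statistics of one partition of labelled, networked examples.

    Fields
    ------
    n : int
        Number of examples in the partition.
    sum_bits : ndarray of shape (K,)
        Per-class sums of label bits (``S_k``); ``sum_bits / n`` is the mean
        label vector (the leaf prototype).
    w_sum : float
        ``sum_i sum_j w_ij`` over *ordered* intra-partition pairs (each edge
        counted twice, matching the double sums of the statistic).
    wd_sum : float
        ``sum_i sum_j w_ij * d(L_i, L_j)^2`` over ordered intra-partition
        pairs.
    """

    __slots__ = ("weights", "n", "sum_bits", "w_sum", "wd_sum", "n_edge_terms")

    def __init__(self, weights: np.ndarray) -> None:
        self.weights = np.asarray(weights, dtype=float)
        self.n = 0
        self.sum_bits = np.zeros(self.weights.shape[0], dtype=float)
        self.w_sum = 0.0
        self.wd_sum = 0.0
        # exact count of ordered intra-partition edge terms; guards the
        # degeneracy test against floating-point residue in w_sum
        self.n_edge_terms = 0

    # ------------------------------------------------------------------
    @classmethod
    def from_labels(
        cls,
        weights: np.ndarray,
        Y: np.ndarray,
        edges: Iterable[tuple[int, int, float]] = (),
    ) -> "PartitionStats":
        """Build from scratch from a (n, K) bit matrix and unordered edges."""
        stats = cls(weights)
        Y = np.asarray(Y, dtype=float)
        stats.n = Y.shape[0]
        stats.sum_bits = Y.sum(axis=0)
        for i, j, w in edges:
            d2 = weighted_squared_distance(stats.weights, Y[i], Y[j])
            stats.w_sum += 2.0 * w
            stats.wd_sum += 2.0 * w * d2
            stats.n_edge_terms += 2
        return stats

    def copy(self) -> "PartitionStats":
        other = PartitionStats(self.weights)
        other.n = self.n
        other.sum_bits = self.sum_bits.copy()
        other.w_sum = self.w_sum
        other.wd_sum = self.wd_sum
        other.n_edge_terms = self.n_edge_terms
        return other

    # ------------------------------------------------------------------
    @property
    def mean(self) -> np.ndarray:
        if self.n == 0:
            raise ValueError("mean of an empty partition is undefined")
        return self.sum_bits / self.n

    @property
    def ssd(self) -> float:
        """Within-partition weighted scatter ``sum_i d(L_i, Lbar)^2``.

        Exact for binary bits: per class, ``sum_i (L_ik - mean_k)^2
        = S_k - S_k^2 / n``.
        """
        if self.n == 0:
            return 0.0
        per_class = self.sum_bits - self.sum_bits**2 / self.n
        return float(np.dot(self.weights, per_class))

    def variance(self) -> float:
        """``Var(U) = ssd / n``; requires a non-empty partition."""
        if self.n < 1:
            raise ValueError("variance of an empty partition is undefined")
        return self.ssd / self.n

    def autocorrelation(self) -> float:
        """The HMC Geary-style statistic ``A_Y`` of this partition.

        Degenerate partitions (no intra-partition edges, a single example,
        or zero label scatter) return the neutral value 0.5.  The raw
        formula can leave [0, 1] on adversarial weight configurations; the
        result is clamped to the stated range (clamping is logged).
        """
        ssd = self.ssd
        if self.n < 2 or self.n_edge_terms == 0 or self.w_sum <= 0.0 or ssd <= _SSD_EPS:
            return NEUTRAL_AUTOCORRELATION
        a = 1.0 - ((self.n - 1) * self.wd_sum) / (4.0 * self.w_sum * ssd)
        if a < 0.0 or a > 1.0:
            log.debug("clamping A_Y=%g into [0, 1]", a)
            a = min(1.0, max(0.0, a))
        return a

    # ------------------------------------------------------------------
    def add_example(
        self, bits: np.ndarray, intra_edges: Iterable[tuple[float, float]] = ()
    ) -> None:
        """Add one example; ``intra_edges`` lists ``(w, d2)`` terms to current members."""
        self.n += 1
        self.sum_bits += bits
        for w, d2 in intra_edges:
            self.w_sum += 2.0 * w
            self.wd_sum += 2.0 * w * d2
            self.n_edge_terms += 2

    def remove_example(
        self, bits: np.ndarray, intra_edges: Iterable[tuple[float, float]] = ()
    ) -> None:
        """Remove one example; ``intra_edges`` lists its ``(w, d2)`` terms to the
        remaining members."""
        if self.n < 1:
            raise ValueError("cannot remove an example from an empty partition")
        self.n -= 1
        self.sum_bits -= bits
        for w, d2 in intra_edges:
            self.w_sum -= 2.0 * w
            self.wd_sum -= 2.0 * w * d2
            self.n_edge_terms -= 2
        if self.n == 0:
            self.sum_bits[:] = 0.0
        if self.n == 0 or self.n_edge_terms == 0:
            # guard against floating residue once no edges remain
            self.w_sum = 0.0
            self.wd_sum = 0.0


def move_example(
    frm: PartitionStats,
    to: PartitionStats,
    bits: np.ndarray,
    edges_from: Iterable[tuple[float, float]] = (),
    edges_to: Iterable[tuple[float, float]] = (),
) -> tuple[PartitionStats, PartitionStats]:
    """Move one example between partitions, updating both stat blocks in place.

    ``edges_from`` lists the example's ``(w, d2)`` edge terms to members that
    stay in ``frm``; ``edges_to`` those to current members of ``to``.  Cost is
    O(K + degree).
    """
    frm.remove_example(bits, edges_from)
    to.add_example(bits, edges_to)
    return frm, to


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Min-max normalisation ``(v - min) / (max - min)`` onto [0, 1].

    A degenerate range (all values equal) maps everything to 0, so a node
    where every candidate leaves the variance unchanged scores no
    variance-reduction credit.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("minmax_normalize requires a non-empty list")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def network_autocorrelation(weights, Y, network, ids) -> float:
    """``A_Y`` of a full labelled dataset over its linkage network.

    Parameters
    ----------
    weights : ndarray (K,) or ClassHierarchy
        Per-class hierarchy weights (a hierarchy object is accepted).
    Y : ndarray (n, K)
        Ancestor-closed binary label matrix aligned with ``ids``.
    network : Network
        The example-linkage network; edges to ids outside the dataset are
        ignored.
    ids : sequence of str
        Example identifiers aligned with the rows of ``Y``.
    """
    w = getattr(weights, "weights", weights)
    restricted = network.restrict(ids)
    stats = PartitionStats.from_labels(w, Y, restricted.edges())
    return stats.autocorrelation()
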