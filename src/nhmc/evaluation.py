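"""Prediction post-processing and precision–recall evaluation.

Membership scores produced by a PCT leaf are binarised with a threshold
``tau`` (``score > tau`` predicts the class); because leaf prototypes are
averages of ancestor-closed vectors, any scalar ``tau`` — and any per-class
threshold map that is non-decreasing from ancestors to descendants — yields
predictions satisfying the hierarchical constraint.

Evaluation follows the standard protocol for hierarchical gene-function
prediction: one precision–recall curve per class, traced by varying ``tau``
from 0 to 1 in steps of 0.02 (51 points, both endpoints included), with
precision defined as 1 when nothing is predicted positive; areas are
obtained by trapezoidal integration over recall and averaged over classes,
either uniformly (weight 1/|C| for every evaluable class) or weighted by
class frequency.  Classes without positive test examples have an undefined
PR curve and are excluded from the average (|C| counts included classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import HMCDataset
from .hierarchy import ClassHierarchy
from .network import Network

__all__ = [
    "tau_grid",
    "binarize",
    "pr_curve",
    "pr_area",
    "aupr_average",
    "evaluate",
    "EvaluationReport",
    "select_significance",
    "holdout_protocol",
]


def tau_grid(step: float = 0.02) -> np.ndarray:
    """Threshold grid from 0 to 1 inclusive (51 points at the default step)."""
    if not 0.0 < step <= 1.0:
        raise ValueError("tau step must lie in (0, 1]")
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def binarize(scores: np.ndarray, tau, hierarchy: Optional[ClassHierarchy] = None) -> np.ndarray:
    """Threshold score vectors into ancestor-consistent label vectors.

    ``tau`` is a scalar in [0, 1] or a per-class array; a per-class map must
    satisfy tau(ancestor) <= tau(descendant) on every hierarchy edge (checked
    when a hierarchy is supplied), which together with the monotonicity of
    leaf prototypes guarantees the hierarchical constraint.  A class is
    predicted iff its score strictly exceeds its threshold, so ``tau = 1``
    predicts nothing.
    """
    scores = np.asarray(scores, dtype=float)
    if np.isscalar(tau) or np.ndim(tau) == 0:
        t = float(tau)
        if not 0.0 <= t <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        return (scores > t).astype(np.uint8)
    t = np.asarray(tau, dtype=float)
    if t.shape[0] != scores.shape[-1]:
        raise ValueError("per-class tau length does not match the number of classes")
    if hierarchy is not None:
        for c in hierarchy.classes:
            k = hierarchy.index[c]
            for p in hierarchy.parents[c]:
                if t[hierarchy.index[p]] > t[k]:
                    raise ValueError(
                        f"per-class thresholds violate the ancestor condition: "
                        f"tau({p})={t[hierarchy.index[p]]} > tau({c})={t[k]}"
                    )
    return (scores > t).astype(np.uint8)


def pr_curve(
    scores: np.ndarray, truth: np.ndarray, k: int, tau_step: float = 0.02
) -> list[tuple[float, float]]:
    """(precision, recall) points for class ``k`` over the threshold grid.

    Precision at zero predicted positives is defined as 1.  Requires at
    least one positive example of the class.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    s = scores[:, k]
    pos = truth[:, k]
    P = int(pos.sum())
    if P == 0:
        raise ValueError(f"class index {k} has no positive examples")
    points = []
    for t in tau_grid(tau_step):
        pred = s > t
        pp = int(pred.sum())
        tp = int((pred & pos).sum())
        precision = tp / pp if pp else 1.0
        recall = tp / P
        points.append((precision, recall))
    return points


def pr_area(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a PR point set.

    Points are augmented with the (recall 0, precision 1) anchor, sorted by
    recall, de-duplicated (keeping the best precision at each recall) and
    integrated over recall.
    """
    best: dict[float, float] = {0.0: 1.0}
    for precision, recall in points:
        r = float(recall)
        if r not in best or precision > best[r]:
            best[r] = float(precision)
    recalls = np.array(sorted(best))
    precisions = np.array([best[r] for r in recalls])
    if recalls.size < 2:
        return 0.0
    return float(np.trapezoid(precisions, recalls))


def aupr_average(
    areas: Sequence[float], counts: Optional[Sequence[int]] = None, mode: str = "uniform"
) -> float:
    """Average per-class AUPRC, uniform (1/|C|) or frequency-weighted."""
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("no classes to average over")
    if mode == "uniform":
        return float(areas.mean())
    if mode == "frequency":
        if counts is None:
            raise ValueError("frequency weighting requires per-class positive counts")
        w = np.asarray(counts, dtype=float)
        return float(np.dot(areas, w) / w.sum())
    raise ValueError(f"unknown weighting mode {mode!r}")


@dataclass
class EvaluationReport:
    """Per-class PR evaluation plus the averaged area."""

    per_class_area: dict[str, float]
    per_class_points: dict[str, list[tuple[float, float]]]
    per_class_positives: dict[str, int]
    average: float
    weighting: str
    n_included: int
    n_excluded: int
    tau_step: float = 0.02
    excluded_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "average_auprc": self.average,
            "weighting": self.weighting,
            "tau_step": self.tau_step,
            "n_classes_included": self.n_included,
            "n_classes_excluded": self.n_excluded,
            "excluded_classes": list(self.excluded_classes),
            "per_class_auprc": dict(self.per_class_area),
            "per_class_positives": dict(self.per_class_positives),
        }


def evaluate(
    scores: np.ndarray,
    truth: np.ndarray,
    hierarchy: Optional[ClassHierarchy] = None,
    tau_step: float = 0.02,
    weighting: str = "uniform",
    keep_points: bool = False,
) -> EvaluationReport:
    """Full PR evaluation of a score matrix against a truth bit matrix."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError(f"score shape {scores.shape} != truth shape {truth.shape}")
    K = truth.shape[1]
    names = hierarchy.classes if hierarchy is not None else [str(k) for k in range(K)]
    areas: dict[str, float] = {}
    pts: dict[str, list] = {}
    npos: dict[str, int] = {}
    excluded: list[str] = []
    for k in range(K):
        P = int(truth[:, k].sum())
        if P == 0:
            excluded.append(names[k])
            continue
        points = pr_curve(scores, truth, k, tau_step)
        areas[names[k]] = pr_area(points)
        npos[names[k]] = P
        if keep_points:
            pts[names[k]] = points
    if not areas:
        raise ValueError("no class has positive examples; nothing to evaluate")
    avg = aupr_average(
        list(areas.values()), counts=[npos[c] for c in areas], mode=weighting
    )
    return EvaluationReport(
        per_class_area=areas,
        per_class_points=pts,
        per_class_positives=npos,
        average=avg,
        weighting=weighting,
        n_included=len(areas),
        n_excluded=len(excluded),
        tau_step=tau_step,
        excluded_classes=excluded,
    )


# ----------------------------------------------------------------------
# Protocols
# ----------------------------------------------------------------------

def select_significance(
    X,
    Y,
    hierarchy: ClassHierarchy,
    levels: Sequence[float],
    *,
    network: Optional[Network] = None,
    ids: Optional[Sequence[str]] = None,
    params: Optional[dict] = None,
    folds: int = 3,
    seed: int = 0,
) -> float:
    """Pick the F-test level by internal cross-validation.

    For each candidate level an internal ``folds``-fold cross-validation is
    run on the training data and the level with the largest mean averaged
    AUPRC wins; ties go to the smaller (more conservative) level.  Folds
    come from a seeded shuffle; the network is restricted to each internal
    training part.
    """
    from .induction import NetworkHMCClassifier

    levels = sorted(float(s) for s in levels)
    if len(levels) == 1:
        return levels[0]
    n = len(X)
    if n < folds:
        raise ValueError(f"need at least {folds} examples for {folds}-fold selection")
    if ids is None:
        ids = [str(i) for i in range(n)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for pos, i in enumerate(perm):
        fold_of[i] = pos % folds
    params = dict(params or {})
    params.pop("significance", None)
    best_level, best_score = levels[0], -np.inf
    for level in levels:
        fold_scores = []
        for f in range(folds):
            tr = np.flatnonzero(fold_of != f)
            va = np.flatnonzero(fold_of == f)
            est = NetworkHMCClassifier(significance=level, **params)
            est.fit(
                X.iloc[tr] if hasattr(X, "iloc") else X[tr],
                np.asarray(Y)[tr],
                hierarchy=hierarchy,
                network=network,
                ids=[ids[i] for i in tr],
            )
            scores = est.predict_proba(X.iloc[va] if hasattr(X, "iloc") else X[va])
            truth = np.asarray(Y)[va]
            if not truth.any():
                continue
            fold_scores.append(evaluate(scores, truth, hierarchy).average)
        mean_score = float(np.mean(fold_scores)) if fold_scores else 0.0
        if mean_score > best_score:
            best_level, best_score = level, mean_score
    return best_level


def holdout_protocol(
    dataset: HMCDataset,
    network: Optional[Network],
    params: Optional[dict] = None,
    *,
    seed: int = 0,
    test_fraction: float = 1.0 / 3.0,
    train_ids: Optional[Sequence[str]] = None,
    test_ids: Optional[Sequence[str]] = None,
    tau_step: float = 0.02,
    weighting: str = "uniform",
):
    """Train on 2/3, test on the held-out 1/3 (or on user-provided id lists).

    The network is restricted to the training ids before induction, so edges
    incident to test examples never enter the training statistics.  Returns
    ``(estimator, EvaluationReport)``; a fixed seed gives an identical
    split, model and report across runs.
    """
    from .induction import NetworkHMCClassifier

    n = dataset.n_examples
    if train_ids is not None or test_ids is not None:
        if train_ids is None or test_ids is None:
            raise ValueError("provide both train_ids and test_ids, or neither")
        train = dataset.subset_ids(train_ids)
        test = dataset.subset_ids(test_ids)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_test = int(round(n * test_fraction))
        if n_test == 0 or n_test == n:
            raise ValueError("dataset too small for the requested split")
        test = dataset.subset(np.sort(perm[:n_test]))
        train = dataset.subset(np.sort(perm[n_test:]))
    est = NetworkHMCClassifier(**dict(params or {}))
    est.fit(train.X, train.Y, hierarchy=dataset.hierarchy, network=network,
            ids=train.ids)
    report = evaluate(
        est.predict_proba(test.X), test.Y, dataset.hierarchy,
        tau_step=tau_step, weighting=weighting,
    )
    return est, report
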