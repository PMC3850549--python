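"""In-memory container for hierarchically labelled tabular datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import ClassHierarchy

__all__ = ["HMCDataset"]


@dataclass
class HMCDataset:
    """Attribute matrix + ancestor-closed label matrix + example identifiers.

    ``X`` is a DataFrame with mixed continuous (float, NaN = missing) and
    discrete (object/category, NaN/None = missing) columns; ``Y`` is a
    (n, K) uint8 matrix aligned with ``hierarchy.classes``; ``ids`` are the
    example identifiers the linkage network refers to.
    """

    X: pd.DataFrame
    Y: np.ndarray
    ids: list[str]
    hierarchy: ClassHierarchy
    name: str = field(default="dataset")
    #: noise-free label matrix, populated only by the synthetic generator
    #: (ground truth behind the observed annotations); never used by learners
    Y_true: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.uint8)
        self.ids = [str(i) for i in self.ids]
        n = len(self.X)
        if self.Y.shape != (n, self.hierarchy.n_classes):
            raise ValueError(
                f"label matrix shape {self.Y.shape} does not match "
                f"{n} examples x {self.hierarchy.n_classes} classes"
            )
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} examples")
        if len(set(self.ids)) != n:
            raise ValueError("example ids must be unique")
        if self.Y_true is not None:
            self.Y_true = np.asarray(self.Y_true, dtype=np.uint8)
            if self.Y_true.shape != self.Y.shape:
                raise ValueError("Y_true shape must match Y")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_examples(self) -> int:
        return len(self.ids)

    def validate_closure(self) -> None:
        """Reject label rows that violate the hierarchical constraint."""
        closed = self.hierarchy.close_bits(self.Y)
        bad = np.flatnonzero(np.any(closed != self.Y, axis=1))
        if bad.size:
            raise ValueError(
                f"label vectors of examples {[self.ids[i] for i in bad[:5]]} "
                "are not ancestor-closed"
            )

    def subset(self, indices) -> "HMCDataset":
        indices = np.asarray(indices)
        return HMCDataset(
            X=self.X.iloc[indices].reset_index(drop=True),
            Y=self.Y[indices],
            ids=[self.ids[i] for i in indices],
            hierarchy=self.hierarchy,
            name=self.name,
            Y_true=None if self.Y_true is None else self.Y_true[indices],
        )

    def subset_ids(self, ids) -> "HMCDataset":
        pos = {u: i for i, u in enumerate(self.ids)}
        return self.subset([pos[str(u)] for u in ids])

    def labels_by_id(self) -> dict[str, np.ndarray]:
        return {u: self.Y[i] for i, u in enumerate(self.ids)}
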