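"""Flat cluster assignments over an ordered item set."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ClusterAssignment:
    """A partition of items into ``k`` clusters labelled ``0 .. k-1``.

    Labels are canonical: cluster 0 contains the smallest item index,
    cluster 1 the smallest index not in cluster 0, and so on.  Use
    :meth:`from_labels` to build one from arbitrary integer labels.
    """

    item_ids: tuple[str, ...]
    labels: np.ndarray = field(repr=False)
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.intp)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (len(self.item_ids),):
            raise ValueError("labels must have one entry per item")
        if labels.size == 0:
            raise ValueError("empty assignment")
        present = np.unique(labels)
        if present[0] != 0 or present[-1] != self.k - 1 or present.size != self.k:
            raise ValueError("labels must cover exactly 0..k-1")

    @classmethod
    def from_labels(cls, item_ids, labels) -> "ClusterAssignment":
        """Build an assignment, renumbering labels in order of smallest member index."""
        labels = np.asarray(labels)
        canon = canonical_labels(labels)
        return cls(tuple(item_ids), canon, int(canon.max()) + 1)

    @property
    def n(self) -> int:
        return len(self.item_ids)

    def clusters(self) -> list[np.ndarray]:
        """Member index arrays, one per cluster label."""
        return [np.flatnonzero(self.labels == c) for c in range(self.k)]

    def onehot(self) -> np.ndarray:
        """(n, k) float indicator matrix."""
        out = np.zeros((self.n, self.k))
        out[np.arange(self.n), self.labels] = 1.0
        return out


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber arbitrary integer labels to 0..k-1 by order of first occurrence."""
    _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first, kind="stable"), kind="stable")
    return order[inverse].astype(np.intp)
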