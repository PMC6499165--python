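"""Quality-threshold clustering of repeated stimuli and cluster consolidation.

Repeated-measures mapping protocols stimulate each scalp site several
times; before surface fitting those repeats are grouped with a
quality-threshold (QT) clustering on pairwise 3D distances, normalised
by the dataset's maximum pairwise distance so that the user-facing
threshold lives in [0, 1]: 0 keeps every event separate, 1 merges all
events into one cluster. Each cluster is then consolidated to a single
representative point by one of five operators (Table-style summary):

=========== ==================================================== ========
method      representative value                                 units
=========== ==================================================== ========
average     mean of member values                                μV
maximum     largest member value                                 μV
minimum     smallest member value                                μV
variance    population variance, Σ(v_i − μ)² / N                 μV²
probability 100 × fraction of members above the binarization     %
            threshold (default 40 μV, strict)
=========== ==================================================== ========

The consolidated position is always the unweighted mean of the member
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import MethodError
from .io import MotorMapDataset

__all__ = [
    "ClusterAssignment",
    "ConsolidatedMap",
    "CONSOLIDATION_METHODS",
    "DEFAULT_BINARIZATION_THRESHOLD_UV",
    "binarize",
    "consolidate",
    "qt_cluster",
]

#: Default μV threshold for binarizing MEPs (probability operator, ROC).
DEFAULT_BINARIZATION_THRESHOLD_UV = 40.0

CONSOLIDATION_METHODS = ("average", "maximum", "minimum", "variance", "probability")

_METHOD_UNITS = {
    "average": "uV",
    "maximum": "uV",
    "minimum": "uV",
    "variance": "uV^2",
    "probability": "%",
}


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster label per event; ids contiguous from 0 in extraction order."""

    labels: np.ndarray
    qt_threshold: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        n_clusters = labels.max() + 1 if labels.size else 0
        if sorted(set(labels.tolist())) != list(range(n_clusters)):
            raise ValueError("cluster ids must be contiguous from 0")
        object.__setattr__(self, "labels", labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass(frozen=True)
class ConsolidatedMap:
    """One representative point per cluster, in the original 3D frame.

    ``cluster_values`` keeps the raw member values of each cluster so the
    consolidation can be audited (the v_i, μ and s of the variance
    formula are recoverable from it).
    """

    points: np.ndarray
    values: np.ndarray
    method: str
    units: str
    binarization_threshold: Optional[float] = None
    cluster_values: tuple = field(default=(), repr=False)

    def __len__(self) -> int:
        return self.points.shape[0]

    def as_dataset(self, template: Optional[MotorMapDataset] = None) -> MotorMapDataset:
        """View the consolidated map as a dataset (for COG/peak on raw points)."""
        return MotorMapDataset(
            self.points,
            self.values,
            reference_point=template.reference_point if template else None,
            session_label=template.session_label if template else "",
        )


def _qt_candidate(seed: int, dsub: np.ndarray, diameter: float) -> np.ndarray:
    """Greedy QT candidate cluster grown from ``seed``.

    Starting from the seed, repeatedly add the point whose inclusion
    gives the smallest cluster diameter, while that diameter stays
    within the bound. ``dsub`` is the pairwise distance submatrix of the
    still-unassigned points; indices are into that submatrix. Returns
    the member indices.

    ``reach[i]`` tracks the max distance from point i to the current
    cluster, i.e. the diameter after adding i (ties: lowest index, via
    argmin).
    """
    n = dsub.shape[0]
    in_cluster = np.zeros(n, dtype=bool)
    in_cluster[seed] = True
    reach = dsub[:, seed].copy()
    reach[seed] = np.inf
    for _ in range(n - 1):
        best = int(np.argmin(reach))
        if reach[best] > diameter:
            break
        in_cluster[best] = True
        reach = np.maximum(reach, dsub[:, best])
        reach[best] = np.inf
    return np.flatnonzero(in_cluster)


def qt_cluster(dataset: MotorMapDataset, qt_threshold: float) -> ClusterAssignment:
    """Quality-threshold clustering on normalized pairwise 3D distances.

    Distances are divided by the maximum pairwise distance of the whole
    dataset. For every unassigned seed a candidate cluster is grown
    while its normalized diameter stays ≤ ``qt_threshold``; the largest
    candidate is extracted (ties: lowest seed index) and the procedure
    repeats on the remainder. A threshold of 0 yields all singletons; a
    threshold of 1 yields a single cluster.
    """
    if not 0.0 <= qt_threshold <= 1.0:
        raise ValueError(f"qt_threshold must be in [0, 1], got {qt_threshold}")
    n = len(dataset)
    labels = np.full(n, -1, dtype=int)
    if qt_threshold == 0.0 or n == 1:
        return ClusterAssignment(labels=np.arange(n), qt_threshold=qt_threshold)
    dmat = squareform(pdist(dataset.points))
    dmax = dmat.max()
    if dmax == 0.0:  # all events coincident
        return ClusterAssignment(labels=np.zeros(n, dtype=int), qt_threshold=qt_threshold)
    diameter = qt_threshold * dmax
    remaining = np.arange(n)
    next_label = 0
    while remaining.size:
        dsub = dmat[np.ix_(remaining, remaining)]
        best_cluster = np.empty(0, dtype=int)
        for seed in range(remaining.size):
            cand = _qt_candidate(seed, dsub, diameter)
            if cand.size > best_cluster.size:
                best_cluster = cand
            if best_cluster.size == remaining.size:
                break
        labels[remaining[best_cluster]] = next_label
        next_label += 1
        keep = np.ones(remaining.size, dtype=bool)
        keep[best_cluster] = False
        remaining = remaining[keep]
    return ClusterAssignment(labels=labels, qt_threshold=qt_threshold)


def binarize(values, threshold: float) -> np.ndarray:
    """Binarize MEP values at a μV threshold: 1 iff strictly above.

    Values exactly at the threshold map to 0 (the definition covers only
    "above" → 1 and "below" → 0; equality is resolved downward).
    """
    if threshold < 0:
        raise ValueError("binarization threshold must be non-negative")
    return (np.asarray(values, dtype=float) > threshold).astype(int)


def consolidate(
    dataset: MotorMapDataset,
    assignment: ClusterAssignment,
    method: str = "average",
    binarization_threshold: float = DEFAULT_BINARIZATION_THRESHOLD_UV,
) -> ConsolidatedMap:
    """Consolidate each cluster to one representative point and value.

    Raises
    ------
    MethodError
        If ``method`` is not one of the five consolidation operators.
    """
    if method not in CONSOLIDATION_METHODS:
        raise MethodError(
            f"unknown method {method!r}; expected one of {CONSOLIDATION_METHODS}"
        )
    if len(assignment.labels) != len(dataset):
        raise ValueError("assignment does not match dataset length")
    n_clusters = assignment.n_clusters
    points = np.zeros((n_clusters, 3))
    values = np.zeros(n_clusters)
    member_values = []
    for c in range(n_clusters):
        members = assignment.members(c)
        v = dataset.values[members]
        points[c] = dataset.points[members].mean(axis=0)
        member_values.append(tuple(v.tolist()))
        if method == "average":
            values[c] = v.mean()
        elif method == "maximum":
            values[c] = v.max()
        elif method == "minimum":
            values[c] = v.min()
        elif method == "variance":
            values[c] = np.mean((v - v.mean()) ** 2)  # population variance
        else:  # probability
            values[c] = 100.0 * binarize(v, binarization_threshold).mean()
    return ConsolidatedMap(
        points=points,
        values=values,
        method=method,
        units=_METHOD_UNITS[method],
        binarization_threshold=(
            binarization_threshold if method == "probability" else None
        ),
        cluster_values=tuple(member_values),
    )
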