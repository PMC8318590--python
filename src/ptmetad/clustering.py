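"""GROMOS-style conformational clustering of trajectory frames.

The greedy neighbour-count algorithm of g_cluster: repeatedly take the
frame with the most neighbours within the RMSD cutoff (0.2 nm by
default), form a cluster of it plus its neighbours, remove them, and
iterate until no frames remain.  Distances exactly at the cutoff count
as neighbours; neighbour-count ties break toward the lowest frame index.
The representative of a cluster is its central structure — the member
with the smallest summed distance to all other members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .structures import Structure, kabsch_rmsd

__all__ = ["DistanceMatrix", "ClusterSet",
           "pairwise_rmsd_matrix", "gromos_cluster", "central_structure"]


@dataclass
class DistanceMatrix:
    """Condensed pairwise frame distances in nm."""

    n: int
    condensed: np.ndarray
    metric: str = "rmsd"

    def __post_init__(self):
        self.condensed = np.asarray(self.condensed, dtype=float)
        if self.condensed.shape != (self.n * (self.n - 1) // 2,):
            raise ValueError("condensed length inconsistent with n")
        if np.any(self.condensed < 0) or not np.all(np.isfinite(self.condensed)):
            raise ValueError("distances must be finite and non-negative")

    def square(self) -> np.ndarray:
        if self.n == 1:
            return np.zeros((1, 1))
        return squareform(self.condensed)


@dataclass
class ClusterSet:
    """Clusters ordered by size (ties: discovery order); partition of all
    frame indices."""

    clusters: list            # list of lists of frame indices
    cutoff: float
    centers: list             # founding centre of each cluster

    def labels(self, n: int) -> np.ndarray:
        lab = np.full(n, -1, dtype=int)
        for ci, members in enumerate(self.clusters):
            lab[members] = ci
        return lab


def pairwise_rmsd_matrix(frames: list[Structure], selection,
                         superpose: bool = True) -> DistanceMatrix:
    """All-against-all Kabsch RMSD over a selection (e.g. the Cα atoms of
    the A-loop and αC-helix)."""
    n = len(frames)
    cond = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            cond[k] = kabsch_rmsd(frames[i], frames[j], selection, superpose)
            k += 1
    return DistanceMatrix(n=n, condensed=cond,
                          metric=f"rmsd(superpose={superpose})")


def gromos_cluster(d: DistanceMatrix, cutoff: float = 0.2) -> ClusterSet:
    """Greedy neighbour-count clustering at an RMSD cutoff (nm)."""
    sq = d.square()
    remaining = list(range(d.n))
    clusters, centers = [], []
    while remaining:
        rem = np.array(remaining)
        sub = sq[np.ix_(rem, rem)]
        counts = np.sum(sub <= cutoff, axis=1)  # includes self
        center_pos = int(np.argmax(counts))     # argmax: lowest index on ties
        members = rem[sub[center_pos] <= cutoff]
        clusters.append(sorted(int(m) for m in members))
        centers.append(int(rem[center_pos]))
        member_set = set(clusters[-1])
        remaining = [r for r in remaining if r not in member_set]
    order = sorted(range(len(clusters)),
                   key=lambda c: (-len(clusters[c]), c))
    return ClusterSet(clusters=[clusters[c] for c in order], cutoff=cutoff,
                      centers=[centers[c] for c in order])


def central_structure(members, d: DistanceMatrix) -> int:
    """The member minimising the summed distance to all other members
    (ties: lowest frame index)."""
    members = sorted(members)
    if not members:
        raise ValueError("empty cluster")
    sq = d.square()
    sums = [float(np.sum(sq[m, members])) for m in members]
    best = int(np.argmin(sums))
    return members[best]
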