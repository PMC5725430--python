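"""Spatial clustering of electrodes into the 19 10-20 regions.

High-density nets oversample the scalp; convolving an image-like tensor
only makes sense if adjacent rows are adjacent on the head.  Electrodes are
therefore partitioned into 19 spatially coherent groups — k-means on 3-D
Cartesian coordinates, seeded at the canonical 10-20 anchor positions — and
rows are ordered group-by-group (anchor sequence Fp1 ... O2, electrodes
within a group sorted by distance to the group centroid).  The result is a
deterministic permutation that turns a trial into an image whose vertical
neighborhoods are anatomical neighborhoods.

Clustering runs on straight-line (chordal) distances rather than geodesic
scalp distances; at 10-20 scale the two rank-order distances nearly
identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans

from .montage import TEN_TWENTY_NAMES, ElectrodeLayout

__all__ = [
    "ClusterAssignment",
    "kmeans_groups",
    "agglomerative_groups",
    "image_order",
    "apply_order",
    "save_assignment",
    "load_assignment",
]


class ClusteringError(ValueError):
    """Invalid layout or assignment."""


@dataclass
class ClusterAssignment:
    """Partition of electrodes into 19 groups plus a deterministic row order.

    ``group_of`` holds group ids 1-19 per electrode (group g corresponds to
    the g-th canonical 10-20 anchor); ``row_order`` is a permutation of
    electrode indices placing each group's electrodes in contiguous rows.
    """

    group_of: np.ndarray
    row_order: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.group_of = np.asarray(self.group_of, dtype=int)
        self.row_order = np.asarray(self.row_order, dtype=int)
        n = self.group_of.shape[0]
        if sorted(self.row_order.tolist()) != list(range(n)):
            raise ClusteringError("row_order is not a permutation")
        ids = np.unique(self.group_of)
        if ids.min() < 1 or ids.max() > 19 or ids.size != 19:
            raise ClusteringError("need exactly 19 non-empty groups in [1, 19]")

    @property
    def n_channels(self) -> int:
        return self.group_of.shape[0]


def _relabel_to_anchor_ids(labels0: np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Map raw cluster indices to 1-19 by matching cluster centroids to the
    canonical anchors (Hungarian assignment, so the mapping is a bijection
    even when a cluster captures two anchors)."""
    from scipy.optimize import linear_sum_assignment

    anchors = layout.anchor_coords()  # canonical order
    centroids = np.stack([layout.coords[labels0 == c].mean(axis=0)
                          for c in range(19)])
    cost = np.linalg.norm(centroids[:, None] - anchors[None], axis=-1)
    rows, cols = linear_sum_assignment(cost)
    mapping = {int(c): int(g) + 1 for c, g in zip(rows, cols)}
    return np.array([mapping[int(l)] for l in labels0], dtype=int)


def _validate_layout(layout: ElectrodeLayout, k: int) -> None:
    if k != 19:
        raise ClusteringError("the 10-20 partition uses exactly k=19 groups")
    anchors = layout.anchor_coords()
    d = np.linalg.norm(anchors[:, None] - anchors[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() == 0.0:
        raise ClusteringError("duplicate anchor coordinates in layout")


def kmeans_groups(layout: ElectrodeLayout, k: int = 19) -> ClusterAssignment:
    """Lloyd's k-means seeded at the 19 anchor coordinates.

    Deterministic: the seeding is fixed by the anchors, so there is no
    random-restart sensitivity at all.
    """
    _validate_layout(layout, k)
    km = KMeans(n_clusters=k, init=layout.anchor_coords(), n_init=1,
                max_iter=300, algorithm="lloyd", random_state=0)
    labels0 = km.fit_predict(layout.coords)
    group_of = _relabel_to_anchor_ids(labels0, layout)
    centroids = np.stack([
        layout.coords[group_of == g].mean(axis=0) for g in range(1, 20)
    ])
    assignment = ClusterAssignment(group_of=group_of,
                                   row_order=np.arange(layout.n_channels),
                                   centroids=centroids)
    assignment.row_order = image_order(assignment, layout)
    return assignment


def agglomerative_groups(layout: ElectrodeLayout, k: int = 19) -> ClusterAssignment:
    """Average-linkage Euclidean agglomeration cut at 19 clusters.

    Provided for comparison with :func:`kmeans_groups`; k-means generally
    yields tighter, more balanced groups on these layouts.
    """
    _validate_layout(layout, k)
    agg = AgglomerativeClustering(n_clusters=k, linkage="average",
                                  metric="euclidean")
    labels0 = agg.fit_predict(layout.coords)
    group_of = _relabel_to_anchor_ids(labels0, layout)
    centroids = np.stack([
        layout.coords[group_of == g].mean(axis=0) for g in range(1, 20)
    ])
    assignment = ClusterAssignment(group_of=group_of,
                                   row_order=np.arange(layout.n_channels),
                                   centroids=centroids)
    assignment.row_order = image_order(assignment, layout)
    return assignment


def image_order(assignment: ClusterAssignment, layout: ElectrodeLayout) -> np.ndarray:
    """Deterministic row order: groups in canonical 10-20 anchor sequence,
    electrodes within a group by ascending distance to the group centroid
    (ties broken by electrode index)."""
    order: list[int] = []
    for g in range(1, 20):
        members = np.nonzero(assignment.group_of == g)[0]
        dists = np.linalg.norm(layout.coords[members]
                               - assignment.centroids[g - 1], axis=1)
        # lexsort: primary key distance, secondary key electrode index
        order.extend(members[np.lexsort((members, dists))].tolist())
    return np.asarray(order, dtype=int)


def apply_order(stack: np.ndarray, row_order: np.ndarray) -> np.ndarray:
    """Permute channel rows of a (channels x samples x modes) tensor."""
    stack = np.asarray(stack)
    row_order = np.asarray(row_order, dtype=int)
    if stack.shape[0] != row_order.shape[0]:
        raise ClusteringError(
            f"row_order length {row_order.shape[0]} != channels {stack.shape[0]}"
        )
    if sorted(row_order.tolist()) != list(range(stack.shape[0])):
        raise ClusteringError("row_order is not a bijection over channels")
    return stack[row_order]


def save_assignment(assignment: ClusterAssignment, layout: ElectrodeLayout,
                    path) -> None:
    """Two-column table (label, group id) plus the row order, re-loadable."""
    with open(path, "w") as fh:
        fh.write("# label group_id\n")
        for label, g in zip(layout.labels, assignment.group_of):
            fh.write(f"{label} {g}\n")
        fh.write("# row_order " + " ".join(map(str, assignment.row_order)) + "\n")
        for c in assignment.centroids:
            fh.write("# centroid " + " ".join(f"{v:.17g}" for v in c) + "\n")


def load_assignment(path) -> ClusterAssignment:
    group_of: list[int] = []
    row_order: list[int] = []
    centroids: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "#":
                if parts[1] == "row_order":
                    row_order = [int(v) for v in parts[2:]]
                elif parts[1] == "centroid":
                    centroids.append([float(v) for v in parts[2:]])
                continue
            group_of.append(int(parts[1]))
    return ClusterAssignment(group_of=np.asarray(group_of),
                             row_order=np.asarray(row_order),
                             centroids=np.asarray(centroids))
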