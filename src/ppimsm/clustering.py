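"""Greedy k-center clustering of trajectory frames under a pluggable metric.

The splitting step of the pipeline divides frames into geometric
microstates with the classic greedy k-center rule: the first center is a
chosen seed frame, each subsequent center is the frame farthest from its
nearest existing center, and the final assignment is nearest-center.
The greedy rule guarantees a maximum cluster radius within a factor 2 of
the optimal k-center radius, and is fully deterministic given the seed
index, which makes runs reproducible.

Metrics are objects exposing vectorized distances from one reference
datum to every frame of a data set; two are provided: Euclidean distance
over feature columns, and ligand RMSD after rigid superposition for
coordinate frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .geometry import metric_rmsd
from .trajectory import CoordinateTrajectory

__all__ = [
    "EuclideanMetric",
    "LigandRMSDMetric",
    "Clustering",
    "kcenter",
    "assign",
    "write_clustering_tsv",
]


class EuclideanMetric:
    """Euclidean distance on ``(n_frames, n_features)`` arrays."""

    description = "euclidean"

    @staticmethod
    def n_frames(data) -> int:
        return np.asarray(data).shape[0]

    @staticmethod
    def frame(data, index: int):
        return np.asarray(data, dtype=float)[index]

    @staticmethod
    def distances(data, ref) -> np.ndarray:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        ref = np.atleast_1d(np.asarray(ref, dtype=float))
        return np.sqrt(((X - ref[None, :]) ** 2).sum(axis=1))


class LigandRMSDMetric:
    """RMSD over the metric subset after superposition on the alignment subset.

    Operates on :class:`~ppimsm.trajectory.CoordinateTrajectory` data; the
    subsets are taken from the trajectory itself.
    """

    description = "ligand-rmsd"

    @staticmethod
    def n_frames(data: CoordinateTrajectory) -> int:
        return data.n_frames

    @staticmethod
    def frame(data: CoordinateTrajectory, index: int):
        return (data.coords[index], data.alignment_subset, data.metric_subset)

    @staticmethod
    def distances(data: CoordinateTrajectory, ref) -> np.ndarray:
        ref_coords, align, metric = ref
        out = np.empty(data.n_frames)
        for i in range(data.n_frames):
            out[i] = metric_rmsd(data.coords[i], ref_coords, align, metric)
        return out


@dataclass
class Clustering:
    """Result of greedy k-center clustering.

    ``center_data`` stores the actual center frames (not just indices) so
    new frames can be assigned without access to the training data.
    """

    k: int
    center_indices: np.ndarray      # frame index of each center in training data
    center_data: list               # metric-specific center representations
    labels: np.ndarray              # per-frame cluster id
    radii: np.ndarray               # max member→center distance per cluster
    mean_distances: np.ndarray      # mean member→center distance per cluster
    metric_description: str

    def __post_init__(self) -> None:
        bad = self.radii + 1e-12 < self.mean_distances
        if np.any(bad):
            raise DataError("cluster radius smaller than mean distance")


def kcenter(data, k: int, metric, initial_index: int = 0) -> Clustering:
    """Greedy k-center clustering.

    The first center is ``data[initial_index]`` (default 0: deterministic
    seeding).  Each subsequent center is the frame farthest from its
    nearest existing center; ties in both farthest-point selection and
    final assignment break to the lowest index.
    """
    n = metric.n_frames(data)
    if not 1 <= k <= n:
        raise DataError(f"k must be in [1, {n}], got {k}")
    if not 0 <= initial_index < n:
        raise DataError(f"initial_index out of range [0, {n})")

    center_idx = [initial_index]
    center_data = [metric.frame(data, initial_index)]
    d_near = metric.distances(data, center_data[0])
    labels = np.zeros(n, dtype=np.int64)
    for _ in range(1, k):
        nxt = int(np.argmax(d_near))  # first occurrence wins ties
        center_idx.append(nxt)
        center_data.append(metric.frame(data, nxt))
        d_new = metric.distances(data, center_data[-1])
        closer = d_new < d_near  # strict: equal distance keeps earlier center
        labels[closer] = len(center_idx) - 1
        d_near = np.where(closer, d_new, d_near)

    radii = np.zeros(k)
    means = np.zeros(k)
    for c in range(k):
        member_d = d_near[labels == c]
        if member_d.size:
            radii[c] = member_d.max()
            means[c] = member_d.mean()
    return Clustering(
        k=k,
        center_indices=np.asarray(center_idx),
        center_data=center_data,
        labels=labels,
        radii=radii,
        mean_distances=means,
        metric_description=metric.description,
    )


def assign(data, clustering: Clustering, metric) -> np.ndarray:
    """Nearest-center assignment of (possibly new) frames.

    Ties break to the lowest center index; assigning the training frames
    reproduces the stored labels.
    """
    if metric.description != clustering.metric_description:
        raise DataError(
            f"metric {metric.description!r} differs from the clustering's "
            f"{clustering.metric_description!r}"
        )
    n = metric.n_frames(data)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    dmat = np.empty((clustering.k, n))
    for c, cd in enumerate(clustering.center_data):
        dmat[c] = metric.distances(data, cd)
    return np.argmin(dmat, axis=0)  # argmin picks the lowest index on ties


def write_clustering_tsv(clustering: Clustering, path, sidecar_path=None) -> None:
    """Serialize assignments as `frame_id<TAB>cluster` plus a center sidecar."""
    with open(path, "w") as fh:
        fh.write(f"# k={clustering.k} metric={clustering.metric_description}\n")
        fh.write("frame_id\tcluster\n")
        for i, lab in enumerate(clustering.labels):
            fh.write(f"{i}\t{lab}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write("cluster\tcenter_frame\tradius\tmean_distance\n")
            for c in range(clustering.k):
                fh.write(
                    f"{c}\t{clustering.center_indices[c]}\t"
                    f"{clustering.radii[c]!r}\t{clustering.mean_distances[c]!r}\n"
                )
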