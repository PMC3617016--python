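"""Potential-of-mean-force projection onto one or two reaction coordinates.

The free-energy surface is a weighted histogram on a regular grid,
``F(bin) = −ln( w(bin) / max_bin w )`` in units of k_BT, shifted so the
minimum over non-empty bins is zero.  Two weighting modes exist:

* ``uniform`` — every frame weighs 1 (a raw histogram);
* ``msm`` — every frame in microstate ``i`` weighs ``π_i / count_i``, so
  each microstate contributes exactly its equilibrium probability.  This
  is the default in the pipeline because short seeding trajectories are
  not equilibrium-distributed.

Empty bins are masked (NaN), never interpolated or assigned a large
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .trajectory import FeatureTrajectory

__all__ = ["PMFGrid", "pmf_project", "write_pmf_csv"]


@dataclass
class PMFGrid:
    coordinate_names: list[str]
    edges: list[np.ndarray]        # bin edges per dimension, Å
    free_energy: np.ndarray        # k_BT units, NaN on masked bins
    mask: np.ndarray               # True where the bin is empty
    weighting: str                 # "uniform" | "msm"
    n_frames_used: int
    n_frames_dropped: int

    def __post_init__(self) -> None:
        finite = self.free_energy[~self.mask]
        if finite.size and abs(np.nanmin(finite)) > 1e-10:
            raise DataError("PMF minimum over non-empty bins must be 0")

    @property
    def bin_centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def _gather(features, coords) -> np.ndarray:
    cols = []
    for traj in features:
        if isinstance(traj, FeatureTrajectory):
            cols.append(np.column_stack([traj.column(c) for c in coords]))
        else:
            arr = np.atleast_2d(np.asarray(traj, dtype=float))
            if arr.shape[1] < len(coords):
                raise DataError("array trajectory has fewer columns than coords")
            cols.append(arr[:, : len(coords)])
    return np.vstack(cols)


def pmf_project(
    features,
    coords,
    bins=50,
    weighting: str = "uniform",
    micro_labels: np.ndarray | None = None,
    pi: np.ndarray | None = None,
    pi_state_labels: np.ndarray | None = None,
    bin_range=None,
    kT_scale: float = 1.0,
) -> PMFGrid:
    """Project frames onto 1 or 2 reaction coordinates as a free-energy grid.

    Parameters
    ----------
    features : list of FeatureTrajectory (or plain arrays)
    coords : list of 1 or 2 coordinate names
    bins : int or explicit strictly increasing edge array(s)
    weighting : "uniform" or "msm"
    micro_labels : per-frame microstate labels (concatenated over the
        trajectory list), required for ``weighting="msm"``
    pi, pi_state_labels : stationary vector over the ergodic microstates
        and the mapping of its entries to original microstate labels.
        Frames whose microstate is outside the ergodic subset are dropped
        and counted in ``n_frames_dropped``.
    kT_scale : multiply the output (e.g. to convert k_BT to kcal/mol).
    """
    coords = list(coords)
    if len(coords) not in (1, 2):
        raise DataError("PMF projection supports 1 or 2 coordinates")
    X = _gather(features, coords)
    n_frames = X.shape[0]

    if weighting == "uniform":
        w = np.ones(n_frames)
        dropped = 0
    elif weighting == "msm":
        if micro_labels is None or pi is None:
            raise DataError("msm weighting needs micro_labels and pi")
        micro_labels = np.asarray(micro_labels, dtype=int)
        if micro_labels.size != n_frames:
            raise DataError("micro_labels length must match total frame count")
        if pi_state_labels is None:
            pi_state_labels = np.arange(len(pi))
        pi_full = np.full(int(max(micro_labels.max(), pi_state_labels.max())) + 1, np.nan)
        pi_full[np.asarray(pi_state_labels, dtype=int)] = pi
        counts = np.bincount(micro_labels, minlength=pi_full.size).astype(float)
        w = pi_full[micro_labels] / counts[micro_labels]
        keep = np.isfinite(w)
        dropped = int((~keep).sum())
        X, w = X[keep], w[keep]
    else:
        raise DataError(f"unknown weighting {weighting!r}")

    if isinstance(bins, int):
        bins_arg = bins
    else:
        edge_list = [np.asarray(e, dtype=float) for e in
                     (bins if isinstance(bins, (list, tuple)) else [bins])]
        for e in edge_list:
            if np.any(np.diff(e) <= 0):
                raise DataError("bin edges must be strictly increasing")
        bins_arg = edge_list
    hist, edges = np.histogramdd(X, bins=bins_arg, range=bin_range, weights=w)
    if hist.sum() == 0:
        raise DataError("all frames fall outside the bin range")
    mask = hist == 0
    F = np.full(hist.shape, np.nan)
    F[~mask] = -np.log(hist[~mask] / hist.max()) * kT_scale
    grid = PMFGrid(
        coordinate_names=coords,
        edges=[np.asarray(e) for e in edges],
        free_energy=F,
        mask=mask,
        weighting=weighting,
        n_frames_used=int(n_frames - dropped),
        n_frames_dropped=dropped,
    )
    return grid


def write_pmf_csv(grid: PMFGrid, path, time_header: str = "") -> None:
    """Long-format CSV: `bin_center[,bin_center2],F_kT,mask`."""
    centers = grid.bin_centers
    with open(path, "w") as fh:
        fh.write(
            f"# coords={','.join(grid.coordinate_names)} units=kT "
            f"lengths=angstrom weighting={grid.weighting}"
            + (f" {time_header}" if time_header else "") + "\n"
        )
        if len(centers) == 1:
            fh.write("bin_center,F_kT,mask\n")
            for i, c in enumerate(centers[0]):
                val = "" if grid.mask[i] else repr(float(grid.free_energy[i]))
                fh.write(f"{c!r},{val},{int(grid.mask[i])}\n")
        else:
            fh.write("bin_center,bin_center2,F_kT,mask\n")
            for i, ci in enumerate(centers[0]):
                for j, cj in enumerate(centers[1]):
                    masked = grid.mask[i, j]
                    val = "" if masked else repr(float(grid.free_energy[i, j]))
                    fh.write(f"{ci!r},{cj!r},{val},{int(masked)}\n")
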