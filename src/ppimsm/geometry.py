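"""Rigid-body superposition and reaction-coordinate extraction.

The conformational distance used for microstate clustering is an RMSD over
a small "metric" atom subset (the ligand atoms) measured after the frame
has been superposed onto a reference via a separate "alignment" subset
(a rigid structural element such as a helix backbone).  Superposition is
the optimal proper rotation + translation (Kabsch); reflections are never
allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateSubsetError
from .trajectory import CoordinateTrajectory, FeatureTrajectory

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "metric_rmsd",
    "distance_features",
]


@dataclass
class SuperpositionResult:
    aligned: np.ndarray      # (n_atoms, 3) mobile frame after the rigid fit
    rotation: np.ndarray     # (3, 3), proper: det = +1
    translation: np.ndarray  # (3,): aligned = (mobile - mob_centroid) @ R.T + ref_centroid
    rmsd: float              # RMSD of the fitted subset after superposition, Å


def _check_subset(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateSubsetError(
            f"alignment subset needs >= 3 atoms, got {points.shape[0]}"
        )
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSubsetError("alignment subset is collinear or degenerate")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, subset=None
) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    The rotation/translation minimising the subset RMSD is found with the
    Kabsch construction (via quaternion solution of the Wahba problem);
    the rotation is always proper (determinant +1), so mirror images keep
    a non-zero residual.

    Parameters
    ----------
    mobile, reference : ndarray, shape (n_atoms, 3)
    subset : index array or None
        Atoms used for the fit; the returned transform is applied to all
        atoms of ``mobile``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if subset is None:
        subset = np.arange(mobile.shape[0])
    subset = np.asarray(subset, dtype=int)
    mob_sub = mobile[subset]
    ref_sub = reference[subset]
    _check_subset(mob_sub)
    _check_subset(ref_sub)

    mob_c = mob_sub.mean(axis=0)
    ref_c = ref_sub.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sub - ref_c, mob_sub - mob_c)
    R = rot.as_matrix()
    aligned = (mobile - mob_c) @ R.T + ref_c
    translation = ref_c - R @ mob_c
    diff = aligned[subset] - ref_sub
    rmsd = float(np.sqrt((diff**2).sum() / subset.size))
    return SuperpositionResult(aligned=aligned, rotation=R, translation=translation, rmsd=rmsd)


def metric_rmsd(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alignment_subset,
    metric_subset,
) -> float:
    """RMSD over ``metric_subset`` after superposing on ``alignment_subset``.

    Superposition is a rigid motion, so the result is symmetric in the two
    frames (to numerical precision) and a pseudo-metric on frames.
    """
    res = kabsch_superpose(frame_a, frame_b, alignment_subset)
    metric_subset = np.asarray(metric_subset, dtype=int)
    diff = res.aligned[metric_subset] - np.asarray(frame_b, dtype=float)[metric_subset]
    return float(np.sqrt((diff**2).sum() / metric_subset.size))


def distance_features(
    traj: CoordinateTrajectory,
    pairs,
    names,
    masses: np.ndarray | None = None,
    mass_weighted: bool = False,
) -> FeatureTrajectory:
    """Per-frame distances between centers of geometry of atom groups.

    Parameters
    ----------
    pairs : list of (group_a, group_b)
        Each group is a list of atom labels or an integer index array.
    names : list of str
        One output coordinate name per pair.
    masses, mass_weighted :
        With ``mass_weighted=True`` the group centers are mass-weighted;
        the default is the unweighted center of geometry, since the toy
        data model carries no masses.
    """
    if len(pairs) != len(names):
        raise ValueError("need one name per pair")

    def resolve(group) -> np.ndarray:
        if len(group) and isinstance(group[0], str):
            return traj.atom_indices(list(group))
        return np.asarray(group, dtype=int)

    def center(idx: np.ndarray) -> np.ndarray:
        pts = traj.coords[:, idx, :]  # (n_frames, n_sel, 3)
        if mass_weighted:
            if masses is None:
                raise ValueError("mass_weighted=True requires masses")
            w = np.asarray(masses, dtype=float)[idx]
            return (pts * w[None, :, None]).sum(axis=1) / w.sum()
        return pts.mean(axis=1)

    cols = []
    for group_a, group_b in pairs:
        ia, ib = resolve(group_a), resolve(group_b)
        if ia.size == 0 or ib.size == 0:
            raise ValueError("atom groups must be non-empty")
        delta = center(ia) - center(ib)
        cols.append(np.linalg.norm(delta, axis=1))
    return FeatureTrajectory(
        names=list(names),
        values=np.column_stack(cols),
        frame_interval=traj.frame_interval,
        time_unit=traj.time_unit,
        source="distance_features",
    )
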