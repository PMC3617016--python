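"""Trajectory containers and plain-text I/O.

Two in-memory containers cover the pipeline's needs:

``FeatureTrajectory``
    Per-frame values of named reaction coordinates (distances in Å), saved
    at a fixed frame interval.  This is the form the microstate clustering
    and the free-energy projections consume.

``CoordinateTrajectory``
    Per-frame Cartesian coordinates (Å) for a small atom set, with two
    named index subsets: one used to superpose frames onto a reference
    (e.g. the Cα atoms of a rigid helix) and one over which a
    conformational distance is measured (e.g. the three ligand atoms).

Frames are 0-indexed; the time of frame ``i`` is ``i * frame_interval``.
All I/O is plain text: CSV for feature series, multi-frame XYZ for
coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = [
    "FeatureTrajectory",
    "CoordinateTrajectory",
    "read_feature_csv",
    "write_feature_csv",
    "read_xyz",
    "write_xyz",
]


@dataclass
class FeatureTrajectory:
    """Named reaction-coordinate values per frame.

    Parameters
    ----------
    names : list of str
        One name per coordinate column (e.g. ``["d1"]``).
    values : ndarray, shape (n_frames, n_coords)
        Coordinate values in Å.
    frame_interval : float
        Time between consecutive frames, in ``time_unit``.
    time_unit : str
        Label for the time axis, e.g. ``"ns"``.
    source : str
        Free-form provenance tag (file name, generator name, ...).
    """

    names: list[str]
    values: np.ndarray
    frame_interval: float
    time_unit: str = "ns"
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise DataError("feature values must be a (n_frames, n_coords) array")
        if self.values.shape[1] != len(self.names):
            raise DataError(
                f"{len(self.names)} coordinate names for "
                f"{self.values.shape[1]} value columns"
            )
        if not self.frame_interval > 0:
            raise DataError(f"frame_interval must be > 0, got {self.frame_interval}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise DataError(f"unknown coordinate name {name!r}; have {self.names}")
        return self.values[:, j]


@dataclass
class CoordinateTrajectory:
    """Cartesian coordinates for a small atom set, per frame.

    ``alignment_subset`` and ``metric_subset`` are integer index arrays
    into the atom axis; they may overlap.
    """

    atom_labels: list[str]
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_interval: float = 1.0
    time_unit: str = "ns"
    alignment_subset: np.ndarray = field(default_factory=lambda: np.arange(0))
    metric_subset: np.ndarray = field(default_factory=lambda: np.arange(0))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_labels):
            raise DataError("atom_labels length does not match coordinate array")
        self.alignment_subset = np.asarray(self.alignment_subset, dtype=int)
        self.metric_subset = np.asarray(self.metric_subset, dtype=int)
        n = self.coords.shape[1]
        for sub, tag in ((self.alignment_subset, "alignment"), (self.metric_subset, "metric")):
            if sub.size and (sub.min() < 0 or sub.max() >= n):
                raise DataError(f"{tag}_subset index out of range for {n} atoms")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, labels: list[str]) -> np.ndarray:
        """Map atom labels to indices, raising on unknown labels."""
        out = []
        for lab in labels:
            try:
                out.append(self.atom_labels.index(lab))
            except ValueError:
                raise DataError(f"unknown atom label {lab!r}")
        return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# CSV dialect: header `frame,time,<coord names...>`, one row per frame.
# ---------------------------------------------------------------------------

def write_feature_csv(traj: FeatureTrajectory, path) -> None:
    """Write a feature trajectory as ``frame,time,<names...>`` CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time"] + list(traj.names))
        times = traj.times
        for i in range(traj.n_frames):
            w.writerow(
                [i, repr(float(times[i]))] + [repr(float(v)) for v in traj.values[i]]
            )


def read_feature_csv(path, time_unit: str = "ns") -> FeatureTrajectory:
    """Read the CSV dialect written by :func:`write_feature_csv`.

    Raises :class:`DataError` naming the offending line for ragged rows,
    non-contiguous frame indices, or a missing/empty header.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise DataError(f"{path}: empty file, not an empty trajectory")
    header = rows[0]
    if len(header) < 3 or header[0] != "frame" or header[1] != "time":
        raise DataError(f"{path}: missing or malformed header {header!r}")
    names = header[2:]
    ncol = len(header)
    values = np.empty((len(rows) - 1, len(names)))
    times = np.empty(len(rows) - 1)
    for k, row in enumerate(rows[1:]):
        line_no = k + 2
        if len(row) != ncol:
            raise DataError(f"{path}: ragged row at line {line_no}")
        try:
            frame = int(row[0])
            times[k] = float(row[1])
            values[k] = [float(x) for x in row[2:]]
        except ValueError as exc:
            raise DataError(f"{path}: unparsable value at line {line_no}: {exc}")
        if frame != k:
            raise DataError(f"{path}: non-contiguous frames at line {line_no}")
    if len(times) >= 2:
        dts = np.diff(times)
        dt = dts[0]
        if dt <= 0 or not np.allclose(dts, dt, rtol=1e-9, atol=1e-12):
            raise DataError(f"{path}: frame interval not constant and positive")
    else:
        dt = 1.0
    return FeatureTrajectory(
        names=names, values=values, frame_interval=float(dt),
        time_unit=time_unit, source=str(path),
    )


# ---------------------------------------------------------------------------
# Multi-frame XYZ: atom-count line, comment line with frame index, then
# `element x y z` per atom.
# ---------------------------------------------------------------------------

def write_xyz(traj: CoordinateTrajectory, path) -> None:
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {i}\n")
            for lab, (x, y, z) in zip(traj.atom_labels, traj.coords[i]):
                fh.write(f"{lab} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(
    path,
    frame_interval: float = 1.0,
    time_unit: str = "ns",
    alignment_subset=(),
    metric_subset=(),
) -> CoordinateTrajectory:
    """Read a multi-frame XYZ file.

    Subsets are not stored in the XYZ format itself and are supplied by the
    caller (or a sidecar config).
    """
    frames: list[np.ndarray] = []
    labels: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            nat = int(lines[pos].strip())
        except ValueError:
            raise DataError(f"{path}: expected atom count at line {pos + 1}")
        block = lines[pos + 2 : pos + 2 + nat]
        if len(block) < nat:
            raise DataError(f"{path}: truncated frame starting at line {pos + 1}")
        labs, xyz = [], []
        for off, ln in enumerate(block):
            parts = ln.split()
            if len(parts) != 4:
                raise DataError(f"{path}: malformed atom record at line {pos + 3 + off}")
            labs.append(parts[0])
            xyz.append([float(p) for p in parts[1:]])
        if labels is None:
            labels = labs
        elif labs != labels:
            raise DataError(f"{path}: atom labels change at line {pos + 3}")
        frames.append(np.asarray(xyz))
        pos += 2 + nat
    return CoordinateTrajectory(
        atom_labels=labels or [],
        coords=np.stack(frames),
        frame_interval=frame_interval,
        time_unit=time_unit,
        alignment_subset=np.asarray(alignment_subset, dtype=int),
        metric_subset=np.asarray(metric_subset, dtype=int),
    )
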