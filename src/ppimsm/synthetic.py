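"""Synthetic trajectories with exact kinetic and thermodynamic ground truth.

The real observable behind the pipeline is the distance between a released
pyrophosphate (PPi) group and the catalytic Mg²⁺ ion of an RNA polymerase
active site, sampled by many short MD runs.  No such data ships with the
package; instead three generators provide inputs whose answers are known
in closed form, so every downstream stage can be checked quantitatively:

* :func:`simulate_jump` — a continuous-time Markov jump process observed
  at a fixed frame interval, with Gaussian emission of a 1-D coordinate
  per hidden state.  :func:`ppi_release_preset` parameterises it as a
  two-state exchange (bound near the active site / released in the
  channel) whose stationary populations and bound→released mean first
  passage time equal the values the full pipeline is expected to recover.
* :func:`simulate_langevin` — overdamped Brownian dynamics on an explicit
  potential, giving a Boltzmann oracle for free-energy projections.
* :func:`make_toy_structures` — small rigid "scaffold + ligand" frames
  with planted conformational clusters, exercising superposition and the
  RMSD clustering metric.

Seeding: one global integer seed expands to per-trajectory substreams as
``seed + trajectory_index``; identical seeds reproduce identical output
bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.spatial.transform import Rotation

from .errors import DataError, NumericalError
from .trajectory import CoordinateTrajectory, FeatureTrajectory

__all__ = [
    "JumpModel",
    "SyntheticTruth",
    "JumpSimulation",
    "ppi_release_preset",
    "simulate_jump",
    "PotentialSpec",
    "gaussian_wells_1d",
    "asymmetric_double_well",
    "symmetric_double_well",
    "flat_potential",
    "boltzmann_basin_probabilities",
    "simulate_langevin",
    "make_toy_structures",
    "write_truth",
    "read_truth",
]


# ---------------------------------------------------------------------------
# Markov jump process with Gaussian emissions
# ---------------------------------------------------------------------------

@dataclass
class JumpModel:
    """Continuous-time Markov jump process with per-state Gaussian emission.

    ``rates[i, j]`` (i ≠ j) is the transition rate i→j per unit time; the
    diagonal is ignored.  The observed coordinate in state ``i`` is drawn
    as ``Normal(emission_mean[i], emission_sd[i])`` (Å).
    """

    n_states: int
    rates: np.ndarray
    emission_mean: np.ndarray
    emission_sd: np.ndarray
    time_unit: str = "ns"

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.emission_mean = np.asarray(self.emission_mean, dtype=float)
        self.emission_sd = np.asarray(self.emission_sd, dtype=float)
        if self.rates.shape != (self.n_states, self.n_states):
            raise DataError("rates must be (n_states, n_states)")
        off = self.rates[~np.eye(self.n_states, dtype=bool)]
        if np.any(off < 0):
            raise DataError("off-diagonal rates must be >= 0")
        if np.any(self.emission_sd <= 0):
            raise DataError("emission_sd must be > 0")

    @property
    def rate_matrix(self) -> np.ndarray:
        """Infinitesimal generator Q: off-diagonal rates, rows sum to zero."""
        Q = self.rates.copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def frame_transition_matrix(self, frame_interval: float) -> np.ndarray:
        """Exact per-frame transition probabilities, ``expm(Q * dt)``."""
        return expm(self.rate_matrix * frame_interval)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the jump process (π Q = 0, Σπ = 1)."""
        Q = self.rate_matrix
        # solve pi Q = 0 with sum constraint via least squares
        A = np.vstack([Q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.any(pi < -1e-10):
            raise NumericalError("stationary distribution not strictly positive")
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def mfpt_matrix(self) -> np.ndarray:
        """Exact pairwise mean first passage times of the jump process.

        ``M[i, f]`` is the expected time to first reach state ``f`` from
        ``i``; the diagonal is zero.  Solves, for each target, the linear
        system ``Q_sub m = -1`` on the non-target states.  Targets that
        are unreachable (absorbing elsewhere) get an infinite MFPT.
        """
        Q = self.rate_matrix
        n = self.n_states
        M = np.zeros((n, n))
        for f in range(n):
            rest = [i for i in range(n) if i != f]
            sub = Q[np.ix_(rest, rest)]
            try:
                m = np.linalg.solve(sub, -np.ones(n - 1))
            except np.linalg.LinAlgError:
                m = np.full(n - 1, np.inf)
            if np.any(m < 0):
                m = np.full(n - 1, np.inf)
            M[rest, f] = m
        return M


@dataclass
class SyntheticTruth:
    """Exact answers attached to a generated data set."""

    stationary_probabilities: np.ndarray
    mfpt_matrix: np.ndarray  # same time unit as the generator
    time_unit: str
    seed: int
    parameters: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stationary_probabilities = np.asarray(self.stationary_probabilities, float)
        self.mfpt_matrix = np.asarray(self.mfpt_matrix, float)
        if not np.isclose(self.stationary_probabilities.sum(), 1.0, atol=1e-9):
            raise DataError("stationary probabilities must sum to 1")
        if np.any(np.abs(np.diag(self.mfpt_matrix)) > 1e-12):
            raise DataError("MFPT diagonal must be 0")


@dataclass
class JumpSimulation:
    """Output bundle of :func:`simulate_jump`."""

    state_paths: np.ndarray          # (n_trajectories, n_frames) int
    features: list[FeatureTrajectory]
    truth: SyntheticTruth


def ppi_release_preset() -> JumpModel:
    """Two-state exchange calibrated to the modeled PPi-release kinetics.

    State 0 is the bound basin (PPi at the active site, coordinate near
    4 Å), state 1 the released basin (elongated channel region, near
    15 Å).  The rates k(0→1) = 2.0000e-3 ns⁻¹ and k(1→0) = 2.8833e-4 ns⁻¹
    give stationary populations 12.60% / 87.40% and a bound→released mean
    first passage time of 500 ns (= 1/k01).  The emission widths (0.8 and
    2.5 Å) make the basins separable but overlapping in the tails.
    """
    k01 = 2.0000e-3
    k10 = 2.8833e-4
    rates = np.array([[0.0, k01], [k10, 0.0]])
    return JumpModel(
        n_states=2,
        rates=rates,
        emission_mean=np.array([4.0, 15.0]),
        emission_sd=np.array([0.8, 2.5]),
        time_unit="ns",
    )


def simulate_jump(
    model: JumpModel,
    n_frames: int,
    frame_interval: float,
    n_trajectories: int,
    seed: int,
    initial_state: int | None = None,
    coord_name: str = "d1",
) -> JumpSimulation:
    """Sample the jump process at a fixed frame interval.

    The hidden chain advances with the exact discrete-time transition
    matrix ``expm(Q · frame_interval)``, so the discretization introduces
    no first-order error at any state count.  Each trajectory uses the
    substream ``seed + trajectory_index``; within a substream the draw
    order is: frame uniforms (the first also selects the initial state
    when ``initial_state`` is None), then emission normals.

    Parameters
    ----------
    initial_state :
        Fixed start state for every trajectory; default draws the start
        from the model's stationary distribution.
    """
    if n_frames < 2:
        raise DataError("n_frames must be >= 2")
    if not frame_interval > 0:
        raise DataError("frame_interval must be > 0")
    P = model.frame_transition_matrix(frame_interval)
    cumP = np.cumsum(P, axis=1)
    wlist: list[str] = []
    if initial_state is None:
        pi0 = model.stationary()
        cum0 = np.cumsum(pi0)
    else:
        cum0 = None

    U = np.empty((n_trajectories, n_frames))
    Z = np.empty((n_trajectories, n_frames))
    for t in range(n_trajectories):
        rng = np.random.default_rng(seed + t)
        U[t] = rng.random(n_frames)
        Z[t] = rng.standard_normal(n_frames)

    S = np.empty((n_trajectories, n_frames), dtype=np.int64)
    if cum0 is not None:
        S[:, 0] = np.searchsorted(cum0, U[:, 0], side="right")
    else:
        S[:, 0] = initial_state
    for k in range(1, n_frames):
        rows = cumP[S[:, k - 1]]
        S[:, k] = (U[:, k, None] > rows).sum(axis=1)
    S = np.clip(S, 0, model.n_states - 1)

    X = model.emission_mean[S] + model.emission_sd[S] * Z
    features = [
        FeatureTrajectory(
            names=[coord_name],
            values=X[t][:, None],
            frame_interval=frame_interval,
            time_unit=model.time_unit,
            source=f"simulate_jump[{t}]",
        )
        for t in range(n_trajectories)
    ]
    visited = np.unique(S)
    if visited.size < model.n_states:
        msg = (
            f"states {sorted(set(range(model.n_states)) - set(visited.tolist()))} "
            "never visited; increase n_trajectories or n_frames"
        )
        wlist.append(msg)
        warnings.warn(msg)
    truth = SyntheticTruth(
        stationary_probabilities=model.stationary(),
        mfpt_matrix=model.mfpt_matrix(),
        time_unit=model.time_unit,
        seed=seed,
        parameters={
            "n_frames": n_frames,
            "frame_interval": frame_interval,
            "n_trajectories": n_trajectories,
            "rates": model.rates.tolist(),
            "emission_mean": model.emission_mean.tolist(),
            "emission_sd": model.emission_sd.tolist(),
        },
        warnings=wlist,
    )
    return JumpSimulation(state_paths=S, features=features, truth=truth)


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics on explicit potentials
# ---------------------------------------------------------------------------

@dataclass
class PotentialSpec:
    """An explicit potential with analytic energy and gradient.

    Energies are in units of ``kT`` when ``kT = 1``; ``bounds`` delimit
    the valid domain (the integrator raises if a trajectory leaves it),
    and ``minima`` lists known well positions, used for the step-size
    safety check.
    """

    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    kT: float
    bounds: tuple
    minima: tuple = ()
    description: str = ""


def gaussian_wells_1d(
    centers: Sequence[float],
    depths: Sequence[float],
    widths: Sequence[float],
    kT: float = 1.0,
    bounds: tuple[float, float] = (-5.0, 5.0),
    wall_height: float = 5.0,
) -> PotentialSpec:
    """Sum of inverted Gaussians plus a steep confining wall.

    ``U(x) = -Σ d_i exp(-(x-c_i)²/(2 w_i²)) + h·((x-m)/s)^10`` where the
    wall (height ``h = wall_height`` at 70% of the half-domain ``s``,
    centered at the domain midpoint ``m``) keeps the Boltzmann integral
    finite and the dynamics inside the stated bounds while being
    negligible (< 1e-3 kT) near the wells.
    """
    c = np.asarray(centers, float)
    d = np.asarray(depths, float)
    w = np.asarray(widths, float)
    lo, hi = bounds
    mid = 0.5 * (lo + hi)
    half = 0.35 * (hi - lo)

    def energy(x):
        x = np.asarray(x, float)
        wells = -(d * np.exp(-((x[..., None] - c) ** 2) / (2 * w**2))).sum(axis=-1)
        return wells + wall_height * ((x - mid) / half) ** 10

    def gradient(x):
        x = np.asarray(x, float)
        g = (x[..., None] - c) / w**2
        wells = (d * g * np.exp(-((x[..., None] - c) ** 2) / (2 * w**2))).sum(axis=-1)
        return wells + 10.0 * wall_height * ((x - mid) / half) ** 9 / half

    return PotentialSpec(
        dimension=1, energy=energy, gradient=gradient, kT=kT, bounds=bounds,
        minima=tuple(float(v) for v in c),
        description=f"gaussian wells at {list(c)} depths {list(d)} widths {list(w)}",
    )


def asymmetric_double_well(kT: float = 1.0) -> PotentialSpec:
    """Wells at x=0 (depth 3 kT) and x=1 (depth 2 kT), equal widths 0.15.

    Equal widths keep the two wells' harmonic corrections identical, so
    the basin occupancy ratio is dominated by the depth difference and the
    Euler-discretization bias largely cancels between basins.
    """
    return gaussian_wells_1d(
        centers=(0.0, 1.0), depths=(3.0 * kT, 2.0 * kT), widths=(0.15, 0.15),
        kT=kT, bounds=(-1.5, 2.5),
    )


def symmetric_double_well(kT: float = 1.0) -> PotentialSpec:
    return gaussian_wells_1d(
        centers=(0.0, 1.0), depths=(2.5 * kT, 2.5 * kT), widths=(0.15, 0.15),
        kT=kT, bounds=(-1.5, 2.5),
    )


def flat_potential(kT: float = 1.0, bounds=(-1e6, 1e6)) -> PotentialSpec:
    def energy(x):
        return np.zeros_like(np.asarray(x, float))

    def gradient(x):
        return np.zeros_like(np.asarray(x, float))

    return PotentialSpec(1, energy, gradient, kT, bounds, (), "flat")


def boltzmann_basin_probabilities(
    potential: PotentialSpec, dividing_point: float | None = None
) -> tuple[np.ndarray, float]:
    """Quadrature oracle: exact basin probabilities of a 1-D potential.

    Splits the domain at ``dividing_point`` (default: the energy maximum
    between the two outermost minima) and integrates the Boltzmann weight
    ``exp(-U/kT)`` over each side.  Returns ``(probabilities, split)``.
    """
    if potential.dimension != 1:
        raise DataError("Boltzmann basin oracle is 1-D only")
    lo, hi = potential.bounds
    if dividing_point is None:
        if len(potential.minima) < 2:
            raise DataError("need two minima or an explicit dividing point")
        a, b = min(potential.minima), max(potential.minima)
        grid = np.linspace(a, b, 2001)
        dividing_point = float(grid[np.argmax(potential.energy(grid))])
    w = lambda x: np.exp(-potential.energy(np.asarray(x)) / potential.kT)
    z_left, _ = quad(w, lo, dividing_point, limit=200)
    z_right, _ = quad(w, dividing_point, hi, limit=200)
    z = z_left + z_right
    return np.array([z_left / z, z_right / z]), dividing_point


def simulate_langevin(
    potential: PotentialSpec,
    n_frames: int,
    time_step: float,
    friction: float,
    seed: int,
    x0: float | np.ndarray | None = None,
    coord_names: Sequence[str] | None = None,
) -> FeatureTrajectory:
    """Overdamped Euler–Maruyama dynamics on an explicit potential.

    Update: ``x ← x − (∇U/γ)·dt + sqrt(2·kT·dt/γ)·ξ`` with ξ standard
    normal.  The step size must satisfy the safety check that the per-step
    displacement sd is below one tenth of the minimum well separation
    (when the potential declares ≥ 2 minima).  Leaving the declared domain
    bounds raises a :class:`DataError` naming the frame.
    """
    if not time_step > 0 or not friction > 0:
        raise DataError("time_step and friction must be > 0")
    step_sd = np.sqrt(2.0 * potential.kT * time_step / friction)
    minima = np.sort(np.asarray(potential.minima, float))
    if minima.size >= 2:
        sep = np.diff(minima).min()
        if not step_sd < sep / 10.0:
            raise DataError(
                f"time_step too large: per-step sd {step_sd:.4g} must be < "
                f"1/10 of the minimum well separation {sep:.4g}"
            )
    dim = potential.dimension
    rng = np.random.default_rng(seed)
    noise = step_sd * rng.standard_normal((n_frames, dim) if dim > 1 else n_frames)
    lo, hi = potential.bounds if dim == 1 else (None, None)

    if dim == 1:
        xs = np.empty(n_frames)
        x = float(x0) if x0 is not None else float(minima[0] if minima.size else 0.0)
        grad = potential.gradient
        inv_g_dt = time_step / friction
        for i in range(n_frames):
            x = x - float(grad(x)) * inv_g_dt + noise[i]
            if not (lo <= x <= hi):
                raise DataError(f"trajectory left domain {potential.bounds} at frame {i}")
            xs[i] = x
        values = xs[:, None]
        names = list(coord_names) if coord_names else ["x"]
    else:
        x = np.array(x0, float) if x0 is not None else np.zeros(dim)
        xs = np.empty((n_frames, dim))
        for i in range(n_frames):
            x = x - potential.gradient(x) * (time_step / friction) + noise[i]
            for d in range(dim):
                blo, bhi = potential.bounds[d]
                if not (blo <= x[d] <= bhi):
                    raise DataError(
                        f"trajectory left domain on axis {d} at frame {i}"
                    )
            xs[i] = x
        values = xs
        names = list(coord_names) if coord_names else [f"x{d}" for d in range(dim)]
    return FeatureTrajectory(
        names=names, values=values, frame_interval=time_step,
        time_unit="time", source=f"simulate_langevin[{potential.description}]",
    )


# ---------------------------------------------------------------------------
# Toy structural frames: rigid scaffold + displaced ligand
# ---------------------------------------------------------------------------

_SCAFFOLD = np.array(
    [  # corners of a 3 Å cube: rigid 8-atom alignment scaffold
        [0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3],
        [3, 3, 0], [3, 0, 3], [0, 3, 3], [3, 3, 3],
    ],
    dtype=float,
)
_LIGAND_TEMPLATE = np.array(
    [  # 3-atom bent triatomic mimicking the two phosphorus + bridge oxygen
        [0.0, 0.0, 0.0], [1.6, 0.0, 0.0], [0.8, 1.2, 0.0],
    ]
)


def make_toy_structures(
    n_frames: int,
    displacement_sd: float,
    seed: int,
    cluster_separation: float = 10.0,
    cluster_probability: float = 0.5,
) -> tuple[CoordinateTrajectory, np.ndarray]:
    """Scaffold+ligand frames with a planted 2-cluster ligand distribution.

    Each frame holds a rigid 8-atom scaffold (the alignment subset) and a
    3-atom ligand (the metric subset) whose position relative to the
    scaffold is one of two planted sites ``cluster_separation`` Å apart,
    jittered by an isotropic Gaussian of sd ``displacement_sd``.  The
    whole frame is then rigidly rotated and translated at random, so only
    alignment-aware metrics can recover the planted partition.

    Returns the trajectory and the planted cluster labels.
    """
    if n_frames < 1:
        raise DataError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    site0 = np.array([6.0, 1.0, 1.0])
    site1 = site0 + np.array([cluster_separation, 0.0, 0.0])
    labels = (rng.random(n_frames) < cluster_probability).astype(int)
    coords = np.empty((n_frames, 11, 3))
    for i in range(n_frames):
        site = site1 if labels[i] else site0
        shift = displacement_sd * rng.standard_normal(3) if displacement_sd > 0 else 0.0
        ligand = _LIGAND_TEMPLATE + site + shift
        frame = np.vstack([_SCAFFOLD, ligand])
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        coords[i] = frame @ R.T + t
    traj = CoordinateTrajectory(
        atom_labels=[f"S{k}" for k in range(8)] + ["P1", "P2", "O"],
        coords=coords,
        frame_interval=1.0,
        alignment_subset=np.arange(8),
        metric_subset=np.arange(8, 11),
    )
    return traj, labels


# ---------------------------------------------------------------------------
# Ground-truth sidecar (key = value text file)
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    n = truth.stationary_probabilities.size
    with open(path, "w") as fh:
        fh.write(f"time_unit = {truth.time_unit}\n")
        fh.write(f"seed = {truth.seed}\n")
        for i in range(n):
            fh.write(
                f"stationary_probability_{i} = "
                f"{float(truth.stationary_probabilities[i])!r}\n"
            )
        for i in range(n):
            for j in range(n):
                if i != j:
                    fh.write(f"mfpt_{i}_{j} = {float(truth.mfpt_matrix[i, j])!r}\n")
        for key, val in truth.parameters.items():
            fh.write(f"param_{key} = {val!r}\n")
        for w in truth.warnings:
            fh.write(f"warning = {w}\n")


def read_truth(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, val = line.split("=", 1)
            out.setdefault(key.strip(), []).append(val.strip())
    return {k: v[0] if len(v) == 1 else v for k, v in out.items()}
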