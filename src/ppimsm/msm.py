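"""Markov state model estimation, lumping, validation, and kinetics.

Pipeline: discrete microstate trajectories → transition counts at a lag
(sliding window, with a re-crossing dwell filter) → restriction to the
largest strongly connected state set → row-normalized transition matrix
``T`` and its stationary distribution π → implied timescales
``τ_k = −τ / ln μ_k`` as a function of lag → spectral-gap choice of the
macrostate count → PCCA+ fuzzy lumping → lumped macrostate model →
populations, mean first passage times (exact linear solve) with
bootstrap uncertainties, and a residence-probability self-consistency
check.

Conventions
-----------
* The dwell (re-crossing) filter: a transition ``i → j`` observed at lag
  ``L`` is counted only if the chain stays in ``j`` for at least
  ``dwell_frames`` consecutive frames starting at the arrival frame;
  frames beyond the trajectory end truncate the check.  The rule applies
  to self-transitions as well.  ``dwell_frames=1`` disables the filter.
* Counts are never taken across trajectory boundaries.
* Raw counts are row-normalized for ``T`` (no symmetrization); a
  symmetrized analysis matrix ``(N + Nᵀ)/2`` is available for PCCA+ only,
  which needs a real spectrum.
* Eigenvalues are sorted by modulus, tie-broken by real part then index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ComplexSpectrumError, DataError, NumericalError, ReducibleMatrixError

__all__ = [
    "CountMatrix",
    "TransitionModel",
    "ImpliedTimescaleTable",
    "MacrostateModel",
    "BootstrapResult",
    "ResidenceValidation",
    "count_transitions",
    "largest_ergodic_subset",
    "transition_matrix",
    "implied_timescales",
    "choose_macrostate_count",
    "pcca_plus",
    "lump",
    "mfpt",
    "bootstrap",
    "validate_residence",
]

_REAL_TOL = 1e-10


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    counts: np.ndarray           # (n, n) non-negative integers
    lag_frames: int
    dwell_frames: int
    sliding: bool
    state_labels: np.ndarray     # row/column -> original microstate label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise DataError("transition counts must be >= 0")
        self.state_labels = np.asarray(self.state_labels, dtype=int)

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class TransitionModel:
    T: np.ndarray                # row-stochastic
    lag_frames: int
    lag_time: float              # lag_frames * frame_interval
    time_unit: str
    pi: np.ndarray               # stationary distribution, sums to 1
    eigenvalues: np.ndarray      # sorted by modulus desc (complex dtype)
    state_labels: np.ndarray     # row -> original microstate label

    def __post_init__(self) -> None:
        rows = self.T.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise NumericalError("transition matrix rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise NumericalError("stationary distribution must sum to 1")
        resid = np.abs(self.pi @ self.T - self.pi).max()
        if resid > 1e-8:
            raise NumericalError(f"pi T = pi violated (residual {resid:.2e})")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


@dataclass
class ImpliedTimescaleTable:
    """Implied timescales per lag; undefined entries are NaN and flagged."""

    lags_frames: np.ndarray          # (n_lags,)
    lags_time: np.ndarray            # (n_lags,) in time units
    timescales: np.ndarray           # (n_lags, k) in time units, NaN = undefined
    undefined: np.ndarray            # bool mask, True where τ_k is undefined
    time_unit: str
    n_requested: int


@dataclass
class MacrostateModel:
    m: int
    memberships: np.ndarray          # (n_micro, m) fuzzy, rows sum to 1
    crisp: np.ndarray                # (n_micro,) argmax of memberships
    macro_counts: np.ndarray         # (m, m)
    macro_T: np.ndarray              # row-stochastic
    lag_time: float
    time_unit: str
    populations: np.ndarray          # π-level: micro π summed per macrostate
    populations_from_counts: np.ndarray  # stationary vector of macro_T
    populations_sd: np.ndarray | None = None
    mfpt: np.ndarray | None = None       # (m, m), [i, f] = MFPT i→f
    mfpt_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.memberships.sum(axis=1), 1.0, atol=1e-8):
            raise NumericalError("membership rows must sum to 1")
        if not np.array_equal(self.crisp, np.argmax(self.memberships, axis=1)):
            raise NumericalError("crisp assignment must be the membership argmax")
        if not np.isclose(self.populations.sum(), 1.0, atol=1e-10):
            raise NumericalError("macrostate populations must sum to 1")


@dataclass
class BootstrapResult:
    populations_mean: np.ndarray
    populations_sd: np.ndarray
    mfpt_mean: np.ndarray
    mfpt_sd: np.ndarray
    n_replicates: int
    n_excluded: int
    excluded_reasons: list = field(default_factory=list)


@dataclass
class ResidenceValidation:
    multiples: np.ndarray            # lag multiples n
    predicted: np.ndarray            # (m, len(multiples)) [macro_T^n]_AA
    observed: np.ndarray             # same shape, NaN where undefined
    undefined: np.ndarray            # bool mask for observed
    max_abs_deviation: np.ndarray    # per macrostate, over defined points


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _as_paths(dtrajs) -> list[np.ndarray]:
    paths = [np.asarray(p, dtype=np.int64) for p in dtrajs]
    if not paths or any(p.size == 0 for p in paths):
        raise DataError("discrete trajectories must be non-empty")
    return paths


def _dwell_ok(s: np.ndarray, dwell: int) -> np.ndarray:
    """ok[t] = chain stays in s[t] for frames t .. t+dwell-1 (truncated)."""
    n = s.size
    ok = np.ones(n, dtype=bool)
    for off in range(1, dwell):
        m = n - off
        if m <= 0:
            break
        ok[:m] &= s[off:] == s[:m]
    return ok


def count_transitions(
    dtrajs,
    n_states: int,
    lag_frames: int,
    dwell_frames: int = 1,
    sliding: bool = True,
) -> CountMatrix:
    """Count lagged transitions with the re-crossing dwell filter.

    For every start frame ``t`` (step 1 if sliding, else ``lag_frames``)
    with ``t + lag_frames`` inside the same trajectory, the transition
    ``s(t) → s(t+lag_frames)`` is counted iff the chain remains in the
    arrival state for ``dwell_frames`` frames from the arrival on
    (truncated at the trajectory end).  Trajectories shorter than the lag
    contribute zero counts.
    """
    if lag_frames < 1 or dwell_frames < 1:
        raise DataError("lag_frames and dwell_frames must be >= 1")
    paths = _as_paths(dtrajs)
    N = np.zeros((n_states, n_states))
    for s in paths:
        if np.any(s < 0) or np.any(s >= n_states):
            raise DataError("state label outside [0, n_states)")
        if s.size <= lag_frames:
            continue
        ok = _dwell_ok(s, dwell_frames)
        step = 1 if sliding else lag_frames
        starts = np.arange(0, s.size - lag_frames, step)
        arrive = starts + lag_frames
        keep = ok[arrive]
        np.add.at(N, (s[starts[keep]], s[arrive[keep]]), 1.0)
    return CountMatrix(
        counts=N,
        lag_frames=lag_frames,
        dwell_frames=dwell_frames,
        sliding=sliding,
        state_labels=np.arange(n_states),
    )


def largest_ergodic_subset(cm: CountMatrix) -> CountMatrix:
    """Restrict to the largest strongly connected component of the count graph.

    States with no counts at all are dropped.  Component size ties break
    to the component containing the lowest original label.  The returned
    matrix's ``state_labels`` maps its rows back to the input labels.
    """
    N = cm.counts
    active = (N.sum(axis=1) + N.sum(axis=0)) > 0
    if not np.any(active):
        raise DataError("count matrix is empty; no ergodic subset exists")
    idx = np.flatnonzero(active)
    sub = N[np.ix_(idx, idx)]
    n_comp, labels = connected_components(
        csr_matrix(sub > 0), directed=True, connection="strong"
    )
    # rank components by size, then by total counts inside, then by the
    # lowest original state label (all deterministic)
    best, best_key = 0, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        within = float(sub[np.ix_(members, members)].sum())
        key = (members.size, within, -int(cm.state_labels[idx[members]].min()))
        if best_key is None or key > best_key:
            best, best_key = comp, key
    keep = idx[np.flatnonzero(labels == best)]
    return CountMatrix(
        counts=N[np.ix_(keep, keep)],
        lag_frames=cm.lag_frames,
        dwell_frames=cm.dwell_frames,
        sliding=cm.sliding,
        state_labels=cm.state_labels[keep],
    )


# ---------------------------------------------------------------------------
# Transition matrix and spectra
# ---------------------------------------------------------------------------

def _sorted_eigenvalues(T: np.ndarray) -> np.ndarray:
    vals = np.linalg.eigvals(T)
    order = np.lexsort((np.arange(vals.size), -vals.real, -np.abs(vals)))
    return vals[order]


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[k] - 1.0) > 1e-6:
        raise ReducibleMatrixError("no eigenvalue 1; matrix not stochastic/irreducible")
    v = np.real(vecs[:, k])
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-8):
        raise ReducibleMatrixError("stationary eigenvector has mixed signs")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def transition_matrix(
    cm: CountMatrix, frame_interval: float = 1.0, time_unit: str = "ns"
) -> TransitionModel:
    """Row-normalize counts: ``T_ij = N_ij / Σ_j N_ij``.

    π is the dominant left eigenvector of T normalized to sum 1 — the
    fixed point of the master equation — not the row-count marginal.
    Raises on zero rows, directing the caller to
    :func:`largest_ergodic_subset`.
    """
    N = cm.counts
    rows = N.sum(axis=1)
    if np.any(rows == 0):
        bad = cm.state_labels[np.flatnonzero(rows == 0)]
        raise DataError(
            f"states {bad.tolist()} have zero outgoing counts; apply "
            "largest_ergodic_subset first"
        )
    T = N / rows[:, None]
    return TransitionModel(
        T=T,
        lag_frames=cm.lag_frames,
        lag_time=cm.lag_frames * frame_interval,
        time_unit=time_unit,
        pi=_stationary(T),
        eigenvalues=_sorted_eigenvalues(T),
        state_labels=cm.state_labels,
    )


def implied_timescales(
    dtrajs,
    n_states: int,
    lags: list[int],
    n_timescales: int = 5,
    dwell_frames: int = 1,
    sliding: bool = True,
    frame_interval: float = 1.0,
    time_unit: str = "ns",
) -> ImpliedTimescaleTable:
    """Relaxation timescales τ_k = −τ / ln μ_k as a function of lag time.

    For each lag the full estimation chain runs (counts → ergodic subset
    → T → spectrum); the k largest non-unit eigenvalues that are real and
    in (0, 1) yield timescales, all others are reported as NaN with the
    ``undefined`` flag set — never silently dropped.
    """
    lags = [int(l) for l in lags]
    if any(l < 1 for l in lags):
        raise DataError("all lags must be >= 1")
    table = np.full((len(lags), n_timescales), np.nan)
    undef = np.ones((len(lags), n_timescales), dtype=bool)
    for row, lag in enumerate(lags):
        cm = count_transitions(dtrajs, n_states, lag, dwell_frames, sliding)
        try:
            model = transition_matrix(
                largest_ergodic_subset(cm), frame_interval, time_unit
            )
        except (DataError, NumericalError):
            continue
        vals = model.eigenvalues[1:]  # drop the unit eigenvalue
        tau = lag * frame_interval
        for k in range(min(n_timescales, vals.size)):
            mu = vals[k]
            if abs(mu.imag) < _REAL_TOL and 0.0 < mu.real < 1.0 - 1e-12:
                table[row, k] = -tau / np.log(mu.real)
                undef[row, k] = False
    return ImpliedTimescaleTable(
        lags_frames=np.asarray(lags),
        lags_time=np.asarray(lags, dtype=float) * frame_interval,
        timescales=table,
        undefined=undef,
        time_unit=time_unit,
        n_requested=n_timescales,
    )


def choose_macrostate_count(
    table: ImpliedTimescaleTable, lag_frames: int
) -> tuple[int, np.ndarray, bool]:
    """Spectral-gap rule: one clear gap in the timescales ⇒ that many slow sets.

    At the chosen lag, ``m = 1 + (1-based index of the largest ratio
    τ_k / τ_{k+1})`` over the finite timescales.  With a single finite
    timescale the convention is ``m = 2`` (one slow process separates two
    states), returned with a flag.  Returns ``(m, ratios, flagged)``.
    """
    rows = np.flatnonzero(table.lags_frames == lag_frames)
    if rows.size == 0:
        raise DataError(f"lag {lag_frames} not present in the timescale table")
    ts = table.timescales[rows[0]]
    finite = ts[np.isfinite(ts)]
    if finite.size == 0:
        raise NumericalError("all timescales undefined at the chosen lag")
    if finite.size == 1:
        return 2, np.empty(0), True
    ratios = finite[:-1] / finite[1:]
    return int(np.argmax(ratios)) + 2, ratios, False


# ---------------------------------------------------------------------------
# PCCA+ lumping
# ---------------------------------------------------------------------------

def _top_right_eigenvectors(T: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    """Top-m right eigenvectors, using the π-symmetrized form when T is
    reversible (numerically stable, guaranteed real), else a dense eig."""
    n = T.shape[0]
    if m > n:
        raise DataError(f"m={m} exceeds {n} microstates")
    flux = pi[:, None] * T
    if np.allclose(flux, flux.T, atol=1e-10):
        d = np.sqrt(pi)
        S = (T * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)
        vals, vecs = np.linalg.eigh(S)
        order = np.argsort(vals)[::-1]
        psi = vecs[:, order[:m]] / d[:, None]
    else:
        vals, vecs = np.linalg.eig(T)
        order = np.lexsort((np.arange(n), -vals.real, -np.abs(vals)))
        top = vals[order[:m]]
        if np.any(np.abs(top.imag) > _REAL_TOL):
            raise ComplexSpectrumError(
                "complex eigenvalues among the top m; build the analysis "
                "matrix from symmetrized counts (analysis_symmetrize)"
            )
        psi = np.real(vecs[:, order[:m]])
    # normalize: constant first vector, unit-norm columns
    psi = psi / np.linalg.norm(psi, axis=0)
    psi[:, 0] = 1.0
    return psi


def _inner_simplex_vertices(psi: np.ndarray) -> np.ndarray:
    """Index the m rows spanning the eigenvector simplex (maximal spread)."""
    n, m = psi.shape
    index = np.zeros(m, dtype=int)
    ortho = psi.copy()
    index[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[index[0]]
    for j in range(1, m):
        prev = ortho[index[j - 1]]
        norm = np.linalg.norm(prev)
        if norm > 0:
            prev = prev / norm
            ortho = ortho - np.outer(ortho @ prev, prev)
        index[j] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    return index


def pcca_plus(model: TransitionModel, m: int) -> np.ndarray:
    """Robust Perron Cluster Cluster Analysis: fuzzy memberships in m sets.

    The rows of the top-m right eigenvectors are mapped into the
    membership simplex by the inner-simplex construction: m rows of
    maximal spread are taken as vertices, the linear transform sending
    them to the simplex corners is applied to all rows, and feasibility
    is repaired by projection (clipping negatives, renormalizing rows).
    Crisp lumping is the row-wise argmax.  For m = 2 and a metastable
    spectrum this coincides with the sign split of the second
    eigenvector.
    """
    if m < 2:
        raise DataError("m must be >= 2")
    psi = _top_right_eigenvectors(model.T, model.pi, m)
    vertices = _inner_simplex_vertices(psi)
    A = np.linalg.inv(psi[vertices])
    chi = psi @ A
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1)
    if np.any(rowsum <= 0):
        raise NumericalError("PCCA+ produced an empty membership row")
    return chi / rowsum[:, None]


# ---------------------------------------------------------------------------
# Lumping, MFPT, bootstrap, validation
# ---------------------------------------------------------------------------

def _lump_counts(N: np.ndarray, crisp: np.ndarray, m: int) -> np.ndarray:
    macro = np.zeros((m, m))
    for a in range(m):
        ia = np.flatnonzero(crisp == a)
        for b in range(m):
            ib = np.flatnonzero(crisp == b)
            macro[a, b] = N[np.ix_(ia, ib)].sum()
    return macro


def lump(
    cm: CountMatrix,
    micro_model: TransitionModel,
    memberships: np.ndarray,
    lag_time: float,
    time_unit: str = "ns",
) -> MacrostateModel:
    """Aggregate an ergodic microstate model into macrostates.

    Macro counts are sums of micro counts over member pairs; the macro
    transition matrix row-normalizes them.  Macrostate populations are
    reported both as sums of the micro stationary vector (the primary
    output) and as the stationary vector of the lumped matrix.
    """
    m = memberships.shape[1]
    crisp = np.argmax(memberships, axis=1)
    present = np.unique(crisp)
    if present.size < m:
        missing = sorted(set(range(m)) - set(present.tolist()))
        raise NumericalError(f"macrostates {missing} have no member microstates")
    macro_counts = _lump_counts(cm.counts, crisp, m)
    rows = macro_counts.sum(axis=1)
    if np.any(rows == 0):
        raise NumericalError("macrostate with zero outgoing counts")
    macro_T = macro_counts / rows[:, None]
    pops = np.array([micro_model.pi[crisp == a].sum() for a in range(m)])
    pops = pops / pops.sum()
    return MacrostateModel(
        m=m,
        memberships=memberships,
        crisp=crisp,
        macro_counts=macro_counts,
        macro_T=macro_T,
        lag_time=lag_time,
        time_unit=time_unit,
        populations=pops,
        populations_from_counts=_stationary(macro_T),
    )


def _check_irreducible(T: np.ndarray) -> None:
    n_comp, _ = connected_components(
        csr_matrix(T > 0), directed=True, connection="strong"
    )
    if n_comp != 1:
        raise ReducibleMatrixError("transition matrix is reducible")


def mfpt(T: np.ndarray, lag_time: float) -> np.ndarray:
    """Mean first passage times by exact linear solve.

    For each target ``f``: ``MFPT_if = Σ_j P_ij (t_lag + MFPT_jf)`` with
    the boundary condition ``MFPT_ff = 0``, i.e. the linear system
    ``(I − P_rest) m = t_lag · 1`` over the non-target states.  No
    iteration, no tolerance.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise NumericalError("MFPT needs a row-stochastic matrix")
    _check_irreducible(T)
    M = np.zeros((n, n))
    for f in range(n):
        rest = [i for i in range(n) if i != f]
        A = np.eye(n - 1) - T[np.ix_(rest, rest)]
        M[rest, f] = np.linalg.solve(A, np.full(n - 1, lag_time))
    return M


def mfpt_micro_to_macrostates(
    model: TransitionModel, crisp: np.ndarray, lag_time: float
) -> np.ndarray:
    """Macrostate MFPTs from the micro-level first-passage system.

    For each target macrostate ``B`` the linear system is solved on the
    microstate transition matrix with every microstate of ``B``
    absorbing; the entry ``[A, B]`` is the π-weighted average over the
    source macrostate's microstates.  Cross-check for the primary
    lumped-matrix MFPT; the two agree when the macrostates are cleanly
    metastable.
    """
    T, pi = model.T, model.pi
    crisp = np.asarray(crisp, dtype=int)
    if crisp.size != T.shape[0]:
        raise DataError("crisp must assign every microstate of the model")
    m = int(crisp.max()) + 1
    _check_irreducible(T)
    out = np.zeros((m, m))
    for btgt in range(m):
        rest = np.flatnonzero(crisp != btgt)
        A = np.eye(rest.size) - T[np.ix_(rest, rest)]
        mf = np.zeros(T.shape[0])
        mf[rest] = np.linalg.solve(A, np.full(rest.size, lag_time))
        for a in range(m):
            if a == btgt:
                continue
            src = np.flatnonzero(crisp == a)
            out[a, btgt] = float((pi[src] * mf[src]).sum() / pi[src].sum())
    return out


def _per_trajectory_counts(
    dtrajs, n_states: int, lag: int, dwell: int, sliding: bool
) -> list[np.ndarray]:
    return [
        count_transitions([p], n_states, lag, dwell, sliding).counts
        for p in _as_paths(dtrajs)
    ]


def bootstrap(
    dtrajs,
    n_states: int,
    crisp_full: np.ndarray,
    lag_frames: int,
    dwell_frames: int = 1,
    sliding: bool = True,
    frame_interval: float = 1.0,
    time_unit: str = "ns",
    n_replicates: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Trajectory-level bootstrap of populations and MFPTs.

    Whole trajectories are resampled with replacement to the original
    count; microstate definitions and the micro→macro assignment stay
    fixed across replicates.  ``crisp_full`` maps every original
    microstate label to its macrostate (−1 for microstates outside the
    full-data ergodic subset; such states are ignored in the lumped
    statistics).  Each replicate reruns counts → ergodic subset → T →
    lumped model.  Replicates whose resample loses a macrostate (or
    yields a reducible macro matrix) are excluded and counted.
    """
    if n_replicates < 2:
        raise DataError("n_replicates must be >= 2")
    paths = _as_paths(dtrajs)
    crisp = np.asarray(crisp_full, dtype=int)
    if crisp.size != n_states:
        raise DataError("crisp_full must have one entry per microstate")
    m = int(crisp.max()) + 1
    per_traj = _per_trajectory_counts(paths, n_states, lag_frames, dwell_frames, sliding)
    per_traj = np.stack(per_traj)
    rng = np.random.default_rng(seed)
    pops, mfpts, reasons = [], [], []
    for _ in range(n_replicates):
        pick = rng.integers(0, len(paths), size=len(paths))
        N = per_traj[pick].sum(axis=0)
        cm = CountMatrix(N, lag_frames, dwell_frames, sliding, np.arange(n_states))
        try:
            erg = largest_ergodic_subset(cm)
            model = transition_matrix(erg, frame_interval, time_unit)
        except (DataError, NumericalError) as exc:
            reasons.append(str(exc))
            continue
        macro_of_row = crisp[erg.state_labels]
        if np.unique(macro_of_row[macro_of_row >= 0]).size < m:
            reasons.append("resample lost a macrostate")
            continue
        p = np.array([model.pi[macro_of_row == a].sum() for a in range(m)])
        p = p / p.sum()
        macro_counts = _lump_counts(erg.counts, macro_of_row, m)
        rows = macro_counts.sum(axis=1)
        if np.any(rows == 0):
            reasons.append("macrostate with zero outgoing counts")
            continue
        macro_T = macro_counts / rows[:, None]
        try:
            M = mfpt(macro_T, lag_frames * frame_interval)
        except NumericalError as exc:
            reasons.append(str(exc))
            continue
        pops.append(p)
        mfpts.append(M)
    if not pops:
        raise NumericalError("all bootstrap replicates were degenerate")
    P = np.stack(pops)
    F = np.stack(mfpts)
    ddof = 1 if len(pops) > 1 else 0
    return BootstrapResult(
        populations_mean=P.mean(axis=0),
        populations_sd=P.std(axis=0, ddof=ddof),
        mfpt_mean=F.mean(axis=0),
        mfpt_sd=F.std(axis=0, ddof=ddof),
        n_replicates=n_replicates,
        n_excluded=n_replicates - len(pops),
        excluded_reasons=reasons,
    )


def validate_residence(
    macro_T: np.ndarray,
    crisp: np.ndarray,
    micro_labels_of_row: np.ndarray,
    dtrajs,
    lag_frames: int,
    multiples,
) -> ResidenceValidation:
    """Compare model-predicted and directly counted residence probabilities.

    Predicted: ``[macro_Tⁿ]_AA``.  Observed: among frames assigned to
    macrostate A (through the crisp micro→macro map), the fraction still
    in A after ``n · lag`` frames, counted with the sliding window
    directly from the discrete trajectories.  Frames whose microstate
    fell outside the ergodic subset are skipped.  Points beyond every
    trajectory's length are NaN and flagged.
    """
    multiples = np.asarray(sorted(int(n) for n in multiples))
    if np.any(multiples < 0):
        raise DataError("lag multiples must be >= 0")
    m = macro_T.shape[0]
    # map original microstate label -> macrostate (-1 = outside ergodic set)
    n_micro = int(max(int(np.max(p)) for p in _as_paths(dtrajs))) + 1
    micro_to_macro = np.full(max(n_micro, micro_labels_of_row.max() + 1), -1)
    micro_to_macro[micro_labels_of_row] = crisp
    macro_paths = [micro_to_macro[np.asarray(p)] for p in _as_paths(dtrajs)]

    predicted = np.empty((m, multiples.size))
    for col, n in enumerate(multiples):
        Tn = np.linalg.matrix_power(macro_T, int(n))
        predicted[:, col] = np.diag(Tn)
    observed = np.full((m, multiples.size), np.nan)
    undefined = np.ones((m, multiples.size), dtype=bool)
    for col, n in enumerate(multiples):
        shift = int(n) * lag_frames
        num = np.zeros(m)
        den = np.zeros(m)
        for mp in macro_paths:
            if mp.size <= shift:
                continue
            a = mp[: mp.size - shift] if shift else mp
            b = mp[shift:]
            valid = (a >= 0) & (b >= 0)
            for A in range(m):
                sel = valid & (a == A)
                den[A] += sel.sum()
                num[A] += (b[sel] == A).sum()
        for A in range(m):
            if den[A] > 0:
                observed[A, col] = num[A] / den[A]
                undefined[A, col] = False
    dev = np.abs(predicted - observed)
    max_dev = np.array(
        [np.nanmax(dev[A]) if np.any(~undefined[A]) else np.nan for A in range(m)]
    )
    return ResidenceValidation(
        multiples=multiples,
        predicted=predicted,
        observed=observed,
        undefined=undefined,
        max_abs_deviation=max_dev,
    )
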