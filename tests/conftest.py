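"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (enumeration, Monte-Carlo,
quadrature) and independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


def sample_chain(T: np.ndarray, n_frames: int, seed: int, start: int | None = None) -> np.ndarray:
    """Sample a discrete Markov chain directly from a transition matrix."""
    rng = np.random.default_rng(seed)
    T = np.asarray(T, float)
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    path = np.empty(n_frames, dtype=np.int64)
    if start is None:
        vals, vecs = np.linalg.eig(T.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
        v = np.abs(v) / np.abs(v).sum()
        path[0] = rng.choice(n, p=v)
    else:
        path[0] = start
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t], side="right")
    return np.clip(path, 0, n - 1)


def sample_chains(T, n_traj, n_frames, seed, start=None) -> list[np.ndarray]:
    return [sample_chain(T, n_frames, seed + i, start) for i in range(n_traj)]


def mc_first_passage(
    T: np.ndarray, start: int, target, n_paths: int, seed: int,
    lag_time: float = 1.0, max_steps: int = 10**6,
) -> tuple[float, float]:
    """Monte-Carlo mean first passage time (mean, standard error)."""
    rng = np.random.default_rng(seed)
    T = np.asarray(T, float)
    cum = np.cumsum(T, axis=1)
    targets = np.atleast_1d(np.asarray(target))
    state = np.full(n_paths, start, dtype=np.int64)
    steps = np.zeros(n_paths, dtype=np.int64)
    active = ~np.isin(state, targets)
    it = 0
    while np.any(active):
        it += 1
        if it > max_steps:
            raise RuntimeError("first-passage simulation did not absorb")
        s = state[active]
        u = rng.random(s.size)
        state[active] = np.array(
            [np.searchsorted(cum[si], ui, side="right") for si, ui in zip(s, u)]
        ).clip(0, T.shape[0] - 1)
        steps[active] += 1
        active = ~np.isin(state, targets)
    times = steps * lag_time
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(n_paths))


def brute_force_kcenter_radius(X: np.ndarray, k: int) -> float:
    """Optimal k-center max radius by enumeration over all center subsets."""
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    best = np.inf
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    for centers in itertools.combinations(range(n), k):
        radius = D[:, list(centers)].min(axis=1).max()
        best = min(best, radius)
    return float(best)


def enumerate_partitions(n: int, m: int):
    """All partitions of n items into exactly m nonempty unlabeled sets,
    yielded as canonical label arrays."""
    for labels in itertools.product(range(m), repeat=n):
        # canonical: label first occurrences in increasing order
        seen: dict[int, int] = {}
        canon = []
        for lab in labels:
            seen.setdefault(lab, len(seen))
            canon.append(seen[lab])
        if tuple(canon) != labels:
            continue
        if len(set(labels)) == m:
            yield np.asarray(labels)


def best_metastability_partition(T: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    """Exhaustive search for the m-partition maximising Σ_A [lumped T]_AA."""
    n = T.shape[0]
    best_score, best_labels = -np.inf, None
    for labels in enumerate_partitions(n, m):
        score = 0.0
        for a in range(m):
            ia = labels == a
            wa = pi[ia].sum()
            score += (pi[ia, None] * T[np.ix_(ia, ia)]).sum() / wa
        if score > best_score:
            best_score, best_labels = score, labels
    return best_labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Equality of partitions up to label permutation."""
    a, b = np.asarray(a), np.asarray(b)
    mapping: dict[int, int] = {}
    for x, y in zip(a, b):
        if mapping.setdefault(int(x), int(y)) != int(y):
            return False
    return len(set(mapping.values())) == len(mapping)


@pytest.fixture(scope="session")
def preset_model():
    from ppimsm.synthetic import ppi_release_preset

    return ppi_release_preset()


@pytest.fixture(scope="session")
def toy_structures():
    from ppimsm.synthetic import make_toy_structures

    return make_toy_structures(n_frames=40, displacement_sd=0.5, seed=11)
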