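"""Discrete-time Markov chain calibration and forward simulation.

The calibration inverts per-state mean dwell times and target stationary
fractions into a row-stochastic per-frame transition matrix: the diagonal
is fixed by dwell_k = Δt / (1 − A_kk), and off-diagonal mass is solved in
probability-flow space (non-negative least squares, balanced in- and
out-flux per state) with ties broken toward a uniform off-diagonal split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear


class InfeasibleTargetsError(ValueError):
    """No non-negative off-diagonal solution reaches the requested
    stationary targets."""

    def __init__(self, state: int, residual: float):
        self.state = state
        self.residual = residual
        super().__init__(
            f"stationary targets infeasible: flow balance for state {state} "
            f"violated by {residual:.3g}"
        )


@dataclass
class StatePath:
    """Hidden-state labels per frame."""

    states: np.ndarray
    frame_interval: float = 5.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or len(self.states) < 1:
            raise ValueError("state path must be a non-empty 1D sequence")

    def __len__(self):
        return len(self.states)


def build_transition_matrix(
    dwell_means,
    stationary_targets=None,
    frame_interval: float = 5.0,
    residual_tol: float = 1e-8,
):
    """Calibrate a per-frame transition matrix from dwell times and
    stationary targets.

    Parameters
    ----------
    dwell_means : per-state mean dwell times in minutes (np.inf allowed;
        an infinite dwell pins the diagonal at 1).
    stationary_targets : per-state stationary fractions summing to 1, or
        None for a uniform off-diagonal split with no flow constraint.
    frame_interval : frame spacing in minutes.

    Returns
    -------
    (A, pi_achieved) : the row-stochastic matrix and the stationary
    distribution actually achieved by it.
    """
    dwell = np.asarray(dwell_means, dtype=float)
    K = dwell.shape[0]
    if np.any(dwell < frame_interval):
        raise ValueError("dwell means must be >= frame_interval")
    with np.errstate(divide="ignore"):
        leave = np.where(np.isinf(dwell), 0.0, frame_interval / dwell)
    diag = 1.0 - leave

    if K == 1:
        return np.array([[1.0]]), np.array([1.0])

    if stationary_targets is None:
        A = np.full((K, K), 0.0)
        for k in range(K):
            A[k] = leave[k] / (K - 1)
            A[k, k] = diag[k]
        return A, _stationary_power(A)

    pi = np.asarray(stationary_targets, dtype=float)
    if pi.shape[0] != K:
        raise ValueError("stationary_targets length must match dwell_means")
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("stationary_targets must be >= 0 and sum to 1")
    if np.any((pi == 0) & (leave > 0)):
        k = int(np.argmax((pi == 0) & (leave > 0)))
        raise InfeasibleTargetsError(k, float(leave[k]))

    f = pi * leave  # per-state outflux per frame
    if np.all(f == 0):
        return np.eye(K), pi.copy()

    # unknowns: off-diagonal flows F_kj (k != j), flattened row-major
    pairs = [(k, j) for k in range(K) for j in range(K) if j != k]
    n_var = len(pairs)
    A_eq = np.zeros((2 * K, n_var))
    b_eq = np.concatenate([f, f])  # row sums then column sums
    for v, (k, j) in enumerate(pairs):
        A_eq[k, v] = 1.0  # out of k
        A_eq[K + j, v] = 1.0  # into j
    # flow balance is enforced with heavy weight; a tiny pull toward the
    # uniform split breaks ties among exact solutions
    W = 1e6
    w = 1e-6
    A_reg = np.sqrt(w) * np.eye(n_var)
    b_reg = np.sqrt(w) * np.array([f[k] / (K - 1) for k, _ in pairs])
    res = lsq_linear(
        np.vstack([W * A_eq, A_reg]),
        np.concatenate([W * b_eq, b_reg]),
        bounds=(0.0, np.inf),
        tol=1e-14,
        lsmr_tol=1e-14,
        max_iter=500,
    )
    resid = A_eq @ res.x - b_eq
    scale = max(1.0, float(np.max(np.abs(b_eq))))
    if np.max(np.abs(resid)) > residual_tol * scale + 1e-12:
        worst = int(np.argmax(np.abs(resid))) % K
        raise InfeasibleTargetsError(worst, float(np.max(np.abs(resid))))

    A = np.zeros((K, K))
    for v, (k, j) in enumerate(pairs):
        if pi[k] > 0:
            A[k, j] = res.x[v] / pi[k]
    np.fill_diagonal(A, 0.0)
    rows = A.sum(axis=1)
    for k in range(K):
        if rows[k] > 0:
            A[k] *= leave[k] / rows[k]  # exact row-stochastic renormalisation
        A[k, k] = 1.0 - A[k].sum()
    return A, _stationary_power(A)


def _stationary_power(A: np.ndarray, tol: float = 1e-14, max_iter: int = 200000):
    """Stationary distribution by repeated application of A^T."""
    K = A.shape[0]
    pi = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        nxt = pi @ A
        if np.max(np.abs(nxt - pi)) < tol:
            return nxt / nxt.sum()
        pi = nxt
    return pi / pi.sum()


def simulate_state_path(model, n_frames: int, seed: int = 0) -> StatePath:
    """Sample a hidden-state path of length ``n_frames`` from the model's
    initial distribution and transition matrix. Deterministic per seed."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    A = np.asarray(model.transmat, dtype=float)
    if np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix must be row-stochastic")
    pi = np.asarray(model.startprob, dtype=float)
    rng = np.random.default_rng(seed)
    K = A.shape[0]
    states = np.empty(n_frames, dtype=np.int64)
    cum_A = np.cumsum(A, axis=1)
    u = rng.random(n_frames)
    states[0] = np.searchsorted(np.cumsum(pi), u[0], side="right")
    for t in range(1, n_frames):
        states[t] = np.searchsorted(cum_A[states[t - 1]], u[t], side="right")
    np.clip(states, 0, K - 1, out=states)
    return StatePath(states=states, frame_interval=model.frame_interval)
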