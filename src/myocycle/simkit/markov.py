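"""Synthetic discrete state trajectories for Markov state model estimation."""

from __future__ import annotations

import numpy as np


def make_state_trajectory(T, n_steps: int, seed: int = 0,
                          init: int | None = None) -> np.ndarray:
    """Sample a discrete-time Markov chain from a row-stochastic matrix.

    Parameters
    ----------
    T : (n, n) array
        Row-stochastic transition matrix; every row must sum to 1 within
        1e-10.
    n_steps : int
        Trajectory length (number of states emitted).
    init : int, optional
        Initial state; drawn uniformly when omitted.

    Returns
    -------
    ndarray of int
        State labels in [0, n).  Empirical transition frequencies converge to
        ``T`` as ``n_steps`` grows.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("T must be a square matrix")
    if np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-10):
        raise ValueError("rows of T must sum to 1 within 1e-10")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    u = rng.random(n_steps)
    traj = np.empty(n_steps, dtype=np.int64)
    state = int(init) if init is not None else int(rng.integers(n))
    traj[0] = state
    for i in range(1, n_steps):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, n - 1)  # guard against roundoff at u ~ 1
        traj[i] = state
    return traj
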