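"""Markov state model estimation from discrete state trajectories.

Transition counts at a lag are regularized with a pseudocount of 1/n (n =
number of microstates) added to every element before row normalization, which
guarantees a strictly positive, ergodic transition matrix; the equilibrium
distribution is its leading left eigenvector and the implied timescales are
t_i(tau) = -tau / ln |lambda_i(tau)|, whose flatness across lags is the
Markovianity (lag-selection) diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix with its spectral summaries."""

    counts: np.ndarray         #: raw transition counts at the lag
    T: np.ndarray              #: row-stochastic, strictly positive
    lag: int                   #: lag in strides
    pi: np.ndarray             #: equilibrium distribution (sums to 1)
    eigenvalues: np.ndarray    #: sorted by magnitude, descending
    timescales: np.ndarray     #: implied timescales (strides), descending
    reversible: bool = True    #: False when complex eigenvalues appeared


def count_transitions(trajectories, lag: int = 1) -> np.ndarray:
    """Sliding-window transition counts at the given lag.

    ``C[i, j]`` counts pairs ``(s_t = i, s_{t+lag} = j)`` within each
    trajectory (no cross-trajectory pairs), summed over trajectories.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 stride")
    trajs = [np.asarray(t, dtype=np.int64) for t in trajectories]
    if any(len(t) <= lag for t in trajs):
        raise ValueError("every trajectory must be longer than the lag")
    n = int(max(t.max() for t in trajs)) + 1
    C = np.zeros((n, n), dtype=float)
    for t in trajs:
        np.add.at(C, (t[:-lag], t[lag:]), 1.0)
    return C


def estimate_transition_matrix(counts, n_states: int | None = None,
                               lag: int = 1) -> TransitionModel:
    """Estimate a transition matrix with the 1/n pseudocount prior.

    ``T = rownorm(C + 1/n)`` with n the number of microstates, so zero data
    yields the uniform matrix and every entry stays positive.  The
    equilibrium distribution is the left eigenvector of the unit eigenvalue,
    normalized to sum to 1.
    """
    C = np.asarray(counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be square")
    if np.any(C < 0):
        raise ValueError("counts must be nonnegative")
    if n_states is None:
        n_states = C.shape[0]
    if n_states == 0:
        raise ValueError("zero-state model")
    if C.shape[0] != n_states:
        padded = np.zeros((n_states, n_states))
        padded[:C.shape[0], :C.shape[1]] = C
        C = padded
    reg = C + 1.0 / n_states
    T = reg / reg.sum(axis=1, keepdims=True)

    vals, vecs = linalg.eig(T, left=True, right=False)
    order = np.argsort(-np.abs(vals))
    vals = vals[order]
    vecs = vecs[:, order]
    if np.any(np.abs(vals.imag) > 1e-12):
        warnings.warn("complex eigenvalues: transition matrix is not "
                      "reversible; timescales use eigenvalue magnitudes",
                      stacklevel=2)
        reversible = False
    else:
        reversible = True
    pi = np.real(vecs[:, 0])
    pi = np.abs(pi) / np.abs(pi).sum()

    mags = np.abs(vals[1:])
    with np.errstate(divide="ignore"):
        ts = np.where(mags >= 1.0, np.inf, -lag / np.log(mags))
    return TransitionModel(counts=C, T=T, lag=lag, pi=pi,
                           eigenvalues=vals, timescales=ts,
                           reversible=reversible)


def implied_timescales(trajectories, lags, n_states: int | None = None
                       ) -> dict[int, np.ndarray]:
    """Implied timescale curves t_i(tau) = -tau/ln lambda_i(tau) per lag.

    Returns a mapping lag -> descending timescales (in strides).  Flat
    curves across lags indicate Markovian behavior at those lags.
    """
    lags = list(lags)
    if len(lags) < 2:
        raise ValueError("need >= 2 lags for the implied-timescales test")
    out = {}
    for lag in lags:
        C = count_transitions(trajectories, lag=lag)
        model = estimate_transition_matrix(C, n_states=n_states, lag=lag)
        out[lag] = model.timescales
    return out
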