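"""Synthetic stopped-flow transients and mant-ATP single-turnover decays.

ATP-induced dissociation of myosin from pyrene-actin relieves the quench, so
dissociation transients rise as 1 - exp(-k_obs t) with
k_obs = K1 k+2 [ATP] / (1 + K1 [ATP]).  ADP competition at fixed ATP scales the
zero-ADP rate by 1/(1 + [ADP]/K_ADP).  Single-turnover decays mix the slow
(SRX) and fast (DRX) relaxed populations after the cold-ATP chase.
"""

from __future__ import annotations

import numpy as np

from ..core import Trace


def make_dissociation_transients(
    K1: float,
    k_plus2: float,
    atp_list,
    amplitude: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_points: int = 400,
    n_lifetimes: float = 6.0,
) -> list[Trace]:
    """Simulate ATP-induced dissociation transients at each [ATP].

    Each trace rises as ``amplitude * (1 - exp(-k_obs t))`` with the true
    ``k_obs`` from the ATP-dependence hyperbola stored in the metadata.  The
    time base spans ``n_lifetimes / k_obs`` per trace.
    """
    atp_list = list(atp_list)
    if len(atp_list) == 0:
        raise ValueError("atp_list must contain at least one concentration")
    rng = np.random.default_rng(seed)
    traces = []
    for atp in atp_list:
        if atp <= 0:
            raise ValueError("ATP concentrations must be positive")
        kobs = K1 * k_plus2 * atp / (1.0 + K1 * atp)
        t = np.linspace(0.0, n_lifetimes / kobs, n_points)
        y = amplitude * (1.0 - np.exp(-kobs * t))
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(Trace(t, y, meta={
            "assay": "atp_dissociation", "nucleotide": "ATP",
            "conc_uM": float(atp), "true_kobs": float(kobs),
            "direction": "rise", "temperature_C": 20.0,
        }))
    return traces


def make_adp_competition_transients(
    k0: float,
    K_ADP: float,
    adp_list,
    amplitude: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    fixed_atp: float = 20.0,
    n_points: int = 400,
    n_lifetimes: float = 6.0,
) -> list[Trace]:
    """Simulate dissociation transients under ADP competition at fixed [ATP].

    Per-trace ``k_obs = k0 / (1 + [ADP]/K_ADP)``; ``k0`` is the observed rate
    at zero ADP for the chosen fixed ATP concentration.
    """
    if K_ADP <= 0:
        raise ValueError("K_ADP must be positive")
    adp_list = list(adp_list)
    if len(adp_list) == 0:
        raise ValueError("adp_list must contain at least one concentration")
    rng = np.random.default_rng(seed)
    traces = []
    for adp in adp_list:
        if adp < 0:
            raise ValueError("ADP concentrations must be non-negative")
        kobs = k0 / (1.0 + adp / K_ADP)
        t = np.linspace(0.0, n_lifetimes / kobs, n_points)
        y = amplitude * (1.0 - np.exp(-kobs * t))
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(Trace(t, y, meta={
            "assay": "adp_competition", "nucleotide": "ADP",
            "conc_uM": float(adp), "fixed_atp_uM": float(fixed_atp),
            "true_kobs": float(kobs), "direction": "rise",
            "temperature_C": 20.0,
        }))
    return traces


def make_turnover_decay(
    p_srx: float,
    k_slow: float,
    k_fast: float,
    duration_s: float = 940.0,
    dt_s: float = 1.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    chase_time_s: float = 60.0,
) -> Trace:
    """Simulate a mant-ATP single-turnover fluorescence decay.

    The trace holds a pre-chase plateau at 1 for ``chase_time_s``, then decays
    as ``p_srx exp(-k_slow t) + (1-p_srx) exp(-k_fast t)`` for ``duration_s``
    after the cold-ATP chase, sampled every ``dt_s``.  The SRX and DRX
    populations are treated as a static mixture over the chase (no
    interconversion).
    """
    if not 0.0 <= p_srx <= 1.0:
        raise ValueError("p_srx must lie in [0, 1]")
    if k_slow >= k_fast:
        raise ValueError("k_slow must be < k_fast (phase labels would be "
                         "ambiguous)")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, chase_time_s + duration_s + dt_s / 2, dt_s)
    post = t >= chase_time_s
    tau = t[post] - chase_time_s
    y = np.ones_like(t)
    y[post] = p_srx * np.exp(-k_slow * tau) + (1 - p_srx) * np.exp(-k_fast * tau)
    y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return Trace(t, y, meta={
        "assay": "single_turnover", "chase_time_s": float(chase_time_s),
        "true_p_srx": float(p_srx), "true_k_slow": float(k_slow),
        "true_k_fast": float(k_fast),
    })
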