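"""Synthetic three-bead optical-trap recordings.

The free dumbbell position is an Ornstein-Uhlenbeck process whose stationary
variance reflects the trap stiffness (equipartition) and whose corner
frequency reflects stiffness over drag.  During an actomyosin binding event
the positional variance drops (the myosin link stiffens the system) and the
mean shifts by the first substep d1 at attachment, then by d2 after an
exponentially distributed delay.  Event starts are Poisson; attachment
durations are exponential with the ATP-limited detachment rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .dataset import SyntheticDataset
from .scheme import KT_PN_NM


@dataclass
class TrapEvent:
    """Ground-truth binding event of a trap simulation (times in s, nm)."""

    start: float
    end: float
    d1: float
    d2: float
    #: Delay from attachment to the second substep (s); events shorter than
    #: their delay never complete the second substep.
    substep_delay: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def completed_substep(self) -> bool:
        return self.substep_delay < self.duration


@dataclass
class TrapSimConfig:
    """Conditions of a simulated optical-trap recording."""

    sample_rate: float = 20_000.0      #: Hz
    filter_cutoff: float = 10_000.0    #: Hz (anti-alias; metadata)
    stiffness: float = 0.04            #: trap stiffness, pN/nm
    corner_freq: float = 2_000.0       #: OU corner frequency, Hz
    free_variance: float | None = None   #: nm^2; default kT/stiffness
    bound_variance: float | None = None  #: nm^2; default free/4
    event_rate: float = 1.0            #: binding events per second of free time
    atp: float = 1.0                   #: uM, metadata for the detachment regime
    detach_rate: float | None = None   #: 1/s; default K1k2-limited at cfg.atp
    K1k2: float = 6.7                  #: 1/(uM s), sets detach_rate from atp
    d1: float = 3.3                    #: nm
    d2: float = 2.0                    #: nm
    substep_delay_rate: float = 100.0  #: 1/s

    def __post_init__(self) -> None:
        if self.free_variance is None:
            self.free_variance = KT_PN_NM / self.stiffness
        if self.bound_variance is None:
            self.bound_variance = self.free_variance / 4.0
        if not self.bound_variance < self.free_variance:
            raise ValueError("bound_variance must be < free_variance")
        if self.sample_rate < 2.0 * self.filter_cutoff:
            raise ValueError("sample_rate must be >= 2 * filter_cutoff "
                             "(Nyquist)")
        if self.detach_rate is None:
            self.detach_rate = self.K1k2 * self.atp


def make_trap_trace(cfg: TrapSimConfig, duration_s: float, seed: int = 0
                    ) -> SyntheticDataset:
    """Simulate a bead-position recording with ground-truth binding events.

    Returns a :class:`SyntheticDataset` whose observables dict holds the
    position array (nm), the sample rate, and metadata; ``ground_truth``
    holds the list of :class:`TrapEvent` and the generating config.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * cfg.sample_rate))
    dt = 1.0 / cfg.sample_rate

    # draw non-overlapping events: Exp(event_rate) gaps, Exp(detach) durations
    events: list[TrapEvent] = []
    t = 0.0
    while cfg.event_rate > 0:
        t += rng.exponential(1.0 / cfg.event_rate)
        dur = rng.exponential(1.0 / cfg.detach_rate)
        if t + dur >= duration_s:
            break
        delay = rng.exponential(1.0 / cfg.substep_delay_rate)
        events.append(TrapEvent(start=t, end=t + dur, d1=cfg.d1, d2=cfg.d2,
                                substep_delay=delay))
        t += dur
    if cfg.event_rate > 0 and not events:
        warnings.warn("trace too short to hold one event at the configured "
                      "rates; ground truth is empty", stacklevel=2)

    # piecewise mean and sigma over the sample grid
    mean = np.zeros(n)
    sigma = np.full(n, np.sqrt(cfg.free_variance))
    sd_bound = np.sqrt(cfg.bound_variance)
    for ev in events:
        i0, i1 = int(ev.start / dt), min(int(ev.end / dt), n)
        mean[i0:i1] = ev.d1
        sigma[i0:i1] = sd_bound
        if ev.completed_substep:
            j = min(int((ev.start + ev.substep_delay) / dt), i1)
            mean[j:i1] = ev.d1 + ev.d2

    # unit-variance OU via exact AR(1) recursion (shared corner frequency)
    tau = 1.0 / (2.0 * np.pi * cfg.corner_freq)
    a = np.exp(-dt / tau)
    innov = rng.normal(0.0, np.sqrt(1.0 - a * a), size=n)
    innov[0] = rng.normal()  # stationary start
    u = lfilter([1.0], [1.0, -a], innov)
    x = mean + sigma * u

    return SyntheticDataset(
        observables={"position_nm": x, "sample_rate": cfg.sample_rate,
                     "atp_uM": cfg.atp, "stiffness_pn_nm": cfg.stiffness},
        ground_truth={"events": events, "config": cfg},
        seed=seed,
        noise_model={"kind": "ornstein-uhlenbeck",
                     "corner_freq_hz": cfg.corner_freq,
                     "free_variance_nm2": cfg.free_variance,
                     "bound_variance_nm2": cfg.bound_variance},
    )
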