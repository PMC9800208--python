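"""Ground-truth kinetic parameterization of the actomyosin chemomechanical cycle.

The cycle is modeled as a serial loop of five biochemical states at reference
conditions (saturating ATP and actin):

    AM --(k+2)--> M.ATP --(k_hyd)--> M.ADP.Pi --(k_attach)--> AM.ADP.Pi
       --(k_Pi)--> AM.ADP --(k-ADP)--> AM

Each state's dwell is exponential with the state's exit rate, so the analytic
mean cycle time is t_cycle = sum(1/rate) and the steady-state turnover rate is
k_cat = 1/t_cycle.  The scheme also carries the parameters the individual
assays probe: ATP binding (K1, k+2), ADP competition (K_ADP), working-stroke
substeps (d1, d2), and the SRX/DRX two-population relaxed-state phenomenology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Boltzmann constant times temperature at 25 degC, in pN nm.
KT_PN_NM = 4.11


@dataclass
class RateScheme:
    """Ground-truth kinetic parameters of the chemomechanical cycle.

    Units: equilibrium constant K1 in 1/uM, first-order rates in 1/s,
    second-order rates in 1/(uM s), K_ADP in uM, displacements in nm.
    """

    #: ATP-binding equilibrium constant (1/uM); 1/K1 is the ATP affinity.
    K1: float = 1.0 / 79.8
    #: Maximal ATP-induced actomyosin dissociation rate (1/s).
    k_plus2: float = 520.7
    #: ADP dissociation constant (uM): the [ADP] at which ATP-induced
    #: dissociation is half-inhibited in the competition assay.
    K_ADP: float = 120.7
    #: ADP release rate (1/s); rate-limiting for detachment at saturating ATP.
    k_minusADP: float = 112.0
    #: Optional microscopic ADP binding rate (1/(uM s)); when None it is
    #: derived from K_ADP = k_minusADP / k_plusADP.
    k_plusADP: float | None = None
    #: ATP hydrolysis rate (1/s).
    k_hyd: float = 100.0
    #: Actin attachment pseudo-first-order rate at reference actin (1/s).
    k_attach: float = 1.0
    #: Phosphate release rate (1/s).
    k_Pi: float = 75.0
    #: Working-stroke substep displacements (nm).
    d1: float = 3.3
    d2: float = 2.0
    #: DRX->SRX and SRX->DRX interconversion rates (1/s); default 0: the
    #: relaxed ensemble is treated as a static mixture per trace.
    k_srx_in: float = 0.0
    k_srx_out: float = 0.0
    #: Single-turnover (basal) rates of the two relaxed populations (1/s).
    k_basal_drx: float = 0.02
    k_basal_srx: float = 0.002
    #: Stationary SRX fraction (0-1).
    p_srx: float = 0.5

    def __post_init__(self) -> None:
        for name in ("K1", "k_plus2", "K_ADP", "k_minusADP", "k_hyd",
                     "k_attach", "k_Pi", "k_srx_in", "k_srx_out",
                     "k_basal_drx", "k_basal_srx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_srx <= 1.0:
            raise ValueError("p_srx must lie in [0, 1]")
        if self.k_plusADP is None and self.K_ADP > 0:
            self.k_plusADP = self.k_minusADP / self.K_ADP

    # -- derived quantities -------------------------------------------------

    def cycle_states(self) -> list[tuple[str, float]]:
        """Serial cycle states and exit rates at reference conditions."""
        return [
            ("AM", self.k_plus2),
            ("M.ATP", self.k_hyd),
            ("M.ADP.Pi", self.k_attach),
            ("AM.ADP.Pi", self.k_Pi),
            ("AM.ADP", self.k_minusADP),
        ]

    @property
    def t_cycle(self) -> float:
        """Analytic mean cycle time (s) of the serial loop."""
        return float(sum(1.0 / r for _, r in self.cycle_states()))

    @property
    def kcat(self) -> float:
        """Steady-state turnover rate 1/t_cycle (1/s)."""
        return 1.0 / self.t_cycle

    @property
    def K1k2(self) -> float:
        """Second-order ATP binding rate constant K1*k+2 (1/(uM s))."""
        return self.K1 * self.k_plus2

    @property
    def d_total(self) -> float:
        """Total working-stroke displacement d1 + d2 (nm)."""
        return self.d1 + self.d2

    def kobs_atp(self, atp_uM) -> np.ndarray | float:
        """Observed ATP-induced dissociation rate at [ATP] (hyperbolic)."""
        atp = np.asarray(atp_uM, dtype=float)
        out = self.K1k2 * atp / (1.0 + self.K1 * atp)
        return float(out) if out.ndim == 0 else out

    def kobs_adp(self, adp_uM, k0: float) -> np.ndarray | float:
        """Observed rate under ADP competition at fixed ATP (k0 at [ADP]=0)."""
        adp = np.asarray(adp_uM, dtype=float)
        out = k0 / (1.0 + adp / self.K_ADP)
        return float(out) if out.ndim == 0 else out

    def with_kcat(self, kcat: float) -> "RateScheme":
        """Return a copy whose attachment rate is retuned to hit ``kcat``.

        All other serial rates are kept; the attachment pseudo-rate absorbs
        the difference, which is the step actin concentration controls.
        """
        others = sum(1.0 / r for name, r in self.cycle_states()
                     if name != "M.ADP.Pi")
        budget = 1.0 / kcat - others
        if budget <= 0:
            raise ValueError("requested kcat is faster than the other serial "
                             "steps allow")
        return replace(self, k_attach=1.0 / budget)


def human_myh7b() -> RateScheme:
    """Parameterization of the human MYH7b S1 construct."""
    return RateScheme(
        K1=1.0 / 79.8, k_plus2=520.7, K_ADP=120.7, k_minusADP=112.0,
        d1=3.3, d2=2.0, p_srx=0.829,
        k_basal_drx=0.02, k_basal_srx=0.002,
    ).with_kcat(0.80)


def python_myh7b() -> RateScheme:
    """Parameterization of the python MYH7b S1 construct."""
    return RateScheme(
        K1=1.0 / 157.3, k_plus2=181.2, K_ADP=17.0, k_minusADP=112.0,
        d1=2.8, d2=2.0, p_srx=0.464,
        k_basal_drx=0.015, k_basal_srx=0.0015,
    ).with_kcat(0.60)


def beta_myhc() -> RateScheme:
    """Parameterization of the human beta-cardiac myosin (MYH7) S1 construct."""
    return RateScheme(
        K1=1.0 / 365.7, k_plus2=991.0, K_ADP=6.1, k_minusADP=192.0,
        d1=3.3, d2=2.0, p_srx=0.144,
        k_basal_drx=0.03, k_basal_srx=0.003,
    ).with_kcat(1.57)


def simulate_cycle_dwells(scheme: RateScheme, n_cycles: int, seed: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Realize the serial chemomechanical cycle as a continuous-time chain.

    Parameters
    ----------
    scheme : RateScheme
        Cycle parameterization; every state's exit rate must be positive.
    n_cycles : int
        Number of complete traversals of the cycle (>= 1).
    seed : int
        Seed for the pseudo-random generator; fixed seed gives identical
        output.

    Returns
    -------
    states, dwells : ndarray
        ``states`` are integer indices into ``scheme.cycle_states()`` in
        visit order; ``dwells`` the exponential dwell time (s) of each visit.
        The mean of the summed per-cycle dwell converges to ``scheme.t_cycle``.
    """
    rates = np.array([r for _, r in scheme.cycle_states()], dtype=float)
    if np.any(~np.isfinite(rates)):
        raise ValueError("all scheme rates must be finite")
    if np.any(rates <= 0):
        bad = scheme.cycle_states()[int(np.argmin(rates))][0]
        raise ValueError(
            f"state {bad!r} has zero total exit rate: absorbing state")
    return simulate_serial_loop(rates, n_cycles, seed)


def simulate_serial_loop(rates, n_cycles: int, seed: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie realization of a serial loop of states with given exit rates.

    Each visit to state ``i`` draws an Exp(rates[i]) dwell; states are visited
    in order, ``n_cycles`` times around the loop.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0) or np.any(~np.isfinite(rates)):
        raise ValueError("all exit rates must be positive and finite: "
                         "a zero-exit-rate state is absorbing")
    rng = np.random.default_rng(seed)
    n_states = len(rates)
    dwells = rng.exponential(1.0 / rates, size=(n_cycles, n_states))
    states = np.tile(np.arange(n_states), n_cycles)
    return states, dwells.ravel()
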