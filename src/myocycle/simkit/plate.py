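"""Synthetic NADH-coupled ATPase plates.

The coupled-enzyme assay regenerates each hydrolyzed ATP at the expense of one
NADH, so A340 falls linearly at a rate proportional to the ATPase rate until
NADH depletes.  Wells are simulated per-[actin] with Michaelis-Menten rates on
top of the basal (actin-free) rate, alongside a 2-fold NADH dilution standard
series used downstream to calibrate absorbance to nanomoles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import SyntheticDataset

#: NADH molar absorptivity at 340 nm, AU per mM per cm.
NADH_EXT_MM_CM = 6.22


def make_atpase_plate(
    kcat: float,
    Km: float,
    basal: float,
    actin_concs,
    myosin_conc: float = 0.4,
    nadh_mM_start: float = 1.0,
    noise_sd: float = 0.001,
    seed: int = 0,
    duration_s: float = 3600.0,
    dt_s: float = 30.0,
    well_volume_uL: float = 20.0,
    path_cm: float = 0.25,
    n_standards: int = 8,
    nadh_mM_initial: float = 1.0,
) -> SyntheticDataset:
    """Simulate a plate of A340(t) well traces plus NADH standard wells.

    Parameters
    ----------
    kcat, Km : float
        Maximal actin-activated ATPase rate (1/s per head) and apparent actin
        affinity (uM).
    basal : float
        Actin-free ATPase rate (1/s per head), present in every well.
    actin_concs : sequence of float
        Actin concentrations (uM); one assay well per concentration, plus one
        basal (actin-free) well.
    myosin_conc : float
        Myosin head concentration in the well (uM).
    nadh_mM_start : float
        Top concentration of the 2-fold NADH standard dilution series (mM).
    noise_sd : float
        Gaussian absorbance noise per read (AU).
    nadh_mM_initial : float
        NADH concentration in assay wells at time zero (mM).

    Returns
    -------
    SyntheticDataset
        ``observables`` is a dict with a wells DataFrame (``time_s`` plus one
        column per well), a ``well_map`` assigning wells to actin
        concentrations / 'basal', and a standards DataFrame
        (``conc_mM``, ``absorbance``).  ``ground_truth`` stores the true
        per-well rates and the generator parameters.
    """
    actin_concs = np.asarray(list(actin_concs), dtype=float)
    if np.any(actin_concs < 0) or Km < 0 or myosin_conc < 0 or basal < 0:
        raise ValueError("concentrations and rates must be non-negative")
    rng = np.random.default_rng(seed)

    time = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    abs_per_mM = NADH_EXT_MM_CM * path_cm            # AU per mM NADH
    nmol_per_au = well_volume_uL / abs_per_mM        # nmol NADH per AU
    nmol_myosin = myosin_conc * well_volume_uL / 1000.0
    a0 = nadh_mM_initial * abs_per_mM

    rates = {"basal": basal}
    for a in actin_concs:
        rates[f"actin_{a:g}"] = basal + kcat * a / (Km + a)

    wells = {"time_s": time}
    truth_rates = {}
    for name, rate in rates.items():
        slope_au = rate * nmol_myosin / nmol_per_au  # AU/s consumed
        clean = np.maximum(a0 - slope_au * time, 0.02 * a0)  # NADH depletion
        wells[name] = clean + rng.normal(0.0, noise_sd, size=time.shape)
        truth_rates[name] = rate

    std_concs = nadh_mM_start * 0.5 ** np.arange(n_standards)
    std_abs = std_concs * abs_per_mM + rng.normal(0.0, noise_sd,
                                                  size=std_concs.shape)
    standards = pd.DataFrame({"conc_mM": std_concs, "absorbance": std_abs})

    well_map = {name: ("basal" if name == "basal" else float(name.split("_")[1]))
                for name in rates}
    return SyntheticDataset(
        observables={
            "wells": pd.DataFrame(wells),
            "well_map": well_map,
            "standards": standards,
            "myosin_conc_uM": myosin_conc,
            "well_volume_uL": well_volume_uL,
        },
        ground_truth={
            "kcat": kcat, "Km": Km, "basal": basal,
            "rates_per_well": truth_rates,
            "conversion_nmol_per_au": nmol_per_au,
        },
        seed=seed,
        noise_model={"kind": "gaussian", "sd_au": noise_sd},
    )
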