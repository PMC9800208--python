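"""Cross-assay derived metrics and consistency diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd


def predict_unloaded_velocity(d_total: float, t_on: float) -> float:
    """Predict the unloaded sliding velocity v = d_total / t_on in um/s.

    At saturating ATP the motility speed is set by the working-stroke
    displacement ``d_total`` (nm) and the actin-attached time ``t_on`` (s);
    this is the cross-assay consistency check between the trap and motility
    modules.
    """
    if d_total <= 0 or t_on <= 0:
        raise ValueError("d_total and t_on must be positive")
    return d_total / t_on / 1000.0  # nm/s -> um/s


def cycle_metric_table(params: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derived cycle metrics from (kcat, Km) pairs per construct.

    ``params`` maps construct name -> (kcat in 1/s, Km in uM).  Returns the
    per-construct table (t_cycle = 1/kcat, efficiency = kcat/Km) and the
    pairwise percent-difference table (larger value as reference).
    """
    from .atpase import MMFit, derive_cycle_metrics

    fits = {}
    for name, (kcat, Km) in params.items():
        if kcat <= 0 or Km <= 0:
            raise ValueError(f"construct {name!r} needs positive kcat and Km")
        fits[name] = MMFit(kcat=kcat, Km=Km, kcat_ci=(np.nan, np.nan),
                           Km_ci=(np.nan, np.nan), t_cycle=1.0 / kcat,
                           efficiency=kcat / Km, n_points=0)
    return derive_cycle_metrics(fits)


def pct_decrease(reference: float, other: float) -> float:
    """Percent decrease of ``other`` relative to ``reference``."""
    return 100.0 * (reference - other) / reference
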