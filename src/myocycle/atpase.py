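"""Steady-state actin-activated ATPase analysis.

The NADH-coupled assay links each ATP turnover to oxidation of one NADH, so
the ATPase rate is read out as the initial linear decrease of A340.  The
pipeline is: calibrate absorbance to nanomoles against the on-plate NADH
standard curve, extract the linear-range slope of each well, convert to a
per-head rate (1/s), subtract the basal (actin-free) rate, and fit the
Michaelis-Menten hyperbola

    rate([actin]) = kcat [actin] / (Km + [actin])

for the maximal rate kcat and apparent actin affinity Km.  Derived metrics:
cycle time t_cycle = 1/kcat and catalytic efficiency kcat/Km.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import Trace


@dataclass
class NadhStandard:
    """NADH standard-curve calibration: nanomoles per absorbance unit."""

    concentrations_mM: np.ndarray
    absorbances: np.ndarray
    conversion_factor: float   #: nmol NADH per AU (regression slope)
    conversion_se: float       #: standard error of the slope
    intercept: float
    r_squared: float
    well_volume_uL: float


@dataclass
class ActivityPoint:
    """A single (actin concentration, per-head rate) measurement."""

    actin_conc: float          #: uM
    rate: float                #: 1/s per myosin head
    basal_subtracted: bool = False
    replicate_id: str | None = None


@dataclass
class RateExtraction:
    """Per-well linear-range rate with its selection diagnostics."""

    rate: float                #: 1/s per head (positive for NADH consumption)
    rate_se: float             #: 1/s, from the window slope standard error
    window: tuple              #: (start index, stop index) of the linear range
    slope_au_per_s: float
    r_squared: float
    rejected: bool = False
    reason: str | None = None


@dataclass
class MMFit:
    """Michaelis-Menten fit with confidence intervals and derived metrics."""

    kcat: float
    Km: float
    kcat_ci: tuple
    Km_ci: tuple
    t_cycle: float
    efficiency: float          #: kcat/Km, 1/(s uM)
    n_points: int
    rejected: bool = False
    reason: str | None = None


def fit_nadh_standard(concentrations_mM, absorbances,
                      well_volume_uL: float = 20.0) -> NadhStandard:
    """Fit the NADH standard curve: nmol NADH versus absorbance.

    ``conversion_factor`` is the ordinary-least-squares slope of nanomoles of
    NADH in the well against absorbance, so multiplying an absorbance slope
    by it yields nmol NADH (= nmol ATP) per unit time.
    """
    conc = np.asarray(concentrations_mM, dtype=float)
    au = np.asarray(absorbances, dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("standard curve needs >= 3 distinct concentrations")
    if np.ptp(au) == 0:
        raise ValueError("all standard absorbances equal: rank-deficient")
    nmol = conc * well_volume_uL  # mM * uL = nmol
    res = stats.linregress(au, nmol)
    return NadhStandard(
        concentrations_mM=conc, absorbances=au,
        conversion_factor=float(res.slope), conversion_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), well_volume_uL=well_volume_uL,
    )


def _window_regression(time, absorbance):
    """Prefix-sum O(1) slope and R^2 over arbitrary [i, j) windows."""
    t = np.asarray(time, float)
    y = np.asarray(absorbance, float)
    one = np.concatenate([[0.0], np.cumsum(np.ones_like(t))])
    st = np.concatenate([[0.0], np.cumsum(t)])
    sy = np.concatenate([[0.0], np.cumsum(y)])
    stt = np.concatenate([[0.0], np.cumsum(t * t)])
    sty = np.concatenate([[0.0], np.cumsum(t * y)])
    syy = np.concatenate([[0.0], np.cumsum(y * y)])

    def stats_ij(i, j):
        n = one[j] - one[i]
        tm, ym = (st[j] - st[i]) / n, (sy[j] - sy[i]) / n
        sxx = (stt[j] - stt[i]) - n * tm * tm
        sxy = (sty[j] - sty[i]) - n * tm * ym
        svv = (syy[j] - syy[i]) - n * ym * ym
        slope = sxy / sxx if sxx > 0 else 0.0
        r2 = (sxy * sxy) / (sxx * svv) if sxx > 0 and svv > 0 else 1.0
        resid_var = max(svv - slope * sxy, 0.0) / max(n - 2, 1)
        return slope, r2, resid_var

    return stats_ij


def extract_rate(trace: Trace, conversion: NadhStandard, myosin_conc: float,
                 well_volume_uL: float | None = None,
                 min_window: int = 10, r2_min: float = 0.995,
                 local_tol: float = 0.05) -> RateExtraction:
    """Extract the per-head ATPase rate from a well's A340(t) trace.

    The linear range is the longest contiguous window of at least
    ``min_window`` samples whose rolling 5-point local slopes stay within
    ``max(local_tol * |window slope|, 3 x local-slope SE)`` of the window's
    global slope and which is linear: either the linear-fit R^2 is at least
    ``r2_min`` or the fit residual SD is consistent with the trace noise
    (within 20%), since R^2 alone penalizes noise-limited low-rate wells
    rather than curvature.  Ties break toward the earliest window (initial
    velocity precedes NADH depletion).  The negative absorbance slope maps
    to a positive ATPase rate.
    """
    if len(trace) < min_window:
        raise ValueError(f"trace must have >= {min_window} samples")
    if well_volume_uL is None:
        well_volume_uL = conversion.well_volume_uL
    t, y = trace.time, trace.signal
    n = len(t)

    # rolling 5-point local slopes and their common standard error; the
    # noise scale comes from a robust MAD of first differences so substrate
    # depletion kinks cannot inflate it
    k = 5
    local = np.full(n, np.nan)
    d = np.diff(y)
    noise_sd = float(1.4826 * np.median(np.abs(d - np.median(d)))
                     / np.sqrt(2.0))
    dtm = float(np.median(np.diff(t)))
    sxx5 = dtm * dtm * 10.0  # sum (t - tbar)^2 for 5 evenly spaced samples
    local_se = noise_sd / np.sqrt(sxx5)
    if np.allclose(np.diff(t), dtm, rtol=1e-6):
        weights = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * dtm / sxx5
        local[k // 2: n - (k // 2)] = np.convolve(y, weights, mode="valid")
    else:
        for i in range(n - k + 1):
            local[i + k // 2] = np.polyfit(t[i:i + k], y[i:i + k], 1)[0]

    win = _window_regression(t, y)
    best = None
    for length in range(n, min_window - 1, -1):
        for start in range(0, n - length + 1):
            stop = start + length
            slope, r2, resid_var = win(start, stop)
            if r2 < r2_min and resid_var > (1.2 * noise_sd) ** 2:
                continue
            tol = max(local_tol * abs(slope), 3.0 * local_se)
            loc = local[start + k // 2: stop - k // 2]
            loc = loc[~np.isnan(loc)]
            if loc.size and np.any(np.abs(loc - slope) > tol):
                continue
            best = (start, stop, slope, r2, resid_var)
            break
        if best is not None:
            break
    if best is None:
        return RateExtraction(rate=np.nan, rate_se=np.nan, window=(0, 0),
                              slope_au_per_s=np.nan, r_squared=np.nan,
                              rejected=True,
                              reason="no window satisfies the linearity "
                                     "criterion")
    start, stop, slope, r2, resid_var = best
    ts = t[start:stop]
    slope_se = np.sqrt(resid_var / np.sum((ts - ts.mean()) ** 2))
    nmol_myosin = myosin_conc * well_volume_uL / 1000.0
    scale = conversion.conversion_factor / nmol_myosin
    return RateExtraction(rate=-slope * scale, rate_se=float(slope_se * scale),
                          window=(start, stop), slope_au_per_s=float(slope),
                          r_squared=float(r2))


def subtract_basal(points: list[ActivityPoint], basal_rate: float
                   ) -> list[ActivityPoint]:
    """Subtract the actin-free basal rate from every activated rate.

    Applied before technical-replicate averaging.  Rates may go slightly
    negative at low actin under noise; they are never clipped.
    """
    out = []
    for p in points:
        if p.basal_subtracted:
            raise ValueError("basal already subtracted for this point "
                             "(double subtraction)")
        out.append(ActivityPoint(actin_conc=p.actin_conc,
                                 rate=p.rate - basal_rate,
                                 basal_subtracted=True,
                                 replicate_id=p.replicate_id))
    return out


def _mm(a, kcat, Km):
    return kcat * a / (Km + a)


def fit_michaelis_menten(points: list[ActivityPoint],
                         ambiguity_ci_frac: float = 1.0,
                         km_bound_factor: float = 10.0) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit with 95% CIs.

    Fits are flagged ``rejected`` (ambiguous) when the relative CI half-width
    on kcat or Km exceeds ``ambiguity_ci_frac``, or when Km exceeds
    ``km_bound_factor`` times the largest tested actin concentration.
    """
    a = np.array([p.actin_conc for p in points], dtype=float)
    r = np.array([p.rate for p in points], dtype=float)
    if len(np.unique(a[a > 0])) < 4:
        raise ValueError("need >= 4 distinct actin concentrations")
    p0 = (max(r.max(), 1e-6), np.median(a[a > 0]))
    popt, pcov = optimize.curve_fit(_mm, a, r, p0=p0,
                                    bounds=([0, 0], [np.inf, np.inf]),
                                    maxfev=10_000)
    kcat, Km = popt
    dof = max(len(a) - 2, 1)
    tval = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    kcat_ci = (kcat - tval * se[0], kcat + tval * se[0])
    Km_ci = (Km - tval * se[1], Km + tval * se[1])

    rejected, reason = False, None
    if kcat <= 0 or not np.isfinite(se[0]) or not np.isfinite(se[1]):
        rejected, reason = True, "non-identifiable fit"
    elif tval * se[0] > ambiguity_ci_frac * kcat or \
            tval * se[1] > ambiguity_ci_frac * Km:
        rejected, reason = True, "relative CI half-width exceeds 100%"
    elif Km > km_bound_factor * a.max():
        rejected, reason = True, "Km exceeds the ambiguity bound"

    return MMFit(kcat=float(kcat), Km=float(Km),
                 kcat_ci=tuple(map(float, kcat_ci)),
                 Km_ci=tuple(map(float, Km_ci)),
                 t_cycle=float(1.0 / kcat) if kcat > 0 else np.inf,
                 efficiency=float(kcat / Km) if Km > 0 else np.nan,
                 n_points=len(a), rejected=rejected, reason=reason)


def derive_cycle_metrics(fits: dict[str, MMFit]) -> pd.DataFrame:
    """Tabulate t_cycle, efficiency, and pairwise percent differences.

    The percent difference between constructs uses the larger value as the
    reference: 100 * (x_A - x_B) / x_A with x_A >= x_B.
    """
    rows = []
    for name, fit in fits.items():
        if fit.kcat <= 0:
            raise ValueError(f"construct {name!r} has non-positive kcat")
        rows.append({"construct": name, "kcat": fit.kcat, "Km": fit.Km,
                     "t_cycle": 1.0 / fit.kcat,
                     "efficiency": fit.kcat / fit.Km})
    table = pd.DataFrame(rows).set_index("construct")

    pairs = []
    for a, b in itertools.combinations(fits, 2):
        for metric in ("kcat", "Km"):
            xa, xb = getattr(fits[a], metric), getattr(fits[b], metric)
            ref, other = (a, b) if xa >= xb else (b, a)
            hi, lo = max(xa, xb), min(xa, xb)
            pairs.append({"metric": metric, "reference": ref, "other": other,
                          "pct_decrease": 100.0 * (hi - lo) / hi,
                          "ratio": hi / lo if lo > 0 else np.inf})
    return table, pd.DataFrame(pairs)


def analyze_plate(wells: pd.DataFrame, well_map: dict, standards: pd.DataFrame,
                  myosin_conc: float, well_volume_uL: float = 20.0
                  ) -> tuple[MMFit, list[ActivityPoint], dict]:
    """Full plate pipeline: standard curve, rates, basal subtraction, MM fit.

    ``wells`` must hold a ``time_s`` column plus one column per well;
    ``well_map`` assigns each well column to an actin concentration (uM) or
    the string 'basal'.

    The kcat confidence interval is widened by the two error sources shared
    across wells, which the per-point fit covariance cannot see: the NADH
    conversion-factor uncertainty (multiplicative) and the basal-rate
    uncertainty (additive).
    """
    standard = fit_nadh_standard(standards["conc_mM"], standards["absorbance"],
                                 well_volume_uL)
    time = wells["time_s"].to_numpy()
    basal_rates, basal_ses, points, log = [], [], [], {}
    for well, assignment in well_map.items():
        ext = extract_rate(Trace(time, wells[well].to_numpy()), standard,
                           myosin_conc, well_volume_uL)
        log[well] = ext
        if ext.rejected:
            continue
        if assignment == "basal":
            basal_rates.append(ext.rate)
            basal_ses.append(ext.rate_se)
        else:
            points.append(ActivityPoint(actin_conc=float(assignment),
                                        rate=ext.rate, replicate_id=well))
    if not basal_rates:
        raise ValueError("no usable basal well on the plate")
    points = subtract_basal(points, float(np.mean(basal_rates)))
    fit = fit_michaelis_menten(points)

    # widen the kcat CI by the shared calibration and basal uncertainties
    conv_rel = standard.conversion_se / standard.conversion_factor
    se_basal = float(np.sqrt(np.mean(np.square(basal_ses)))
                     / len(basal_rates))
    hw = (fit.kcat_ci[1] - fit.kcat_ci[0]) / 2.0
    tval = stats.t.ppf(0.975, max(fit.n_points - 2, 1))
    hw = np.sqrt(hw ** 2 + (tval * fit.kcat * conv_rel) ** 2
                 + (tval * se_basal) ** 2)
    fit.kcat_ci = (fit.kcat - hw, fit.kcat + hw)
    return fit, points, log
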