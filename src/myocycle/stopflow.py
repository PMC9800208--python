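"""Stopped-flow transient kinetics of ATP-induced actomyosin dissociation.

Mixing ATP with pyrene-actin.S1 relieves the pyrene quench as myosin
dissociates, giving a single-exponential transient whose observed rate k_obs
depends hyperbolically on [ATP]:

    k_obs = K1 k+2 [ATP] / (1 + K1 [ATP])

where K1 k+2 is the second-order ATP-binding rate constant (the low-ATP
linear slope), k+2 the maximal dissociation rate, and 1/K1 the ATP affinity.
With ADP competing for the nucleotide pocket at fixed ATP,

    k_obs = k0 / (1 + [ADP] / K_ADP)

where k0 is the zero-ADP observed rate and K_ADP the ADP affinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import Trace


@dataclass
class KobsPoint:
    """Observed single-exponential rate at one nucleotide concentration."""

    nucleotide_conc: float     #: uM
    k_obs: float               #: 1/s
    k_obs_se: float
    amplitude: float
    trace_id: str | None = None
    truncated: bool = False    #: k_obs * t_max < 3: span too short


@dataclass
class AtpDependenceFit:
    """ATP dependence of k_obs: linear-regime and hyperbolic parameters."""

    K1k2: float                #: 1/(uM s), from the low-ATP linear branch
    K1k2_se: float
    k_plus2: float             #: 1/s, hyperbola saturation
    k_plus2_ci: tuple
    invK1: float               #: uM, ATP affinity 1/K1
    invK1_ci: tuple
    n_linear: int              #: points in the linear regime
    K1k2_hyper: float          #: 1/(uM s), from the hyperbolic branch
    consistent: bool           #: K1k2 vs k_plus2/invK1 within 2x combined SE
    unidentifiable: bool = False


@dataclass
class AdpCompetitionFit:
    """ADP competition fit: K_ADP with CI and the zero-ADP rate."""

    K_ADP: float               #: uM
    K_ADP_ci: tuple
    k0: float                  #: 1/s
    k0_fitted: bool
    fixed_atp: float | None = None
    model_violation: bool = False  #: k_obs increased with [ADP]


def fit_transient_exponential(trace: Trace) -> KobsPoint:
    """Fit a single-exponential transient for its observed rate constant.

    Rising transients (pyrene dequench on dissociation) fit
    ``y = c + A (1 - exp(-k t))``; decaying ones ``y = c + A exp(-k t)``,
    chosen by the ``direction`` metadata or the sign of the overall trend.
    Initialization comes from log-linearized data.  Transients whose span is
    shorter than 3/k_obs are flagged ``truncated``.
    """
    t, y = trace.time, trace.signal
    direction = trace.meta.get("direction")
    if direction is None:
        direction = "rise" if y[-1] >= y[0] else "decay"

    # log-linearized initialization: log|y_inf - y| is linear with slope -k
    tail = float(np.mean(y[-max(len(y) // 20, 3):]))
    resid = np.abs(tail - y) + 1e-12
    use = resid > 0.05 * np.max(resid)
    k0 = max(-stats.linregress(t[use], np.log(resid[use])).slope, 1e-6)
    amp0 = float(y[-1] - y[0])

    if direction == "rise":
        model = lambda tt, A, k, c: c + A * (1.0 - np.exp(-k * tt))
        p0 = (abs(amp0), k0, float(y[0]))
    else:
        model = lambda tt, A, k, c: c + A * np.exp(-k * tt)
        p0 = (abs(amp0), k0, float(y[-1]))
    popt, pcov = optimize.curve_fit(model, t, y, p0=p0,
                                    bounds=([0, 0, -np.inf],
                                            [np.inf, np.inf, np.inf]),
                                    maxfev=10_000)
    A, k, _ = popt
    se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return KobsPoint(
        nucleotide_conc=float(trace.meta.get("conc_uM", np.nan)),
        k_obs=float(k), k_obs_se=se, amplitude=float(A),
        trace_id=trace.meta.get("trace_id"),
        truncated=bool(k * t[-1] < 3.0),
    )


def _hyperbola(atp, K1k2, K1):
    return K1k2 * atp / (1.0 + K1 * atp)


def fit_atp_dependence(points: list[KobsPoint],
                       linear_frac: float = 0.2) -> AtpDependenceFit:
    """Fit the ATP dependence of k_obs: linear branch and full hyperbola.

    A pilot hyperbolic fit estimates 1/K1; points with
    ``[ATP] <= linear_frac / K1`` (at least 3, falling back to the lowest
    three) form the linear regime, fitted through the origin for K1k2.  The
    full hyperbola yields k_plus2 and 1/K1 with 95% CIs, plus the internal
    consistency check K1k2 ~ k_plus2/invK1.
    """
    if len(points) < 5:
        raise ValueError("need >= 5 ATP concentrations")
    atp = np.array([p.nucleotide_conc for p in points], float)
    k = np.array([p.k_obs for p in points], float)
    se = np.array([p.k_obs_se for p in points], float)
    w = np.where(np.isfinite(se) & (se > 0), se, np.nan)
    sigma = w if np.all(np.isfinite(w)) else None

    p0 = (k[np.argsort(atp)][:2].mean() / atp[np.argsort(atp)][:2].mean(),
          1.0 / np.median(atp))
    popt, pcov = optimize.curve_fit(_hyperbola, atp, k, p0=p0, sigma=sigma,
                                    bounds=([0, 0], [np.inf, np.inf]),
                                    maxfev=20_000)
    K1k2_h, K1_h = popt

    unidentifiable = False
    if K1_h * atp.max() < 0.5:
        # all points effectively in the linear regime: saturation unseen
        unidentifiable = True

    low = atp <= linear_frac / K1_h if K1_h > 0 else np.zeros_like(atp, bool)
    if low.sum() < 3:
        low = np.argsort(atp) < 3
        low = np.isin(np.arange(len(atp)), np.where(low)[0])
    # regression through the origin on curvature-corrected points: at low ATP
    # k_obs = K1k2 [ATP] / (1 + K1 [ATP]), so multiplying each k_obs by
    # (1 + K1_pilot [ATP]) removes the first-order hyperbola bias (< 20% in
    # the regime) while keeping the slope estimate driven by the low points.
    kc = k[low] * (1.0 + K1_h * atp[low])
    wts = 1.0 / w[low] ** 2 if sigma is not None else np.ones(low.sum())
    K1k2 = float(np.sum(wts * kc * atp[low]) /
                 np.sum(wts * atp[low] ** 2))
    resid = kc - K1k2 * atp[low]
    dof = max(low.sum() - 1, 1)
    K1k2_se = float(np.sqrt(np.sum(wts * resid ** 2) / dof /
                            np.sum(wts * atp[low] ** 2)))

    dof_h = max(len(atp) - 2, 1)
    tval = stats.t.ppf(0.975, dof_h)
    pse = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    k_plus2 = float(K1k2_h / K1_h) if K1_h > 0 else np.inf
    invK1 = float(1.0 / K1_h) if K1_h > 0 else np.inf
    # delta-method SEs for the derived parameters
    var = pcov
    g_kp2 = np.array([1.0 / K1_h, -K1k2_h / K1_h ** 2])
    se_kp2 = float(np.sqrt(max(g_kp2 @ var @ g_kp2, 0.0)))
    se_inv = float(pse[1] / K1_h ** 2)

    ratio = k_plus2 / invK1 if np.isfinite(k_plus2) else np.nan
    comb_se = np.sqrt(K1k2_se ** 2 +
                      (ratio * np.hypot(se_kp2 / k_plus2, se_inv / invK1)) ** 2
                      ) if np.isfinite(ratio) and k_plus2 > 0 else np.inf
    consistent = bool(abs(K1k2 - ratio) <= 2.0 * comb_se) \
        if np.isfinite(ratio) else False

    return AtpDependenceFit(
        K1k2=K1k2, K1k2_se=K1k2_se,
        k_plus2=k_plus2, k_plus2_ci=(k_plus2 - tval * se_kp2,
                                     k_plus2 + tval * se_kp2),
        invK1=invK1, invK1_ci=(invK1 - tval * se_inv, invK1 + tval * se_inv),
        n_linear=int(low.sum()), K1k2_hyper=float(K1k2_h),
        consistent=consistent, unidentifiable=unidentifiable,
    )


def fit_adp_competition(points: list[KobsPoint], k0: float | None = None,
                        fixed_atp: float | None = None) -> AdpCompetitionFit:
    """Fit the ADP-competition curve k_obs = k0 / (1 + [ADP]/K_ADP).

    ``k0`` is fitted unless supplied; the point set must include [ADP] = 0
    when ``k0`` is not given.  A positive trend of k_obs with [ADP] sets the
    ``model_violation`` flag.
    """
    if len(points) < 4:
        raise ValueError("need >= 4 ADP concentrations")
    adp = np.array([p.nucleotide_conc for p in points], float)
    k = np.array([p.k_obs for p in points], float)
    se = np.array([p.k_obs_se for p in points], float)
    sigma = se if np.all(np.isfinite(se) & (se > 0)) else None
    if k0 is None and not np.any(adp == 0):
        raise ValueError("need a zero-ADP point or a supplied k0")

    violation = bool(stats.linregress(adp, k).slope > 0)

    if k0 is None:
        model = lambda a, kk0, kd: kk0 / (1.0 + a / kd)
        p0 = (k[np.argmin(adp)], np.median(adp[adp > 0]))
        popt, pcov = optimize.curve_fit(model, adp, k, p0=p0, sigma=sigma,
                                        bounds=([0, 1e-12],
                                                [np.inf, np.inf]),
                                        maxfev=20_000)
        k0_fit, K_ADP = popt
        se_kd = float(np.sqrt(max(pcov[1, 1], 0.0)))
        dof = max(len(adp) - 2, 1)
        fitted = True
    else:
        model = lambda a, kd: k0 / (1.0 + a / kd)
        popt, pcov = optimize.curve_fit(model, adp, k,
                                        p0=(np.median(adp[adp > 0]),),
                                        sigma=sigma, bounds=(1e-12, np.inf),
                                        maxfev=20_000)
        K_ADP = popt[0]
        k0_fit = k0
        se_kd = float(np.sqrt(max(pcov[0, 0], 0.0)))
        dof = max(len(adp) - 1, 1)
        fitted = False
    tval = stats.t.ppf(0.975, dof)
    return AdpCompetitionFit(
        K_ADP=float(K_ADP), K_ADP_ci=(K_ADP - tval * se_kd,
                                      K_ADP + tval * se_kd),
        k0=float(k0_fit), k0_fitted=fitted, fixed_atp=fixed_atp,
        model_violation=violation,
    )
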