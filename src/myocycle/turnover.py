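"""Single mant-ATP turnover decomposition into SRX and DRX phases.

After a chase with excess unlabeled ATP, the mant-ATP fluorescence decays as
each head releases its labeled nucleotide once.  Two detached-myosin
populations produce a biexponential decay: the fast phase reports the
disordered-relaxed state (DRX, basal turnover) and the slow phase the
super-relaxed state (SRX, ~10-fold slower here).  Decays are normalized to
the pre-chase plateau and fit under the constraints Y0 = 1 and plateau = 0,
so the two fractional amplitudes sum to one and the slow amplitude is the SRX
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import Trace


@dataclass
class TurnoverFit:
    """Constrained biexponential fit of a single-turnover decay."""

    A_slow: float              #: fractional SRX amplitude
    A_fast: float              #: fractional DRX amplitude (= 1 - A_slow)
    k_slow: float              #: 1/s
    k_fast: float              #: 1/s (> k_slow by construction)
    chase_time: float          #: s, chase location in the raw trace
    constraint: str = "Y0=1, plateau=0"
    rejected: bool = False
    reason: str | None = None

    @property
    def pct_SRX(self) -> float:
        return 100.0 * self.A_slow

    @property
    def pct_DRX(self) -> float:
        return 100.0 * self.A_fast


def locate_chase(trace: Trace, window: int = 10) -> float:
    """Locate the chase injection as the strongest sustained signal drop.

    The chase is the kink between the flat pre-chase plateau and the
    decaying tail: the point maximizing the drop of the local slope, where
    slopes are fitted over ``window`` samples on each side.  Windowed slopes
    make the detection robust to sample-level noise when the post-chase
    decay is gentle.
    """
    y = trace.signal
    n = len(y)
    if n < 2 * window + 1:
        raise ValueError("trace too short to locate the chase")
    offsets = np.arange(window) - (window - 1) / 2.0
    kernel = offsets / np.sum(offsets ** 2)
    # slope of the window starting at each index (per-sample units)
    slopes = np.convolve(y, kernel[::-1], mode="valid")
    i = np.arange(window, n - window + 1)
    change = slopes[i] - slopes[i - window]
    return float(trace.time[int(i[np.argmin(change)])])


def _biexp(t, A, k_slow, dk):
    k_fast = k_slow + dk
    return A * np.exp(-k_slow * t) + (1.0 - A) * np.exp(-k_fast * t)


def fit_single_turnover(trace: Trace, chase_time: float | None = None,
                        collapse_ratio: float = 3.0,
                        n_norm: int = 5) -> TurnoverFit:
    """Fit the constrained biexponential to a single-turnover trace.

    The signal is normalized to the mean of the ``n_norm`` samples preceding
    the chase, time is re-zeroed at the chase, and
    ``A exp(-k_slow t) + (1-A) exp(-k_fast t)`` is fitted with A in [0, 1]
    and k_slow < k_fast enforced by parameterizing k_fast = k_slow + dk,
    dk >= 0.  SRX is the slower phase.  Fits whose rates fall within
    ``collapse_ratio`` of each other are flagged rejected (phase collapse).

    ``chase_time`` falls back to the trace metadata, then to detection as the
    largest single-sample drop.
    """
    if chase_time is None:
        chase_time = trace.meta.get("chase_time_s")
    if chase_time is None:
        chase_time = locate_chase(trace)
    t, y = trace.time, trace.signal
    if not t[0] <= chase_time <= t[-1]:
        raise ValueError("chase_time outside the trace span")
    post = t >= chase_time
    if t[post][-1] - chase_time < 200.0:
        raise ValueError("need >= 200 s of post-chase data")

    pre = np.where(t < chase_time)[0]
    if len(pre) == 0:
        raise ValueError("no pre-chase samples to normalize against")
    norm = float(np.mean(y[pre[-n_norm:]]))
    tt = t[post] - chase_time
    yy = y[post] / norm

    # log-linearized tail gives the slow-rate initial guess
    tail = yy[-len(yy) // 4:]
    ttail = tt[-len(yy) // 4:]
    good = tail > 1e-3
    if good.sum() >= 3:
        k_slow0 = max(-np.polyfit(ttail[good], np.log(tail[good]), 1)[0],
                      1e-5)
    else:
        k_slow0 = 1.0 / tt[-1]
    p0 = (0.5, k_slow0, 9.0 * k_slow0)
    popt, _ = optimize.curve_fit(
        _biexp, tt, yy, p0=p0,
        bounds=([0.0, 1e-7, 0.0], [1.0, np.inf, np.inf]), maxfev=20_000)
    A, k_slow, dk = popt
    k_fast = k_slow + dk
    ssr_bi = float(np.sum((_biexp(tt, *popt) - yy) ** 2))

    # single-exponential comparison: a genuinely one-phase decay degenerates
    # gracefully to A_fast -> 0 rather than a phase-collapse rejection
    (k1,), _ = optimize.curve_fit(lambda t, k: np.exp(-k * t), tt, yy,
                                  p0=(k_slow0,), bounds=(1e-7, np.inf),
                                  maxfev=10_000)
    ssr_single = float(np.sum((np.exp(-k1 * tt) - yy) ** 2))

    rejected, reason = False, None
    if A > 0.99 or A < 0.01 or ssr_single <= ssr_bi * (1.0 + 1e-3):
        # second phase carries no information; report a pure slow phase
        return TurnoverFit(A_slow=1.0, A_fast=0.0, k_slow=float(k1),
                           k_fast=np.inf, chase_time=float(chase_time))
    if k_fast < collapse_ratio * k_slow:
        rejected, reason = True, "phase collapse: rates within 3x"
    return TurnoverFit(A_slow=float(A), A_fast=float(1.0 - A),
                       k_slow=float(k_slow), k_fast=float(k_fast),
                       chase_time=float(chase_time),
                       rejected=rejected, reason=reason)


def make_reference_curves(fit: TurnoverFit, time: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Single-exponential bounding curves at the fitted slow and fast rates.

    Both start at 1 at t = 0; any biexponential mixture with 0 < A_slow < 1
    lies strictly between them for t > 0 (the slow curve above, the fast
    curve below), so they bracket the data curve for QC plotting.
    """
    time = np.asarray(time, dtype=float)
    with np.errstate(invalid="ignore"):
        slow = np.where(time > 0, np.exp(-fit.k_slow * time), 1.0)
        fast = np.where(time > 0, np.exp(-fit.k_fast * time), 1.0)
    return slow, fast
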