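# Methods

This note documents the models behind each analysis module, the synthetic
data they are validated against, the numerical choices that were genuinely
open, and the limits of what the tests demonstrate.

## The chemomechanical cycle and its observables

A myosin head cycles through ATP binding and actomyosin dissociation,
hydrolysis, actin attachment, phosphate release (coupled to the working
stroke), and ADP release. The package represents this as a serial loop of
five states with exit rates (k₊₂, k_hyd, k_attach, k_Pi, k₋ADP), so the
analytic mean cycle time is t_cycle = Σ 1/rateᵢ and the steady-state
turnover rate is k_cat = 1/t_cycle. The built-in parameterizations
(`simkit.beta_myhc`, `human_myh7b`, `python_myh7b`) carry the fitted
constants for each construct; the actin-attachment pseudo-rate is retuned
so the serial loop reproduces each construct's k_cat, since attachment is
the actin-concentration-dependent step. ADP-release rates are set from the
measured sliding speeds via v = d/t_on with t_on = 1/k₋ADP; the hydrolysis
and phosphate-release rates are generic fast values (100 and 75 s⁻¹) that
do not limit the cycle.

K_ADP is stored directly in µM as the ADP concentration at which
ATP-induced dissociation is half-inhibited — the operationally unambiguous
definition — with the microscopic rates as optional derived fields
(K_ADP = k₋ADP/k₊ADP). The ADP-competition model is implemented with a
rate prefactor, k_obs = k₀/(1+[ADP]/K_ADP), as dimensional consistency
requires; k₀ is the zero-ADP observed rate at the fixed ATP concentration
of the experiment.

## Synthetic data: what it emulates, what it does not

Every generator draws from known ground truth with seeded noise, and every
dataset carries its truth in a sidecar that analysis code never reads.

* **ATPase plates** — A340 falls linearly at a rate proportional to the
  per-head ATPase rate (one NADH per ATP), with Gaussian read noise
  (default SD 0.001 AU, a good plate reader) and saturating NADH depletion
  at late times. A 2-fold NADH dilution series (1 → 0.0078 mM) provides
  the calibration wells. Conversion assumes ε₃₄₀ = 6.22 mM⁻¹cm⁻¹ and a
  0.25 cm effective path for a 20 µL 384-well volume. Not emulated:
  coupled-enzyme lag, evaporation, well-to-well drift.
* **Stopped-flow transients** — rising exponentials
  amplitude·(1−e^(−k_obs·t)) spanning six lifetimes, Gaussian noise
  (default SD 2% of amplitude). Not emulated: mixing dead time, photobleach
  drift, multiphasic transients.
* **Single-turnover decays** — 1 Hz sampling, a 60 s pre-chase plateau at
  1.0 and a 940 s biexponential decay (defaults: k_slow 0.002 s⁻¹,
  k_fast 0.02 s⁻¹; noise SD 0.01 normalized units). SRX and DRX are a
  static mixture per trace (interconversion rates accepted but default 0,
  since the chase protocol gives no handle on them).
* **Trap recordings** — a unit-variance Ornstein–Uhlenbeck process (exact
  AR(1) recursion) scaled piecewise: stationary variance kT/κ when free
  (κ = 0.04 pN/nm → ~103 nm²), one quarter of that when bound; one shared
  corner frequency (2 kHz, a stiff dumbbell). Events start as a Poisson
  process, last exponentially with the ATP-limited detachment rate, shift
  the mean by d₁ at attachment and by d₂ after an exponential delay
  (default rate 100 s⁻¹, i.e. the substep completes in ~10 ms as expected
  for a stroke coupled to fast product release). If the delay outlasts the
  event, the second substep never occurs — real ensemble averages carry the
  same incompleteness. Not emulated: two-bead covariance geometry, drift,
  low-pass filter ringing, load dependence.
* **Motility movies** — straight filaments with a Gaussian cross-section
  (σ = width/2.355) rendered analytically (erf-smoothed ends), translating
  along their own axis; Poisson photon noise over a constant background
  (signal 500, background 100 counts). Ground-truth midpoints are exact
  sub-pixel values. Not emulated: filament flexing, photobleaching,
  off-axis wobble, surface detachment.

Passing recovery tests therefore shows the estimators are correct and
well-calibrated under these idealized conditions; it does not certify
robustness to the instrumental artifacts listed as not emulated.

## Analysis pipelines and numerical choices

### ATPase
The linear range of each well is the longest window (≥10 samples) whose
rolling 5-point slopes agree with the window slope within
max(5%, 3× the local-slope SE), and which is linear by either R² ≥ 0.995
or a residual SD within 20% of the trace noise. The second branch exists
because R² measures signal-to-noise, not linearity: a basal (actin-free)
well at realistic noise never reaches R² 0.995 despite being perfectly
linear. The noise scale is a MAD of first differences, robust to the
depletion kink. Ties break toward the earliest window (initial velocity).
Basal subtraction precedes replicate averaging. Michaelis–Menten fits are
nonlinear least squares with t-based 95% CIs; fits are discarded as
ambiguous when a relative CI half-width exceeds 100% or K_M exceeds 10×
the largest tested actin concentration. The plate-level kcat CI is widened
by the two error sources shared across wells — NADH conversion-factor
uncertainty (multiplicative) and basal-rate uncertainty (additive) — which
per-point fit covariance cannot see; without this the CI under-covers
(~75% instead of ~95%).

### Stopped-flow
Transients are fit as single exponentials initialized from log-linearized
data; fits with k·t_max < 3 are flagged truncated. The ATP dependence is
fit twice: the full two-parameter hyperbola, and a low-ATP branch
([ATP] ≤ 0.2/K₁ from a pilot fit, minimum three points) regressed through
the origin after multiplying each k_obs by (1 + K₁[ATP]). The correction
removes the first-order curvature bias of the low-ATP subset (10–17%
uncorrected), so the internal-consistency invariant K₁k₊₂ ≈ k₊₂/(1/K₁)
holds within 2× combined SE on accepted fits. Data entirely in the linear
regime are flagged hyperbolically unidentifiable. ADP competition fits
k₀/(1+[ADP]/K_ADP) with k₀ free unless supplied; a positive trend of
k_obs with ADP raises a model-violation flag.

### Single turnover
The chase is taken from metadata, or located as the largest sustained
slope change (windowed slopes on both sides of each candidate point —
single-sample differences are too noisy at gentle decay rates). The signal
is normalized to the mean of the 5 pre-chase samples and fit with
A·e^(−k_slow·t)+(1−A)·e^(−k_fast·t), A ∈ [0,1], ordering enforced by
parameterizing k_fast = k_slow + δ, δ ≥ 0. SRX is the slower phase. If a
single exponential fits as well as the biexponential (or A leaves [0.01,
0.99]), the trace is reported as a pure slow phase — a single-phase decay
carries no label information, so the constrained report A_slow = 1 is the
convention; genuinely two-phase fits with rates within 3× are rejected as
phase collapse.

### Optical trap
Stiffness calibration fits the sampled (aliased) Lorentzian — the AR(1)
spectrum, linear in cos ω — rather than the continuous Lorentzian, which
is biased near Nyquist; variance follows by integrating the fitted
spectrum and stiffness by equipartition. Event detection thresholds the
10 ms windowed variance with hysteresis (enter 0.5×, exit 0.75× the free
level, estimated as the median windowed variance), then refines both event
edges to sub-millisecond accuracy with a Gaussian mean/variance
changepoint. The 10 ms window (rather than 5 ms) keeps the false-positive
rate on pure noise below 0.01 events/s at a 2 kHz corner; the dead time
equals the window. Because events between 1× and 2× the dead time are
only partially detected (soft truncation), rate estimation uses events
≥ 2× the dead time with the truncation point propagated into the MLE,
rate = 1/(mean − deadtime), with a 1000-resample bootstrap percentile CI.
Ensemble averages align events at attachment (forward) and detachment
(reversed), extend short events by holding the terminal bound level, and
estimate d₁ as the t→0 intercept of an exponential fit to the forward
average — skipping the first 2 ms, where alignment jitter smears the
attachment edge — and d_total as the reversed-average plateau, excluding a
1 ms guard before detachment; d₂ = d_total − d₁, with a bootstrap noise
floor over events. Traces are sign-oriented per molecule before averaging
(actin polarity is random between assemblies).

### Motility
The ridge response is the maximum of `skimage.filters.sato` over scales
matched to the 2–6 px width band; the mask threshold is Otsu's (a fixed
value or quantile can be supplied). Components are skeletonized and pruned
to the longest geodesic path (double Dijkstra sweep over the pixel graph);
the midpoint is interpolated at half arc length. Width is twice the mean
distance-transform value along the skeleton — orientation-independent,
unlike area/length. Three classes of detection are dropped: widths outside
the band; skeletons touching the image border (clipped fibers' midpoints
lag their motion); and components whose longest path covers <80% of the
skeleton — these are crossing fibers, whose pruned-line midpoint tracks
the slowly moving overlap and would bias the per-video mean velocity
several percent low. Tracking solves a linear assignment problem per frame
with squared-displacement costs, a gating radius (scaled by the time gap),
and birth/death costs of gate²; gap closing keeps lost tracks alive for a
configurable number of frames. Velocity is the mean frame-to-frame speed
(min 5 frames per track); a minimum-speed filter exists but defaults off.
Coordinates are pixel centers, origin top-left, x right / y down.

### Markov state models
Counts use sliding windows at the chosen lag within each trajectory.
Estimation adds a pseudocount of 1/n (n = number of microstates) to every
count and row-normalizes — no detailed-balance constraint, matching the
stated procedure. π is the leading left eigenvector; eigenvalues sort by
magnitude with index tie-breaks; complex pairs raise a non-reversibility
warning and enter timescales by magnitude. Note the pseudocount keeps
every λ₂ strictly below 1, so a non-interconverting system reports a
timescale on the order of the total data rather than infinity.

## Problem sizes

The recovery studies run at 100 plates per ATPase parameterization, 200
stopped-flow datasets per construct (50 for ADP competition), ≥1200
pooled trap events per construct across three recordings, three
20-filament 30-frame motility videos, and a 10⁶-step Markov chain — sizes
at which medians are stable to well under the comparison tolerances while
a full run stays under two minutes.

## Known limitations

* The serial-cycle simulator has no load dependence and no branching
  (e.g. no futile hydrolysis), so it cannot emulate strain-gated kinetics.
* Trap step estimates from bound-segment means are slightly below
  d₁ + d₂ (by ~0.2–0.3 nm) because events spend their first ~10 ms at d₁;
  the ensemble-average route is the unbiased substep estimator.
* Detected trap event durations inherit ~1 ms edge jitter; at detachment
  rates ≫ 100 s⁻¹ this would bias rate estimates, so the analysis is
  intended for the ≤10 s⁻¹ regime probed at low ATP.
* The filament tracker assumes rigid straight filaments; strongly curved
  or flexing filaments would shift midpoints off the true center of mass.
* Single-phase turnover decays are reported as 100% of the slow phase by
  convention; distinguishing a pure-SRX from a pure-DRX population
  requires external rate references.
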