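# Methods

`thzcoag` models a transmission-mode terahertz time-domain spectroscopy
(THz-TDS) measurement of human blood in a thin fluidic chamber, the
inversion of those measurements to optical constants, and the cohort-level
statistics that expose the absorption signature of coagulation.  This note
records the model, its assumptions, the defaults and why, and what the
synthetic data can and cannot establish.

## Forward model

### Chamber

A liquid channel of thickness d = 100 um sits between polyethylene (PE)
windows (n_PE = 1.5, lossless); the ambient index is 1.  Relative to the
source field, the channel region transmits

    empty  : T_PE-air · e^{i w d / c} · T_PE-air
    filled : T_PE-liq · e^{i w d n / c} · e^{-w d k / c} · T_liq-PE

with the normal-incidence Fresnel field transmission
T_a-b = 2 n̄_a / (n̄_a + n̄_b), n̄ = n + i k.  The empty-chamber expression
deliberately carries T_PE-air at *both* interfaces; the air-filled channel
therefore differs from the empty one by the real constant
T_air-PE / T_PE-air = 2/3.  Because the inversion uses the identical
convention, this constant cancels from every extracted quantity — it is a
bookkeeping convention, not physics.  The model is single-pass; an optional
flag adds the first Fabry-Perot echo of the channel (free spectral range
c/(2nd) ≈ 0.6 THz for water) to emulate residual etalon ripple.

### Liquid

Blood plasma is, by volume, almost entirely water, so the liquid baseline
is a two-relaxation (double-Debye) water permittivity

    eps(w) = eps_inf + (eps_s − eps_1)/(1 − i w tau_1)
                     + (eps_1 − eps_inf)/(1 − i w tau_2)

with room-temperature literature defaults eps_s = 78.36, eps_1 = 5.16,
eps_inf = 3.49, tau_1 = 8.24 ps, tau_2 = 0.18 ps (all overridable in
config).  These give n ≈ 2.46, k ≈ 0.94 at 0.35 THz and alpha ≈ 125 cm^-1
at 0.27 THz — standard bulk-water sub-THz values.

The blood states modify only the extinction coefficient (the real index is
left at the water value — the phenomenology of interest lives in the
absorption constant alpha = 2 w k / c):

* **uncoagulated** — k(f) = k_water(f) · (1 + c_RBC (RBC − 4.5)), with
  c_RBC = 0.026 per M/uL.  No platelet dependence.  The coefficient is a
  free calibration chosen, together with the between-subject scatter,
  to produce a Pearson correlation r ≈ 0.4 between RBC count and
  alpha(270 GHz) at n = 28 (closed form:
  r = c_RBC·sd(RBC) / sqrt(c_RBC²·sd(RBC)² + sigma_s²) with sd(RBC) = 0.5).
* **early-coagulated / thrombus** — the RBC dependence disappears and
  k(f) = k_water(f) · (1 + s·(f − f_t(PLT))), a linear normalized
  absorption change with slope s = 0.13 per THz whose zero crossing — the
  transparency frequency — falls linearly with platelet count:
  f_t = 0.68 THz − 0.5 THz · (PLT − 196.5)/50 per 50 K/uL.  The thrombus
  state blue-shifts f_t by +0.05 THz.  Below f_t absorption is reduced
  ("THz defect"), above it increased ("THz excess").  The anchors — a
  680 GHz pooled transparency frequency, 0.9/0.4 THz at platelet-bin mean
  counts of 175/224 K/uL, and a 200-270 GHz group reduction of ~5-7 cm^-1 —
  fix every parameter of this effect model.

Between-subject variability is a log-normal multiplicative scale on k with
sigma = 0.03; clotting time is drawn uniformly on [8, 21] min and carried
as metadata only.  A `heparin_control` flag exists as a no-op: heparin at
control concentrations has no measurable THz effect.

### Cohort covariates

Hematology covariates are truncated normals: RBC ~ N(4.5, 0.5) on [3, 6]
M/uL, WBC ~ N(7, 1.8) K/uL, MCH ~ N(30, 2) pg, MCHC ~ N(34, 1.2) g/dL and
PLT ~ N(196.5, 31) on [100, 400] K/uL.  The PLT mean makes
f_t(mean PLT) = 0.68 THz; the sd is chosen so the conditional means of the
100-200 and 200-300 K/uL bins are ≈ 174/224 K/uL, the bin averages the
effect model is anchored to.  The default cohort is 29 early-coagulated +
28 uncoagulated subjects (n = 57); a thrombus group is added by config
where needed.

### Instrument

Each subject contributes one minute per arm: 120 waveforms of 1024 samples
at 0.05 ps (51.2 ps delay span).  The source spectrum is log-normal in
frequency — exp(−(ln(f/0.35 THz))²/(2·1.1²)) with smooth low/high cutoffs
at 0.04 and 2 THz — i.e. a single-cycle pulse whose spectrum is flat
within ~6 dB across 0.1-1.2 THz.  Two numerical requirements drove this
choice and the span: (i) the transmitted pulse (including the ~8 ps slow
water-relaxation tail and the pulse's own acausal tail) must decay to
< 1e-3 of its peak inside the window, otherwise zero-padded spectra
interpolate a wrapped signal and the inversion inherits ~1e-2 errors in k;
(ii) band-edge spectral amplitude within ~6 dB of peak is needed for the
1% three-fill repeatability at the nominal dynamic range.  Noise is white
Gaussian in the time domain, per waveform, scaled so the single-waveform
*spectral* peak dynamic range (peak reference spectral amplitude over
per-bin noise floor — the conventional TDS figure) is 48 dB.  One seed
drives everything; per-subject noise streams are spawned deterministically
so any subject subset is independently reproducible.

## Inversion

Minute-averaged traces are Fourier-transformed (conjugate-rfft convention,
so a delay dt appears as phase +w·dt, matching e^{i w d n / c}; rectangular
window, 4x zero padding) and divided:
R(w) = E_sample/E_ref = C(n̄)·e^{i w d (n−1)/c}·e^{−w d k/c}, with C the
filled-over-empty interface-term ratio.  First estimates ignore C:

    k_0 = −(c/(w d)) ln|R|,    n_0 = 1 + (c/(w d))·Δφ,

where Δφ is the unwrapped phase of R, anchored at the lowest band
frequency with the 2π branch chosen so n there is physically plausible
(1-4; for this geometry the branch is unambiguous — one 2π step changes n
by ~20 at 0.13 THz).  Note the leading minus sign in k_0: an attenuating
sample (|R| < |C|) must give k > 0 under the e^{−w d k/c} convention.
The Fresnel terms are then eliminated by per-frequency fixed-point
iteration — form C_k from n̄_k, update

    k_{k+1} = −(c/(w d)) ln(|R|/|C_k|),
    n_{k+1} = 1 + (c/(w d)) (Δφ − arg C_k)

— until both |Δn| and |Δk| fall below 0.001 (at most 100 iterations;
unconverged frequencies keep their last value, flagged, and a log message
distinguishes oscillation from slow convergence).  Because C varies slowly
with n̄ the iteration contracts quickly: ~10-12 iterations for water
across 0.13-1.02 THz.  The first estimate's k_0 is biased by
−(c/(w d))·ln|C| — 40-300% of k below 4 THz for d = 100 um — which is
exactly the bias the iteration removes; n_0 is within ~10% from the start.
Finally alpha = 2 w k / c, reported in cm^-1.

Reference and sample are treated as drift-free pairs (the reference minute
precedes the fill); drift modeling, multi-echo transfer-matrix inversion
and Debye fits to extracted spectra are out of scope.

## Statistics

* Pooled-variance two-tailed two-sample t-test per frequency with the 95%
  CI of the mean difference (classic equal-variance `ttest2` semantics);
  Welch's variant is available by calling scipy directly but the pooled
  form is the default deliberately.  Significance stars use the printed
  open bins *0.01<p<0.05, **0.001<p<0.01, ***p<0.001; boundary p-values
  are labelled on the less-significant side and flagged.
* Pearson r with the two-sided t-transform p-value; a correlation is
  "declared" only when p < 0.05.
* Hematology filters exactly as printed: 4 < RBC <= 5 M/uL (half-open) and
  100 <= PLT <= 300 K/uL (closed).
* delta-alpha/alpha_blood uses group-mean spectra; the transparency
  frequency is the zero crossing of an unweighted least-squares line over
  0.13-1.02 THz, not the nearest raw sign change — the raw curve carries
  etalon ripple and noise, the fitted crossing is the stable estimand.  A
  fitted |slope| below 1e-3 per THz flags the crossing undefined.
* The PLT-stratified analysis bins filtered early-coagulated subjects at
  [100, 200) and [200, 300] K/uL and reports per-bin transparency
  frequencies and their difference (negative = red shift).
* No multiple-testing correction is applied across frequencies;
  per-frequency p-values are reported as such (caveat emptor).

## Problem sizes and determinism

Default analyses use the 29+28 (+29 thrombus where relevant) cohorts with
120 waveforms per arm; the stratified analysis draws early-coagulated
subjects in batches until both platelet bins hold 9 filtered subjects.
One full cohort simulate-extract-analyze cycle takes ~2 s on one CPU.
Replicate-mean estimates in `scripts/acceptance.py` use 20 cohorts for the
pooled transparency frequency and 100 for the per-bin quantities, whose
9-subject bins carry a ~0.11 THz per-replicate sampling SD.  All
randomness descends from a single integer seed through named substreams;
identical config + seed reproduces outputs byte-for-byte.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis assumes:
water-dominated absorption, an RBC-scaled uncoagulated state, a linear
PLT-anchored normalized change after coagulation, instrument noise at a
stated dynamic range, and between-subject scatter.  Passing tests
demonstrate that the inversion is a faithful inverse of the forward model
and that the estimators recover the calibrated effect structure at the
study's sample sizes — not that real blood behaves this way.  In
particular: absolute alpha levels of blood are not ground truth anywhere
(only the water baseline and the normalized changes are anchored); scatter
is a single log-normal scale rather than cell-resolved optics; n(f) of
blood is left at the water value; temperature, drift and heparin chemistry
are unmodeled.  The linear delta-alpha/alpha law necessarily exits the
measured band at extreme platelet counts (f_t(300 K/uL) < 0); it is used
as a local, in-band description, which is how it is anchored.

## Numerical choices

* Convergence is per-frequency and both-parameter (|Δn| and |Δk| < 0.001).
* Rectangular window by default: the synthetic traces decay inside the
  span, so apodization would only bias amplitudes; Hann is available.
* Zero-padding 4x gives a 4.88 GHz grid over the analysis band.
* Reference bins with |E_ref| under 1e-12 of peak are flagged unconverged
  rather than propagated.
* Degenerate statistics (zero pooled variance, zero-variance correlates)
  return the conventional limits (p = 1 / p = 0, undefined r) with a
  `degenerate` flag instead of raising.
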