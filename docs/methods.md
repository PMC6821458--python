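# Methods

This note records the model, the estimation choices, what the synthetic
signals do and do not emulate, and the numerical decisions a maintainer
would otherwise have to reverse-engineer from the code.

## Signal decomposition

A single-channel voltage trace is filtered into a low band (default
4–7 Hz) and a high band (default 100–140 Hz) with symmetric least-squares
linear-phase FIR filters applied forward–backward, so the filtered series
have zero group delay. Phase and amplitude come from the analytic signal
(Hilbert transform): φ_low and A_low from the low band, A_high from the
high band. One second is discarded at each record edge before any model is
fit, covering the filter and Hilbert transients.

Filter design is a dense-grid least-squares fit of the amplitude response
(passband 1, stopbands 0, transition regions excluded: 2 Hz per edge for
the low band, 10 Hz for the high band). Both even and odd tap counts are
supported; with an even count the response is expanded in half-integer
cosines (type II linear phase). The designer matches `scipy.signal.firls`
where the latter applies (odd tap counts).

Both default filter orders are 375 at the default 1 kHz sampling rate.
This matters for the low band: phase-amplitude coupling lives or dies on
the accuracy of φ_low at the low-frequency peaks, and an FIR filter's
transition width is roughly fs divided by its tap count. A much shorter
low-band filter (say order 50 at 1 kHz) passes broadband power, roughly
40% of the filtered variance falls outside 2–9 Hz, the filtered signal
acquires ~40% spurious local maxima, and phase estimates at the true peaks
err by more than a radian — enough to make even strong simulated coupling
undetectable. Order 375 keeps out-of-band leakage under 2% of variance.
The passband ripple that remains (~17% on the envelope after
forward–backward application) is a pure scale factor on A_low and is
absorbed by the regression coefficients.

## The coupling models

A_high is strictly positive and right-skewed; it is modelled as gamma
distributed with a log link. Three nested models are fit per record:

* **phase model** — log μ = Σₖ βₖ fₖ(φ_low), k = 1..n;
* **amplitude model** — log μ = β₁ + β₂ A_low;
* **joint model** — the phase model plus A_low, A_low·sin φ_low and
  A_low·cos φ_low (n + 3 coefficients).

The phase basis {fₖ} consists of periodic cardinal splines with n = 10
control points equally spaced on [0, 2π) and tension 0.5 (the Catmull-Rom
choice): fₖ interpolates the indicator of control point k, at most four
basis functions are non-zero at any phase, and the basis sums to one
everywhere — which is why the spline models carry no separate intercept.
The two trigonometric interaction terms let the phase effect grow or
rotate with A_low without the full n-fold phase-by-amplitude interaction.

n = 10 is supported by an AIC scan: refitting the phase model for
n = 4..30 on signals carrying both couplings and scoring each fit with
AIC = deviance + 2n, the minimizer concentrates in 7–12 (the acceptance
suite reruns this selection study).

Fitting is iteratively reweighted least squares. For the gamma family
with a log link the IRLS working weights are identically one, so the Gram
matrix X'X is fixed: it is Cholesky-factorized once per design and each
fit reduces to a handful of matrix–vector products (initialized from the
Gaussian fit to log A_high; relative deviance tolerance 1e-8, maximum 100
iterations; the resampling loops use a cheaper coefficient-stability
criterion at 1e-6 and compute the deviance once at the end). The gamma
shape ν is the reciprocal of the Pearson dispersion; the coefficient
covariance is dispersion × (X'X)⁻¹. Fits are cross-checked against
statsmodels' gamma GLM in the test suite. Non-positive amplitude values
(possible only for amplitude series assembled outside the Hilbert
pipeline, e.g. spikes plus noise) are floored at the smallest positive
observation before fitting; the modulation index uses the same floored
series.

## The statistics R_PAC and R_AAC

Each fitted model is evaluated as a mean-response surface on a shared
grid: 640 evenly spaced A_low values between the 5th and 95th sample
quantiles of the observed A_low (linear-interpolation quantiles), by 100
evenly spaced phases in [−π, π]. The amplitude-model surface is constant
along phase, the phase-model surface constant along A_low. Then

    R_PAC = max |1 − S_Alow / S_joint|,
    R_AAC = max |1 − S_φlow / S_joint|,

maxima over the grid of positive surfaces. Both statistics are ≥ 0 and
unbounded above. Because every log-surface is linear in A_low at fixed
phase and |1 − eᵈ| is quasiconvex in the log-ratio d, the grid maximum is
always attained on the A_low grid endpoints; the resampling loops use this
200-point shortcut, and a test pins it to the full-grid and double-loop
evaluations at 1e-12.

**Confidence intervals.** A parametric bootstrap: coefficient vectors for
the two models entering a statistic are drawn independently from
multivariate normals centred on the fits with the fitted covariances
(default 10,000 draws), the surfaces rebuilt and the statistic recomputed
per draw; the CI is the 2.5–97.5% quantile range. A covariance that fails
the Cholesky factorization is diagonalized; genuinely negative eigenvalues
trigger a warning and projection to the nearest PSD matrix.

**Significance.** AAFT surrogates of the high-frequency signal: the
signal is rank-mapped onto a Gaussian sequence, the Gaussian copy is
phase-randomized in the Fourier domain (Hermitian symmetry preserved),
and the original values are mapped back by rank — an exact permutation of
the observed values with approximately the original spectrum. Per
surrogate the envelope is re-extracted and only the affected model pair is
refit (amplitude + joint for R_PAC; phase + joint for R_AAC; both
condition models for the condition statistic); φ_low and A_low are
untouched by construction. p = (# surrogate statistics > observed) /
n_surrogates, with a floor of 0.0005 when the count is zero (default
1,000 surrogates; ties in the rank maps broken by first occurrence, so
every surrogate is reproducible under its seed). Surrogates whose refit
fails to converge are dropped with a recorded count.

**Condition covariate.** For two-condition records (binary indicator P),
two extended models are fit: the joint model plus the full
P × (spline block, A_low) interaction (2n + 4 coefficients), and the joint
model plus P × A_low alone (n + 4). Both are evaluated at P = 1 on the
shared grid and compared with the same max-fractional-distance statistic
(R_PAC,condition); a large value means the phase profile itself changes
with condition, not merely the amplitude. Its p-value reuses the AAFT
machinery on the full high-frequency signal with the condition labels held
fixed (the construction of this surrogate is an implementation choice; a
within-condition permutation would be a reasonable alternative).

**Modulation index.** For comparisons, the package includes the
phase-binned MI: mean A_high in 18 equal phase bins, normalized to a
probability vector, scored by KL divergence from uniform divided by
log 18. Empty bins take the global mean with a warning.

## Synthetic signals

All generators are seeded and return their ground truth (components,
modulation signal, bump times, thresholds). The common background is pink
noise — Fourier amplitudes ∝ f^(−1/2), uniform random phases, unit
variance — filtered into V_low and V_high with the analysis filters; the
assembled trace is V = V_low + V_high′ + 0.01·V_pink with a fresh noise
instance.

* **PAC**: a modulation signal M, baseline 1, with a Hanning bump of peak
  exactly 1 + I_PAC centred on each local maximum of V_low (42 ms support;
  43 samples at 1 kHz so the unit peak lands on the maximum itself);
  V_high′ = M·V_high. I_PAC = 1 doubles the amplitude at each peak.
  Overlapping bumps take the pointwise maximum.
* **AAC**: V_high′ = V_high·(1 + I_AAC·A_low/max A_low).
* **PAC + AAC**: the phase modulation applied first, the envelope scaling
  second.
* **Sparse PAC**: bumps retained only at peaks whose envelope exceeds the
  83rd quantile of the V_low peak values (~17% of cycles, confined to
  high-amplitude stretches). The default quantile reproduces the realized
  event rate of constructions that threshold a broadband short-filter
  envelope at the 95th quantile of its peak values: such an envelope rides
  25–30% above the band-limited peak values, so the nominal "top 5%"
  comparison in fact keeps every cycle inside the high-envelope stretches
  — measured directly, ~19 distinct coupled events per 20 s. A strict
  top-5% variant (`quantile=0.95`, ~6 events per 20 s) is available; its
  coupling is close to undetectable by any phase-based measure at this
  record length.
* **Opposed PAC**: threshold at the median of the A_low local-maximum
  values; bumps above it keep the 1 + I_PAC amplification, bumps below it
  have M forced to 0 over the bump support. Averaged over amplitudes the
  phase profile looks nearly flat.
* **Amplitude confound pair**: the same PAC components reassembled with
  V_low doubled and fresh noise — coupling untouched.
* **Stepped confound**: 200 s, no PAC; at the midpoint the low-frequency
  amplitude jumps tenfold and AAC of intensity 2 switches on. Any PAC
  detection is a false positive.
* **Two-condition records**: 40 s with P switching at the midpoint;
  variants with PAC turning on (step), nothing changing (null), or the
  low-frequency amplitude doubling under fixed PAC (amp_double).
* **Spiking model**: A_low a slow sinusoid between 1 and 2 (0.1 Hz),
  φ_low a 6 Hz carrier, preferred phase φ* = π(1 + A_low) wrapped; the
  per-sample spike probability is λ₀·exp[−(1 + s(φ_low − φ*)²/2σ²)] with
  σ = 0.01, s the absolute wrapped phase difference, and λ₀ = 2e so the
  nominal peak rate is 2, clamped to a valid probability (a rate above one
  spikes with certainty). A_high = spikes + Gaussian noise (sd 0.1). The
  preferred phase sweeps half the circle as A_low traverses its range, so
  phase-only measures see a much weaker effect than the joint model.

What the generators emulate: 1/f background spectra, band-limited slow
rhythms with waxing-waning envelopes, multiplicative phase-locked and
envelope-locked modulation of fast activity, and abrupt condition changes.
What they do not emulate: non-sinusoidal or asymmetric slow waveforms
(which confound all phase-based CFC measures), latent common drivers,
nonstationary band frequencies, multichannel structure, or measurement
artifacts. Passing the simulation studies therefore demonstrates
correctness of the estimator under the stated generative model, not
robustness to every pathology of in vivo data.

## Study scales and defaults

Full-scale references for the detection-rate studies use 1,000 runs ×
1,000 surrogates per scenario; that is hours of CPU. The package's study
runner defaults to 100 runs × 100 surrogates (binomial SE ≤ 5 points;
p-value resolution 0.01), and `scripts/acceptance.py` uses 80 runs for
the 20 s scenarios, 20 runs for the 200 s stepped-confound pair, and 40
runs for the 40 s two-condition tests — sizes chosen so the whole script
completes in roughly a quarter hour on one CPU. The test suite replicates
each study at 20–40 runs × 50 surrogates and compares rates to the
full-scale references within three binomial standard errors. Every run
draws its simulation and its surrogates from an independently spawned
stream of one root seed, so studies are reproducible and order-independent.

## Known limitations

* R_AAC depends on the observed A_low range (the 5–95% grid bounds); the
  amplitude model is linear in A_low, so the maximum distance typically
  sits at a grid edge.
* The frequency bands are fixed inputs; coupling outside them is
  invisible. Scanning bands is possible but quadratically expensive.
* The AAFT null preserves the amplitude distribution and spectrum but not
  envelope autocorrelation exactly; for heavily nonstationary records the
  surrogate null can be conservative or anticonservative (the stepped
  scenario probes one such case for the modulation index).
* The gamma/log-link model assumes a multiplicative, smooth dependence of
  A_high on the predictors; sharp transients or non-sinusoidal slow waves
  violate it.
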