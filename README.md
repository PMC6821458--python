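# glmcfc

Cross-frequency coupling (CFC) analysis for neural voltage recordings,
built on gamma generalized linear models.

## The problem

Slow brain rhythms modulate fast ones. The two couplings most often
reported between a low-frequency band (e.g. theta, 4–7 Hz) and the
amplitude of a high-frequency band (e.g. high gamma, 100–140 Hz) are

* **phase–amplitude coupling (PAC)** — the fast amplitude A_high depends on
  the slow phase φ_low, and
* **amplitude–amplitude coupling (AAC)** — A_high depends on the slow
  envelope A_low.

Phase-only PAC measures (such as the phase-binned modulation index, MI) are
confounded by changes in low-frequency power and by coupling that itself
depends on A_low: they can report PAC where none exists when A_low steps
up, and miss PAC that occurs only during high-amplitude stretches.

`glmcfc` addresses this by modelling A_high as a gamma random variable
whose log mean is linear in *both* phase and amplitude predictors:

    phase model:      log μ = Σₖ βₖ fₖ(φ_low)
    amplitude model:  log μ = β₁ + β₂ A_low
    joint model:      log μ = Σₖ βₖ fₖ(φ_low) + β_{n+1} A_low
                              + β_{n+2} A_low sin φ_low + β_{n+3} A_low cos φ_low

where {fₖ} is a periodic cardinal-spline basis (n = 10 control points,
tension 0.5) that sums to one at every phase. Each fitted model defines a
mean-response surface over a 640 × 100 grid of (A_low, φ_low) values
(A_low spanning its 5th–95th sample quantiles), and coupling is measured
as the maximum absolute fractional distance between nested surfaces:

    R_PAC = max |1 − S_Alow / S_joint|      (what phase adds, net of A_low)
    R_AAC = max |1 − S_φlow / S_joint|      (what A_low adds, net of phase)

Uncertainty comes from a parametric bootstrap on the fitted coefficients
(10,000 multivariate-normal draws → 95% CIs), and significance from
amplitude-adjusted Fourier transform (AAFT) surrogates of the
high-frequency signal (1,000 surrogates → p-values, floored at 0.0005),
which preserve its amplitude distribution exactly and its spectrum
approximately while destroying any coupling. A condition-extended model
pair tests whether the PAC profile itself differs between two experimental
conditions (R_PAC,condition). A full set of seeded signal generators (pink
noise backgrounds, phase-locked Hanning modulation, envelope scaling,
sparse/opposed/stepped variants, a stochastic spiking model, two-condition
records) makes every validation study reproducible from a seed.

## Worked example

```python
from glmcfc import CFCModel
from glmcfc.simulate import simulate_pac

sim = simulate_pac(i_pac=1.0, duration=20.0, fs=1000.0, seed=7)
res = CFCModel(sim.v, sim.fs).fit()
res.conf_int(n_draws=2000, seed=1)
res.significance(("r_pac", "r_aac"), n_surrogates=200, seed=2)
print(res.summary())
```

prints

```
Cross-frequency coupling (gamma GLM) results
=============================================
observations: 18000  (fs = 1000 Hz, 18.0 s after edge trim)
low band: (4.0, 7.0) Hz   high band: (100.0, 140.0) Hz
spline control points: 10 (tension 0.5)

model    #coef      deviance           AIC  shape nu
phi         10       6286.64       6306.64     3.462
alow         2       6695.31       6699.31     3.049
joint       13       6258.84       6284.84     3.467

R_PAC  = 0.3055   95% CI [0.2769, 0.3359]   p = 0.01
R_AAC  = 0.1281   95% CI [0.1111, 0.1748]   p = 0.235
```

The simulated trace carries strong PAC (the high-frequency amplitude
doubles in a 42 ms window around each low-frequency peak) and no AAC, and
the statistics agree: the joint-model surface departs from the
amplitude-only surface by 31% at its largest, far outside the surrogate
distribution (p = 0.01 at 200 surrogates), while R_AAC is unremarkable
(p = 0.24).

The same analysis is available from the shell:

```sh
glmcfc simulate --scenario pac --i-pac 1.0 --seed 7 --out sim.csv
glmcfc analyze sim_voltage.csv --fs 1000 --out report.json
glmcfc study --scenario pac --n-runs 100 --n-surrogates 100 --seed 1
```

For two-condition recordings (one voltage column, one 0/1 condition
column), `glmcfc analyze-condition` fits the condition-extended models and
reports R_PAC,condition with its surrogate p-value.

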