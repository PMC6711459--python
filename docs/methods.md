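# Methods

## Scope and model class

`dcmfmri` implements the deterministic, one-state, bilinear dynamic causal
model for task fMRI: experimental inputs drive and modulate a linear
network of regional neural states, each state drives a balloon–Windkessel
haemodynamic cascade, and a static BOLD equation plus a confound GLM and
IID Gaussian noise produce the observations. Two-state neural models,
stochastic dynamics, nonlinear (second-order-in-state) coupling,
cross-spectral (frequency-domain) fitting, sparsity priors for large
(>8-region) networks, multi-start estimation, and group-level (empirical
Bayes) analysis are out of scope, as are ROI selection and timeseries
extraction, which are assumed to have happened upstream.

## Experimental inputs

Inputs live on a microtime grid of 16 bins per TR by default (configurable
through the `dt` passed to `build_input_matrix`). Block conditions are unit
boxcars. Conditions consisting entirely of zero-duration events place
`1/dt` in each event bin, so the integral of a column equals its event
count regardless of resolution; conditions mixing events and blocks are
rejected because that scaling is defined only for all-event conditions.
Onsets are seconds from the start of the first volume. Within-condition
overlap is rejected; between-condition overlap is allowed (condition
hierarchies such as task/sub-task are normal designs). Mean-centring is a
separate, explicit step applied after construction and before integration;
it subtracts each column mean, making the `A` matrix the *average*
connectivity across conditions, and a second centring call is an error
rather than a silent no-op. The centred inputs are used everywhere in the
neural equation, driving inputs included.

## Parametrisation and priors

Free parameters are collected in a fixed, documented order: `A` row-major,
`B` per condition row-major, `C` column-major, then transit times, decay
rates, the global intra/extravascular ratio ε, then confound coefficients.
Switched-off parameters are *excluded* from the vector (the forward model
uses zero) rather than carried with near-zero variance — equivalent
posteriors, better-conditioned covariance matrices.

Diagonal (self) entries of `A` and `B` are unitless log-scalings of the
default −0.5 Hz self-inhibition; off-diagonal entries are rates in Hz. `C`
is stored on its unit-variance prior parametrisation and scaled by 1/16
inside the neural flow. Prior variances: 1/64 for `A`, 1 for `B` and `C`,
1/256 for the three haemodynamic log-scalings. Confound coefficients get
N(0, 1e8) — effectively flat, as appropriate for nuisance means. All prior
covariances are diagonal. Under these priors an isolated region's time
constant τ = 2 exp(−A_I) lies in [1.63, 2.46] s with 90% probability, and
in [0.38, 10.49] s when one condition modulates the self-connection.

κ (vasodilatory decay) and τ_h (transit time) are per-region; ε is one per
model, following the convention that the intra/extravascular balance is a
property of the acquisition rather than of a region.

## Haemodynamics and fixed constants

The cascade and BOLD equation are stated in the README. Fixed constants
(one `HaemoConstants` object, overridable): γ = 0.41 Hz (inflow feedback),
α = 0.32 (Grubb's exponent), E0 = 0.4 (resting oxygen extraction), V0 = 4
(resting venous volume scaling — this convention puts the output in percent
signal change), r0 = 25 Hz, θ0 = 40.3 Hz. γ = 0.41 is the classic
balloon-model value; together with κ = 0.64 Hz and τ_h = 2.00 s it places
the peak of the response to a brief stimulus at ≈5.7 s post stimulus,
within the physiological 5–6 s window, which is the one property of these
constants the test suite depends on. (The more recent alternative
γ = 0.32 pushes the peak just past 6 s.) V0 = 4 rather than a volume
*fraction* of 0.04 keeps predictions on the percent-change scale on which
the observation-noise prior (variance exp(−6) = 0.0025) is meaningful.

Inflow, volume and deoxyhaemoglobin are integrated in log space, which
enforces their positivity exactly; the vasodilatory signal stays linear.

## Integration and sampling

A fixed-step classical RK4 scheme advances the coupled 5R-state system
over microtime bins with zero-order-hold inputs; each bin is subdivided so
substeps never exceed 62.5 ms. Fixed-step integration was chosen over
adaptive schemes for bit-level reproducibility; RK4 at this step passes a
matrix-exponential oracle on the (linear) neural subsystem to 1e-8 and a
step-halving check to 1e-4 relative. States start at the exact rest point
with no burn-in (inputs are centred excursions around baseline). Region
r's BOLD output is sampled at `j·TR + slice_times[r]` (slice-timing
model); the default slice time is TR/2, settable per region up to TR.
Numerical blow-up aborts with the first bad microtime bin identified.

For the inversion, finite-difference sensitivities are obtained by
integrating all 2·n+1 perturbed parameter vectors as one broadcast batch,
which costs roughly one integration of wall time instead of 2·n+1.

## Noise model

One IID covariance component per region: an identity block over that
region's volumes in the region-major observation vector. The precision
Σ_i exp(λ_i) Q_i is therefore diagonal and its log-determinant exact.
λ_i ~ N(6, 1/128), i.e. prior noise sd ≈ 0.05 on the percent-change scale.
No temporal correlation components are provided; data are assumed
pre-whitened/high-pass filtered upstream.

## Variational Laplace

Gauss–Newton ascent on the free energy with Levenberg–Marquardt damping:
steps that increase F are accepted (damping ×0.7), steps that do not are
rejected and retried from the best point (damping ×2). λ is updated by
clamped Newton steps (prior ±8 sd — the clamp prevents precision collapse
on degenerate data) inside a short fixed-point loop with the posterior
covariance. Initialisation is the prior mean, deterministically — with
shrinkage priors the prior mean is the natural origin, and no stochastic
multi-start is attempted. Convergence: improvement below 1e-2 nats for 4
consecutive accepted iterations, or a stationary point detected after 8
consecutive rejections with sub-tolerance proposals; cap 128 iterations.
Central differences use step 1e-4.

The reported F is the Gaussian expected log-likelihood (including the
trace coupling of posterior parameter uncertainty into the residuals and
the precision log-determinant) minus the parameter KL *and* the
hyperparameter KL, so model comparisons are internally consistent; with
the noise fixed (`fit_noise=False`) the hyperparameter term is omitted and
F reduces to the exact log evidence for linear problems, which the test
suite verifies against the conjugate closed form.

## Diagnostics

Explained variance removes confound-space variance from data and
prediction before comparing sums of squares (so the figure reflects the
dynamic model, not the fitted mean), is computed over all regions jointly,
and is floored at zero. Per-parameter probabilities are Φ(|μ|/σ), the
posterior mass on the sign of the mean. Credible intervals are two-sided
90% (z = 1.6449). The summary table reports extrinsic connections with a
`source → target` label and units Hz, self and modulatory log-scalings as
unitless, and the effective-self-connection helper converts a fitted model
plus an input context into Hz, time constant and half-life.

## Synthetic data generator

The generator emulates a blocked factorial language design: 10 cycles of
72 s, each holding a 21.6 s "Pictures" and a 21.6 s "Words" block
separated by 14.4 s rest; "Task" events (duration 0) mark every trial
onset within the blocks. Four regions (lvF, ldF, rvF, rdF) with extrinsic
connections between dorsal/ventral pairs within hemisphere and homologous
pairs across hemispheres; Task drives all regions; Pictures and Words
modulate every self-connection — 24 free neural parameters, 37 in all with
the haemodynamic and confound terms. TR = 3.6 s, TE = 30 ms.

Ground-truth defaults are moderate relative to the priors (extrinsic
±0.1–0.3 Hz, modulations ±0.2–0.9, haemodynamic log-scalings ±0.05). The
driving strengths were set by a forward amplitude calculation so that
per-region signal sd is ≈0.05 percent — the scale at which the noise
hyperprior sits, i.e. the scale of normalised extracted ROI timeseries.
SNR is defined as sd(noise-free signal)/sd(added noise) per region (equal
across regions by construction, so the average equals the request);
`snr=inf` returns noise-free data. Everything derives from a single seed.

What the generator does **not** emulate: serially correlated (AR) noise,
motion and physiological confounds beyond a constant column, unmodelled
baseline conditions, regional variation in the BOLD equation constants,
and model mismatch in general — the fitted model class always contains the
generating process. Passing recovery tests therefore demonstrate the
estimator's calibration and identifiability under the model's own
assumptions, not robustness to the violations real data exhibit; on real
subjects, unmodelled baseline conditions and nuisance variance make
explained-variance figures far lower than on synthetic data.

## Numerical and edge-case choices

- Zero-variance (fully confound-explained) data are rejected by
  `explained_variance` rather than returning 0/0.
- A posterior-variance-exceeds-prior check emits a warning, not an error.
- Event bins falling exactly on the scan end are clipped to the last bin;
  input matrices are built with ceil(total/dt) bins so they always cover
  the sampling grid.
- The λ Newton step is always well-defined (its Hessian is strictly
  negative), and λ is clamped to the prior ±8 sd.
- Fitting is fully deterministic given data and options; the only
  randomness in the package is the synthetic generator's seeded noise.

## Known limitations

- Finite-difference sensitivities cost two integrations per parameter
  (amortised by batching); forward-sensitivity ODEs would be exact and
  faster for large models but are not implemented.
- The free energy uses point estimates of exp(λ) rather than its
  expectation under q(λ); with the tight λ prior the difference is
  negligible.
- Evidence comparisons between models fitted on *different* data are
  meaningless; the CLI does not guard against this.
- With ≫8 regions the dense finite-difference Jacobian and the absence of
  sparsity priors make fits slow and potentially under-identified.
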