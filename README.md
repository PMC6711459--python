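# dcmfmri

Deterministic one-state bilinear **dynamic causal modelling (DCM) for fMRI**:
a biophysical generative model mapping experimental inputs through latent
neural dynamics and haemodynamics to BOLD timeseries, inverted with
variational Laplace to yield Gaussian posteriors over connectivity
parameters and a free-energy approximation to the log model evidence.

The package is for researchers who want to estimate *effective
connectivity* — the directed causal influence of one brain region on
another — from task fMRI region timeseries, and to compare competing
network architectures by their model evidence. It covers model
specification and priors, experimental-input construction, forward
simulation, Bayesian inversion, diagnostics, and a synthetic-data
generator with known ground truth for validation.

## The model

Neural activity `z` (one value per region) obeys a bilinear state equation

```
dz/dt = J(u) z + (C/16) u
J(u)  = -0.5 exp(A_I + Σ_k B_I^(k) u_k)   on the diagonal
J(u)  =  A_E + Σ_k B_E^(k) u_k            off the diagonal
```

where `u` are the (optionally mean-centred) experimental inputs, `A` is the
average effective connectivity, `B^(k)` its modulation by condition `k`,
and `C` the driving inputs. Self-connections are exponentiated log-scaling
parameters around the default −0.5 Hz, so they are always inhibitory and
run-away excitation is precluded. Element `(m, n)` of `J` is the connection
from region *n* to region *m*, in Hz.

Per region, `z` drives a balloon–Windkessel cascade — vasodilatory signal
`s`, inflow `f`, venous volume `v`, deoxyhaemoglobin `q`:

```
ds/dt = z - 0.64 exp(κ) s - γ (f - 1)
df/dt = s
2 exp(τ_h) dv/dt = f - v^(1/α)
2 exp(τ_h) dq/dt = f E(f, E0)/E0 - v^(1/α) q / v
```

and the BOLD signal is the static map
`S = V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v))`. Observed data are
`y = g(z, θ_h) + X0 β0 + ε` with IID Gaussian noise whose per-region log
precisions λ carry priors N(6, 1/128).

Inversion maximises the negative variational free energy

```
F = accuracy − complexity ≈ ln p(y | m)
```

by Gauss–Newton ascent with Levenberg–Marquardt damping
(finite-difference sensitivities, Newton updates of λ), under zero-mean
shrinkage priors: `A` entries N(0, 1/64), `B` and `C` entries N(0, 1),
haemodynamic log-scalings N(0, 1/256). Complexity is the KL divergence
from priors to posteriors, so the best model is the most accurate *and*
least complex — comparing `F` across architectures implements Bayesian
model comparison.

## Worked example

Interpreting published posterior means (region `lvF`, conditions Task /
Pictures / Words with centred inputs 0.6 / 0.8 / −0.2 during picture
trials):

```python
import dcmfmri as dcm

params = dcm.ParameterSet.zeros(dcm.default_spec())
params.a[0, 0] = -0.16       # average self-connection (log scaling)
params.b[1][0, 0] = -0.47    # modulation by Pictures
params.b[2][0, 0] = 2.80     # modulation by Words
J = dcm.neural_jacobian(params, u=[0.6, 0.8, -0.2])
print(f"self-inhibition of lvF during pictures: {J[0, 0]:.2f} Hz")
print(f"time constant: {dcm.time_constant(round(J[0, 0], 2)):.2f} s")
```

```
self-inhibition of lvF during pictures: -0.17 Hz
time constant: 5.88 s
```

So during picture trials the region decays slowly (τ = 5.88 s) and is
correspondingly sensitive to its inputs; during word trials the same
arithmetic gives −4.40 Hz (τ = 0.23 s), a strongly self-inhibited state.

End-to-end parameter recovery on a synthetic blocked factorial design
(4 regions, 3 conditions, 200 volumes, SNR 1):

```python
import numpy as np
import dcmfmri as dcm

cfg = dcm.SyntheticConfig(seed=1, snr=1.0, n_volumes=200)
data, truth = dcm.generate_dataset(cfg)
result = dcm.fit(cfg.spec, data)                  # ~40 s on one core
report = dcm.summarise(result, cfg.spec, data=data)
print(f"F = {result.F:.1f} (accuracy {result.accuracy:.1f}, "
      f"complexity {result.complexity:.1f})")
print(f"explained variance = {report.explained_variance:.1f}%")
theta = dcm.vectorise(truth, cfg.spec)
z = (result.posterior.mean - theta) / result.posterior.sd()
print(f"{100 * np.mean(np.abs(z) <= 3):.0f}% of true parameters "
      "within 3 posterior sd")
```

```
F = 1160.9 (accuracy 1249.9, complexity 89.0)
explained variance = 54.5%
100% of true parameters within 3 posterior sd
```

At SNR 1 half the data variance is noise, so ~54% explained variance means
essentially all of the signal was captured; every ground-truth parameter
lies within its 90%-style posterior uncertainty.

The same workflow is available from the shell:

```sh
dcmfmri simulate --out-dir data --seed 1
dcmfmri fit --spec data/spec.json --data data/Y.tsv \
            --timings data/timings.tsv --out fit.json
dcmfmri report --fit fit.json --spec data/spec.json --out report.tsv
dcmfmri recover --seed 1        # simulate + fit + truth comparison
```

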