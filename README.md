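# smkinetics

Single-molecule dwell-time kinetics and mRNA decay analysis for protein–RNA
binding studies.

## The problem

In surface-tethered single-molecule fluorescence (TIRF co-localization)
assays, a labeled RNA binds and releases an immobilized protein — here, the
bacterial RNA chaperone Hfq, with or without its co-repressor Crc — and each
binding event contributes one *dwell time*. The distribution of dwell times
mixes kinetically distinct complexes: a K-component exponential mixture whose
amplitudes `a_k` are the fractions of events dissociating at rate `1/τ_k`.
Two experimental artifacts shape what is observable: events shorter than the
minimum resolvable interval `t_m` (one 0.1 s camera frame) are invisible, and
events longer than the recording `t_x` (3-minute movies) cannot be timed, so
the observed density is the mixture renormalized over `[t_m, t_x]`:

```
f(t) = Σ_k (a_k/τ_k) e^(−t/τ_k)  /  Σ_k a_k (e^(−t_m/τ_k) − e^(−t_x/τ_k))
```

Fluorophore photobleaching (Cy5 lifetime ≈ 173 s) further competes with
dissociation, adding `1/τ_bleach` to every observed rate.

This package provides, as importable library code:

* a **synthetic-data generator** for dwell times (mixture draws, competing
  photobleaching, frame quantization, window censoring), intensity traces,
  and rifampicin-chase decay curves — so the whole analysis is testable
  without experimental data;
* an **event caller** turning per-frame intensity traces into dwell tables;
* **maximum-likelihood fitting** of the truncated mixture for K = 1–4 on
  un-binned dwell times, with BIC model selection;
* **bootstrap standard errors** (resample events, refit, take the σ of the
  replicate estimates), quadrature propagation for a residual amplitude
  `σ_a3 = √(σ_a1² + σ_a2²)`, binomial histogram error bars `√(NP(1−P))`, and a
  two-tailed unpaired test between conditions;
* **half-life estimation** for transcription shut-off (rifampicin chase) time
  courses: reference (16S) normalization, first-order `t½ = ln2/k` from a
  log-linear trendline, and the linear-trendline fallback `t½ = 50/k*` for
  non-first-order decay.

## Worked example

```python
import numpy as np
from smkinetics import (MixtureModel, ObservationWindow, SimulationConfig,
                        simulate_dwells, fit_mixture, bootstrap_fit)

window = ObservationWindow(t_min=0.1, t_max=180.0)          # one frame .. movie end
truth = MixtureModel(weights=[0.56, 0.44], lifetimes=[2.0, 60.0])
data = simulate_dwells(truth, window, SimulationConfig(n_events=5000, seed=0))
fit = fit_mixture(data, K=2, seed=0)
for w, tau in zip(fit.model.weights, fit.model.lifetimes):
    print(f"tau = {tau:6.2f} s   weight = {w:.3f}")
```

prints

```
tau =   2.02 s   weight = 0.559
tau =  57.46 s   weight = 0.441
```

i.e. from 5000 simulated events the fit recovers the unstable (~2 s) and
stable (~60 s) complex populations and their 56/44 split. Bootstrapping
(`bootstrap_fit(data, 2, n_boot=1000, seed=0)`) attaches a σ to each number,
and `compare_conditions` turns two conditions' `(estimate, σ)` pairs into a
two-tailed p-value — e.g. a long-lived fraction of 0.44 ± 0.05 without the
co-repressor versus 0.70 ± 0.04 with it gives p ≈ 5·10⁻⁵.

The numbered scripts under `analysis/` run the full narrative — simulate all
study conditions, fit and select K, bootstrap and compare, estimate decay
half-lives — writing tables under `results/`. The `smkin` CLI exposes the
same stages as subcommands (`smkin simulate-dwells`, `smkin fit`,
`smkin halflife`, `smkin run --config run.yaml`, ...).

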