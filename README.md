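# synpair

Biophysical simulation and simulation-based inference for synaptically
coupled neuron pairs recorded on microelectrode arrays.

When two neurons grow toward each other through a microchannel, the
extracellular electrodes along the channel see both axons' propagating
action potentials, and sorted spike trains reveal whether — and how
strongly — one neuron drives the other.  `synpair` is the computational
arm of that experimental design, for researchers who want to go from
spike trains to biophysical mechanism:

- **Simulate** a pair of ball-and-stick Hodgkin–Huxley neurons (soma +
  100-segment axon each, Crank–Nicolson cable integration) coupled by a
  stochastic AMPA+NMDA synapse at coordinate `z_syn`, driven by Poisson
  spontaneous input, with line-source extracellular potentials at two
  electrodes.
- **Summarize** a pair as the six observables
  `x = (f_pre, f_post, v_pre, v_post, p_syn, lag)` — firing rates,
  axonal conduction speeds, postsynaptic spike probability, and the
  coupling lag.
- **Identify coupling** with transfer entropy on 1-ms binned trains:
  `TE(Y→X) = I(X_t ; Y_{t−δ} | X_past)`, maximized over lag δ ≤ 10 ms
  and target history k ≤ 5 ms, circular-shift surrogate significance
  (200 permutations), Benjamini–Hochberg correction, then a multivariate
  TE stage.
- **Infer parameters** by neural posterior estimation: a mixture density
  network `q(θ|x)` (10 Gaussian components, 2×64 tanh network,
  numpy-native) trained on significance-filtered prior simulations over
  the nine-parameter uniform box
  `θ = (d_pre, d_post, μ_AMPA, σ_AMPA, μ_NMDA, σ_NMDA, λ_pre, λ_post,
  z_syn)`, with amortized sampling, density evaluation and MAP
  extraction.
- **Compare conditions** (e.g. before/after stimulation): per-parameter
  KS shift tests with BH adjustment, Kruskal–Wallis + Dunn across three
  or more conditions, KL divergence between binned distributions.

The model, estimators, and all numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from synpair import (PairParameters, SimulationConfig,
                     run_pair_simulation, extract_summary)

theta = PairParameters(d_pre=1.0, d_post=3.0,
                       mu_ampa=0.0012, sigma_ampa=0.0005,
                       mu_nmda=0.00005, sigma_nmda=0.00002,
                       lambda_pre=15.0, lambda_post=10.0, z_syn=1500.0)
res = run_pair_simulation(theta, SimulationConfig(duration=10_000, seed=7))
s = extract_summary(res)
print(f"f_pre={s.f_pre:.1f} Hz  f_post={s.f_post:.1f} Hz")
print(f"v_pre={s.v_pre:.3f} m/s  v_post={s.v_post:.3f} m/s")
print(f"p_syn={s.p_syn:.3f}  lag={s.lag:.0f} ms")
```

```
f_pre=15.3 Hz  f_post=115.1 Hz
v_pre=0.373 m/s  v_post=0.663 m/s
p_syn=0.634  lag=5 ms
```

The presynaptic neuron fires at ~15 Hz — each Poisson drive event
reliably elicits a spike.  Its d=1 µm axon conducts at 0.37 m/s while the
thicker d=3 µm postsynaptic axon conducts at 0.66 m/s (≈√d scaling).  The
postsynaptic rate is far above its own 10 Hz drive because each synaptic
activation's slow NMDA component (30 ms decay) keeps the axon
suprathreshold for tens of milliseconds — a burst per presynaptic spike.
The transfer-entropy scan places the coupling lag at 5 ms, and 63 % of
presynaptic spikes are answered by a postsynaptic spike within ±0.5 ms of
that lag — a strong pair that passes the p_syn > 0.05 keep-filter.

Training a posterior and recovering parameters:

```python
from synpair import build_training_set, train_posterior
ts = build_training_set(1000, SimulationConfig(duration=4000), seed=101)
model = train_posterior(ts)                      # MDN, early stopping
est = model.map_estimate(s.to_array(), rng=np.random.default_rng(0))
print(dict(zip(model.prior.names, np.round(est.theta_star, 4))))
```

A command-line interface mirrors the library:
`synpair simulate | summarize | te | train | infer | compare | synth`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the pipeline from scratch at smoke scale — synthetic coupled
point processes through TE pair identification, a filtered simulated
training set, posterior training, amortized MAP inference, and a null
condition comparison — and writes the target report JSON.
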