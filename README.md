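# forcekit

FORCE learning and reservoir computing for chaotic recurrent neural
networks, in plain NumPy.

Chaotic recurrent networks — rate-based reservoirs and spiking networks
of LIF, Izhikevich or theta neurons — can be trained to produce target
time series by **FORCE** (First-Order, Reduced and Controlled Error)
learning: a recursive-least-squares (RLS) rule applied online, while the
network runs, so that the output error stays clamped near zero and the
network's own fed-back output stands in for the target. `forcekit` is for
computational neuroscientists and reservoir-computing practitioners who
want these trainers as composable library pieces — network layers whose
forward dynamics are independent of the training rule, trainers that work
with any compatible layer, and seeded generators for the standard
benchmark tasks — without a deep-learning framework dependency.

## The algorithm

For a rate network with currents **x**, rates **r** = *H*(**x**) and
linear readout **z** = **w**ₒᵤₜᵀ**r**, the forward pass is

> **x**(t) = **x**(t−Δt) + (Δt/τ)(−**x**(t−Δt) + **w**ᵢₙᵀ**f**ᵢₙ(t) +
> **w**ᵣᵀ**r**(t−Δt) + **w**_Fᵀ**z**(t−Δt))

FORCE maintains **P**(t) = (α**I** + Σₛ **r**(s)**r**(s)ᵀ)⁻¹ — the inverse
regularized correlation matrix of the rates, a direction-dependent
learning rate — by rank-one Sherman–Morrison updates, computes the
a-priori error **e**₋(t) = **z**(t) − **f**ₒᵤₜ(t), and applies

> **w**ₒᵤₜ(t) = **w**ₒᵤₜ(t−Δt) − **P**(t)**r**(t)**e**₋(t)ᵀ

Four trainers build on this core:

| trainer | weights trained | features | cost/step |
|---|---|---|---|
| `force_fit` | readout (optionally recurrent via per-neuron **A**ⁱ on presynaptic sets B(i)) | rates | O(N²) (O(N³) recurrent) |
| `full_force_fit` | full recurrent matrix + readout, matching a target-driven generator network's currents | rates | O(N²) |
| `spiking_fit` | decoders of a spiking network | filtered spike trains | O(N²) |
| `bio_force_fit` | per-neuron incoming weights of a connectome-constrained network fitted to recorded traces | recorded rates (teacher-forced) | O(Σ\|B(i)\|²) |

See `docs/methods.md` for the exact update rules, spiking neuron models,
synaptic filter, defaults and their rationale.

## Worked example: effective connectivity from population recordings

Fit a connectome-constrained network to synthetic population recordings
generated by a teacher network with known weights (50 neurons, 500
samples at Δt = 0.25 s), learning an effective weight matrix:

```bash
forcekit train --config examples/recording_bio.yaml --out runs/bio --verbose
```

```
seed=1 task_seed=1641411168 weight_seed=1454127163 state_seed=602120507
task=synthetic_recording T=500 dt=0.25
layer=constrained_esn N=50
trainer=bio_force epochs=15 k=1 warmup=0 alpha=1.0
epoch 0: train_mae=0.02757011444842853 val_mae=0.03414974474478982 updates=499
epoch 1: train_mae=0.018803317315742137 val_mae=0.03066289003256256 updates=499
...
epoch 14: train_mae=0.0177964848179046 val_mae=0.02622882282225426 updates=499
final_mae=0.02617636517660975
```

`train_mae` is the mean absolute one-step error during teacher-forced
fitting; `val_mae` is the closed-loop error of the fitted network
free-running against the recorded traces (trace amplitudes are order 1,
so 0.026 means the autonomous replay tracks the data to a few percent).
The run directory contains `history.csv`, the fitted outputs
(`outputs.csv`), the learned effective weight matrix
(`effective_weights.csv`, also in `weights.h5`), the resolved config, and
a log. Re-running the same config reproduces every file byte for byte.

Other shipped recipes: `examples/sines_force.yaml` and
`examples/sines_fullforce.yaml` (autonomous periodic generation with a
400-neuron reservoir), `examples/lorenz_theta.yaml` (Lorenz dynamics
decoded from theta neurons), `examples/delayed_lif.yaml`
(delayed-response task in a LIF network).

The library surface mirrors the CLI:

```python
from forcekit import (gen_synthetic_recording, init_rate_network,
                      bio_force_fit, TrainingConfig)

task, truth, mask = gen_synthetic_recording(n_neurons=50, n_steps=500, seed=1)
params, _ = init_rate_network(50, "constrained_esn", gain=0.0, dims=(3, 1),
                              seed=2, tau=0.5, dt=0.25, mask=mask)
result = bio_force_fit(params, task.f_out, TrainingConfig(epochs=10),
                       f_in=task.f_in)
result.effective_weights      # learned N x N effective connectivity
```

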