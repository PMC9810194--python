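# Methods

`forcekit` trains chaotic recurrent networks with FORCE (First-Order,
Reduced and Controlled Error) learning: an online recursive-least-squares
(RLS) rule that updates readout (and optionally recurrent) weights at
every step while the network runs, keeping the output error clamped so
the network's own output is a usable stand-in for the target. This note
records the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Rate networks

The forward pass is the forward-Euler discretization of the standard
leaky reservoir equation for currents `x` and rates `r = H(x)`:

    x(t) = x(t-dt) + (dt/tau) * ( -x(t-dt) + w_in^T f_in(t)
                                  + w_R^T r(t-dt) + w_F^T z(t-dt) )
    r(t) = H(x(t)),   z(t) = w_out^T r(t)

- `H` defaults to `tanh` and is pluggable by name (`identity`, `relu`).
- Recurrent weights are Bernoulli(`p`)-sparse, zero-mean normal with
  standard deviation `g / sqrt(p N)`. The default gain `g = 1.5` places a
  large network in the chaotic regime that FORCE exploits; `g < 1` decays
  to a fixed point (a property the tests assert).
- Feedback uses the *previous* step's readout, exactly as the update is
  written; there is no same-step feedback.
- Euler only, first order: halving `dt` halves the endpoint error of a
  trajectory (the convergence test asserts ~2x per halving, at least 5x
  over three halvings). No adaptive stepping.
- The connectome-constrained variant reuses the same dynamics under a
  boolean mask with an empty diagonal (no self-loops); masked-out entries
  of `w_R` are exactly zero through every operation.

## RLS and the four trainers

`P(t) = (alpha I + sum_s r(s) r(s)^T)^(-1)` is maintained by the
Sherman-Morrison rank-one recursion and re-symmetrized each update (the
drift is pure round-off; symmetrization keeps it below 1e-10
indefinitely). `alpha` defaults to 1.0 and acts as a ridge regularizer:
with feedback-independent rates and a zero-initialized readout, one
training pass is *exactly* ridge regression, which is the main oracle the
test suite checks against. The error convention is `e = z - f_out`, so
the update `w_out <- w_out - (P r) e^T` reduces the error. Ordering
within a step: P update, a-priori error (pre-update weights),
pseudogradient, weight update; multi-dimensional outputs share one P.

Update gating: after `warmup_steps` settling steps, updates fire on every
`update_interval`-th step, giving `floor((T - warmup) / k)` updates per
epoch. Validation at each epoch end re-runs the training input/target
closed-loop with no updates; P persists across epochs (training is one
continuous RLS stream, epochs are replays).

**Classic recurrent FORCE** (scalar output) keeps one inverse-correlation
matrix `A^i` per neuron, restricted to its presynaptic set `B(i)`. With
full connectivity every `A^i` reproduces the shared P bit-for-bit — an
exact consistency check in the suite. Cost is O(N^3) per step, which is
why it is not the default anywhere.

**full-FORCE** builds a second, fixed target-generating network that
receives the task input *through the same input weights as the task
network*, plus the target (and hint) through its own random encoders. The
task network's recurrent weights are trained with the shared-P RLS so its
recurrent current matches the target network's recurrent current plus the
encoder drive; because the driven network combines `r_D(t)` with the next
step's drive, the matching target uses the drive at `t+1`. The readout is
trained concurrently with the same P. Cost is O(N^2) per step. Hint
channels are a training crutch: they drive only the target-generating
network, while classic FORCE consumes them as extra input dimensions.

A finding from this implementation: with few epochs the concurrent
readout RLS blends samples from the first, pre-convergence epoch into its
regression. Decomposing the final validation error shows the *trained
dynamics* support a fresh ridge readout as accurate as classic FORCE's;
the online readout lags that oracle by tens of percent at 10 epochs. The
comparative benchmark between full-FORCE and classic FORCE is therefore
seed-sensitive at this scale (classic FORCE on a no-feedback reservoir is
an unusually strong baseline, since its validation replays the training
rates and its readout is an exact accumulated ridge fit).

**Spiking FORCE** regresses on the double-exponentially filtered spike
trains and trains the decoders `phi`; the decoded output feeds back
through fixed random encoders `eta` scaled by `Q`. Warm-up runs the
forward pass only (the reservoir must reach its asynchronous spiking
regime before features are informative).

**Bio-constrained FORCE** fits a constrained network to recorded traces,
one model neuron per recorded neuron. Training is teacher-forced: the
regressors are the recorded rates (and the recorded input), which is the
FORCE error clamp applied exactly — during fitting the presynaptic
activity is pinned to the data. Two error conventions:

- `match='currents'` (default): regress the trace-implied current
  increment `(x(t) - (1 - dt/tau) x(t-1)) / (dt/tau)` on the presynaptic
  rates. This is exactly linear, so each per-neuron RLS converges to its
  ridge solution in a single pass and, on teacher-generated data,
  recovers the generating weights up to noise.
- `match='rates'`: the delta rule on `H(x) - trace`. The update direction
  is the same but its magnitude is attenuated by `(dt/tau) * H'(x)`
  relative to the linear error RLS assumes, so convergence is slow; it is
  kept as a switch because the rate error is the quantity reported.

Traces are scaled down uniformly (no offset) only if they exceed the
invertible range of the activation; each neuron's input weights are
fitted together with its incoming recurrent weights; neurons with an
empty presynaptic set are warned about and left untrained. Validation is
a closed-loop pass scored against the traces; early stopping monitors it
with a patience/min-delta rule, and a final no-update pass produces the
reported outputs and the learned `w_R` — the effective connectivity.

## Spiking neuron models

All three models take one Euler step per `dt`, detect threshold
crossings, reset, and enter an absolute refractory period (`t_ref`);
spikes are assigned to the step of the crossing, with no within-step
interpolation (the closed-form tests absorb the O(dt) bias by running at
small dt). Defaults put a few-hundred-neuron network in an asynchronous
spontaneously spiking regime at the default `dt`:

- **LIF**: `tau_m dv/dt = -(v - v_rest) + R I`; defaults `tau_m` 10 ms,
  rest/reset -65 mV, threshold -40 mV, `t_ref` 2 ms, bias 30 (resting
  drive just above threshold, tonic ~56 Hz, matching the closed-form
  interspike interval `tau_m ln[(RI - (v_reset - v_rest)) /
  (RI - (v_thresh - v_rest))]`).
- **Izhikevich**: classic `0.04 v^2 + 5v + 140 - u + I` form integrated
  in milliseconds; defaults a=0.02, b=0.2, c=-65, d=8, peak 30 mV.
- **Theta**: `dtheta/dt = (1 - cos theta) + (1 + cos theta) I`; a spike
  is the phase crossing pi (wrap by -2 pi); constant drive I gives period
  `pi / sqrt(I)`. Refractoriness is a phase hold. Default bias 100
  (~3 Hz tonic).

The synapse is the coupled first-order pair `h' = -h/tau_r + s/(tau_r
tau_d)`, `r' = -r/tau_d + h` (defaults 2 ms rise, 20 ms decay) integrated
*exactly* between spikes with the analytic matrix exponential of the
pair, so a single spike reproduces the impulse response
`(e^{-t/tau_d} - e^{-t/tau_r}) / (tau_d - tau_r)` to machine precision on
the step grid. The filter has unit area, so `syn_r` reads as an
instantaneous firing-rate estimate in Hz.

## Synthetic tasks

- **Sum of sines**: scalar input, constant 1.0 on the first 20 of 801
  steps, silent after; the target is four harmonics (1, 2, 3, 5 of a
  400-step fundamental, two periods per window) normalized to unit peak;
  a dummy all-zero hint channel is attached. The component frequencies
  are a calibration choice of this package.
- **Lorenz**: RK4 at the classical sigma=10, rho=28, beta=8/3, scaled by
  1/10 so tanh-range readouts can match it; autonomous (zero input
  channels).
- **Delayed response**: a 0.5 s input boxcar at a seeded uniform-random
  onset; the target repeats the boxcar 50 ms after input offset; defaults
  5 s at dt = 0.1 ms (5000-sample pulse, 500-sample lag, 50 000 samples).
- **Connectome**: Bernoulli(density) off-diagonal mask, empty diagonal.
- **Synthetic recording**: a connectome-constrained teacher network with
  known weights, driven by 3 slow latent Ornstein-Uhlenbeck inputs
  (timescale 50*dt) standing in for shared sensory/state drive, simulated
  at dt = 0.25 s with `tau = 2 dt`, gain 1.2, input scale 0.5; rates plus
  2% Gaussian observation noise are the traces. Default dimensions
  emulate a single-brain-area population recording (365 neurons, 2500
  samples); tests use a 50-neuron, 500-sample preset. The regime was
  chosen so traces are smooth (lag-1 autocorrelation > 0.5), correlated
  across neurons, and stay out of the activation's saturated range —
  saturation destroys the information needed to invert rates to currents,
  and purely autonomous small teachers either die to a fixed point or
  saturate. If a drawn teacher is temporally degenerate it is re-drawn
  (at most 5 attempts).

What the recording emulator does *not* capture: spiking/calcium indicator
dynamics and deconvolution artifacts, nonstationary baselines, slow
drifts, heavy-tailed noise, and unobserved external drive. Passing the
teacher-student benchmark therefore demonstrates that the fitting
machinery is correct and well-conditioned on data generated by its own
model class — it does not certify weight recovery on real recordings,
where model mismatch dominates.

## Problem sizes in tests and acceptance runs

Chosen to keep the full suite at desk scale: the training-progress
ensemble uses 400 fully connected rate neurons, 10 epochs, 10 seeds; the
ridge oracle 100 neurons x 500 steps; the P oracle 30 x 200; the
teacher-student fit 50 neurons, 400 training + 100 held-out samples; the
spiking Lorenz demonstration 200 theta neurons at dt = 0.1 ms for 3 s
(training on the first 2 s, closed-loop generation on the last 1 s, where
the success criterion is bounded output, not accurate tracking — accurate
spiking generation needs thousands of neurons and finer steps).

## Determinism and seeding

Every stochastic component takes an explicit seed; the experiment
runner splits its single config seed into independent sub-seeds for task
generation, weight initialization and state initialization via
`numpy.random.SeedSequence`. Histories and outputs are written with
`repr`-exact floats, so re-running a config reproduces artifacts byte for
byte.

## Known limitations

- Classic recurrent FORCE is O(N^3) per update step and is only
  practical for small networks; full-FORCE is the O(N^2) alternative.
- The bio-constrained fit assumes the recorded quantity is (an affine
  scaling of) the model rate; there is no observation model beyond
  additive noise.
- Spiking training supports decoder learning only (no recurrent weight
  learning in the spiking layers), matching the scope of the rate/spiking
  split.
- No batching: one trajectory at a time, by design.
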