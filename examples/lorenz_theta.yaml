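# Autonomous Lorenz dynamics decoded from a theta-neuron network
# (desk-scale: 200 neurons, dt = 0.1 ms, 3 s of simulated time).
# The first 0.5 s are a warm-up with no decoder updates; afterwards the
# decoders are updated every 50 steps.
seed: 1
task:
  name: lorenz
  params:
    duration_s: 3.0
    dt: 0.0001
layer:
  kind: theta
  n_neurons: 200
  sparsity: 0.1
  gain: 25.0
  params:
    feedback_scale: 15.0
    dt: 0.0001
trainer:
  kind: spiking
  epochs: 1
  update_interval: 50
  warmup_steps: 5000
output:
  directory: runs/lorenz_theta
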