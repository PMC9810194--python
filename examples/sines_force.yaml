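# Classic FORCE: readout training on a 400-neuron chaotic reservoir.
# The target is an autonomous sum of sines; the input is a 20-step cue.
seed: 1
task:
  name: sum_of_sines
layer:
  kind: nofeedback_esn
  n_neurons: 400
  gain: 1.5
trainer:
  kind: force
  epochs: 10
output:
  directory: runs/sines_force
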