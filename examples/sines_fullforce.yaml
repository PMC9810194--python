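# full-FORCE: recurrent + readout training against a target-generating
# network, with the dummy (all-zero) hint channel.
seed: 1
task:
  name: sum_of_sines
layer:
  kind: nofeedback_esn
  n_neurons: 400
  gain: 1.5
trainer:
  kind: full_force
  epochs: 10
output:
  directory: runs/sines_fullforce
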