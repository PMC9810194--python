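# Effective-connectivity fitting: a connectome-constrained network is
# fitted to synthetic population recordings (teacher network with known
# weights; 50 neurons, 500 samples at dt = 0.25 s) with early stopping.
seed: 1
task:
  name: synthetic_recording
  params:
    n_neurons: 50
    n_steps: 500
layer:
  kind: constrained_esn
  n_neurons: 50
  gain: 0.0          # start from zero recurrent weights
  params:
    tau: 0.5
    dt: 0.25
trainer:
  kind: bio_force
  epochs: 15
  early_stopping:
    patience: 3
    min_delta: 0.0001
output:
  directory: runs/recording_bio
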