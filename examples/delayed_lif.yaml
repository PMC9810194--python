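# Delayed-response task in a LIF network (desk-scale): echo a 0.1 s input
# boxcar 50 ms after it ends.
seed: 1
task:
  name: delayed_response
  params:
    duration_s: 1.0
    dt: 0.0001
    pulse_width_s: 0.1
    delay_s: 0.05
layer:
  kind: lif
  n_neurons: 200
  gain: 10.0
  params:
    feedback_scale: 10.0
    dt: 0.0001
trainer:
  kind: spiking
  epochs: 5
  update_interval: 50
  warmup_steps: 1000
output:
  directory: runs/delayed_lif
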