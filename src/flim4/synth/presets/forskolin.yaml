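name: forskolin
description: >
  Browning stimulus (adenylate-cyclase activation); like epinephrine with a
  slightly stronger uncoupling shift.
amplitude_factors:
  mitochondria: [0.82, 1.0]
  cytoplasm: [1.163, 1.0]
  droplet: [1.0]
  background: [1.0]
fad_factor: 1.1
oxidative_activity: 1.6
expected_direction:
  MCR: down
  free_to_bound: flat
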