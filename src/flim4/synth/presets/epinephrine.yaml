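name: epinephrine
description: >
  Browning stimulus; UCP1 upregulation uncouples mitochondria (mild FCCP-like
  shift): small drop in mitochondrial free NADH, small rise in cytoplasmic
  free NADH, leaving the free-to-bound ratio flat while the MCR falls.
amplitude_factors:
  mitochondria: [0.86, 1.0]
  cytoplasm: [1.13, 1.0]
  droplet: [1.0]
  background: [1.0]
fad_factor: 1.1
oxidative_activity: 1.5
expected_direction:
  MCR: down
  free_to_bound: flat
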