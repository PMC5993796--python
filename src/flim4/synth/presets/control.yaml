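name: control
description: Untreated baseline; all amplitude factors unity.
amplitude_factors:
  mitochondria: [1.0, 1.0]
  cytoplasm: [1.0, 1.0]
  droplet: [1.0]
  background: [1.0]
fad_factor: 1.0
oxidative_activity: 1.0
expected_direction: {}
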