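name: two_dg
description: >
  2-deoxy-D-glucose blocks glycolysis; reduced ETC substrate turnover lets
  mitochondrial NADH accumulate relative to the cytoplasm.
amplitude_factors:
  mitochondria: [1.25, 1.25]
  cytoplasm: [1.0, 1.0]
  droplet: [1.0]
  background: [1.0]
fad_factor: 1.0
oxidative_activity: 0.8
expected_direction:
  MCR: up
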