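name: glucose
description: >
  Substrate saturation raises metabolic throughput in both compartments
  proportionally: component intensities rise while every intensity ratio
  (MCR, free-to-bound) stays flat.
amplitude_factors:
  mitochondria: [1.3, 1.3]
  cytoplasm: [1.3, 1.3]
  droplet: [1.0]
  background: [1.0]
fad_factor: 1.0
oxidative_activity: 1.0
expected_direction:
  MCR: flat
  free_to_bound: flat
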