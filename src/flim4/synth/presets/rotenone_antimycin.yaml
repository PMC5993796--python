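name: rotenone_antimycin
description: >
  Complex I/III inhibition maximizes mitochondrial NADH (oxidation to NAD+
  blocked) and prevents FADH2 oxidation to fluorescent FAD.
amplitude_factors:
  mitochondria: [2.0, 1.4]
  cytoplasm: [0.9, 1.0]
  droplet: [1.0]
  background: [1.0]
fad_factor: 0.5
oxidative_activity: 0.25
expected_direction:
  MCR: up
  free_to_bound: up
  redox: down
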