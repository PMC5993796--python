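name: oligomycin
description: >
  ATP-synthase inhibition blocks oxidative phosphorylation: mitochondrial
  NADH accumulates (free pool most strongly), cytoplasmic free NADH is drawn
  down by upregulated glycolysis, and FAD falls with ETC throughput.
amplitude_factors:
  mitochondria: [1.8, 1.3]
  cytoplasm: [0.9, 1.0]
  droplet: [1.0]
  background: [1.0]
fad_factor: 0.7
oxidative_activity: 0.45
expected_direction:
  MCR: up
  free_to_bound: up
  redox: down
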