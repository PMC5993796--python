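name: fccp
description: >
  Protonophore uncoupling accelerates respiration and depletes the
  mitochondrial NADH pool; cytoplasmic free NADH rises slightly with
  compensatory glycolysis.
amplitude_factors:
  mitochondria: [0.6, 0.6]
  cytoplasm: [1.05, 1.0]
  droplet: [1.0]
  background: [1.0]
fad_factor: 1.1
oxidative_activity: 1.8
expected_direction:
  MCR: down
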