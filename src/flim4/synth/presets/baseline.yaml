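# Ground-truth NADH decays per compartment.
#
# Mitochondria carry the short free/bound lifetime pair (0.5, 2.3) ns and the
# cytoplasm the longer pair (1.0, 3.7) ns.  Amplitudes are photon-rate
# weights normalized so each in-cell compartment has unit steady-state
# brightness (sum of alpha_i * tau_i = 1); droplets and background are set to
# 4% brightness so they fall below the 100-photon QC floor at the default
# 500 photons/pixel budget.
#
# The within-compartment amplitude splits (mitochondria 75/25, cytoplasm
# 65/35 favoring the short, free component) are placeholders: no published
# per-compartment free/bound amplitude ratios exist for adipocytes.  The
# mitochondrial pool is given the larger free fraction so the two
# compartments have distinct amplitude ratios (3.0 vs 1.86), which is what
# makes the free-to-bound ratio respond to intensity shifts between them.
compartments:
  mitochondria:
    lifetimes_ns: [0.5, 2.3]
    amplitudes: [0.78947, 0.26316]   # split 75/25, brightness 1.0
  cytoplasm:
    lifetimes_ns: [1.0, 3.7]
    amplitudes: [0.33419, 0.17995]   # split 65/35, brightness 1.0
  droplet:
    lifetimes_ns: [7.5]              # long mono-exponential lipid signal
    amplitudes: [0.00533]            # brightness 0.04
  background:
    lifetimes_ns: [1.0]
    amplitudes: [0.04]               # dark/stray counts, brightness 0.04
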