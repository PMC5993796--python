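# Methods

`flim4` re-creates, on fully synthetic data with known ground truth, the
four-component NADH fluorescence-lifetime analysis of adipocyte metabolism:
per-pixel bi-exponential TCSPC fitting under spatial binning, decomposition
of the image-wide lifetime distribution into four Gaussian pools, the
mitochondrial–cytoplasmic ratio (MCR) and companion optical ratios, phasor
analysis, and pharmacological stress-test comparisons. This note documents
the models, the parameters that matter, the numerical choices, and the
limits of what the synthetic results demonstrate.

## Forward model (simulator)

**Decay model.** Each cellular compartment carries a multi-exponential NADH
decay: mitochondria the (0.5, 2.3) ns free/bound pair, cytoplasm the
(1.0, 3.7) ns pair, lipid droplets a dim 7.5 ns mono-exponential, and the
background a dim nuisance decay. Amplitudes are photon-rate weights, so the
steady-state intensity of component *i* is αᵢτᵢ; the in-cell compartments
are normalized to unit brightness (Σαᵢτᵢ = 1), and droplets/background to
0.04, which puts them below the 100-photon QC floor at the default budget.
The within-compartment amplitude splits (75/25 mitochondria, 65/35
cytoplasm, favoring the short/free component) are placeholders — no
published per-compartment free/bound ratios exist for adipocytes — and are
flagged as such in the baseline config. The splits differ between
compartments on purpose: the intensity-weighted free-to-bound ratio only
responds to intensity shifts between compartments if their α₁/α₂ differ.

**Timing.** 80 MHz repetition (12.5 ns period), 256 time channels of
~48.8 ps. Re-excitation every period makes the recorded decay the periodic
sum of all previous pulses; the 3.7 ns component visibly wraps. All
convolution with the instrument response is therefore circular over the
period. A convenient exact identity follows: the periodic sum of
`exp(-t/τ)` integrates to ατ over one period, so channel sums equal
steady-state intensities and photon-budget bookkeeping is exact. The IRF is
a Gaussian of 0.25 ns FWHM peaking 2.0 ns into the window (no shape was
available; a narrow Gaussian is the standard approximation).

**Geometry.** Frames are 256×256 px over 105×105 µm (0.41 µm pitch);
analyses here run on 64×64 tiles at the same pitch so twenty-image batches
complete at desk scale — the pitch, not the frame size, controls every
partial-volume effect. Cells are round footprints with elliptical
lipid-droplet voids (25% of the footprint by default). Mitochondria are
tubules of 1.2 µm diameter (2–3 px) and 2–6 µm length, laid down as
*oriented ribbons*: pairs of abutting parallel tubules chained end-to-end
along a per-cell direction, with ~6 µm across-ribbon period (jittered
±15% per cell), 85% chain fill, and a 0.5 px Gaussian blur on the
mitochondria indicator for sub-resolution/motion mixing. The ribbon layout is the one
structural choice not pinned down by published observations, and it is
load-bearing: mitochondrial domains ~2.5 µm wide separated by ~3 µm
channels mean a 3×3 binning footprint (1.2 µm) samples essentially pure
decays of either compartment, while a 9×9 footprint (3.7 µm) always spans
domain and channel together. That is precisely the spatial regime in which
low binning resolves four lifetime pools and high binning collapses them
to two. Scattered single tubules (no pure 3×3 windows) and large compact
patches (pure 9×9 windows) both destroy one side of this result; only the
quasi-one-dimensional domain structure supports both.

**Noise.** Photon counts are Poisson per channel around the expected decay;
500 photons/pixel in-cell by default (the 100–1000 range typical of live
NADH imaging). FAD images are Poisson, mitochondria-weighted, and scaled by
each scenario's FAD factor; the stain channel is mito-fraction times a gain
plus Gaussian read noise.

**Scenarios.** Pharmacological presets (YAML data files) rescale
compartment amplitudes only — concentration/quantum-yield shifts, never
lifetime shifts — and declare the expected direction of each optical
metric together with a scalar oxidative-activity proxy standing in for
flux-analyzer respirometry (which is not modeled). ETC inhibition
(oligomycin, rotenone/antimycin) raises mitochondrial NADH with the free
pool rising more than the bound pool and dims FAD; uncoupling (FCCP) and
browning stimuli (epinephrine, forskolin) deplete it; glucose scales both
compartments proportionally so every intensity ratio stays flat while all
component intensities rise. The browning factors were chosen so the MCR
falls 5–10% while the intensity-weighted free-to-bound ratio stays inside
a ±10% equivalence band, using the frozen geometry's ~0.35 mitochondrial
intensity share in the flatness arithmetic.

## Per-pixel fitting

The measured decay is modeled as `m(t) = Σᵢ Aᵢ S(t; τᵢ)`, where `S` is the
unit-sum profile of a wrapped exponential circularly convolved with the
normalized IRF; `Aᵢ` is then directly the component's photon total, and
fractional intensities are `Aᵢ/ΣAⱼ`. Fitting uses variable projection: the
amplitudes are solved linearly at every step, leaving only the lifetimes
(log-parameterized, bounded to [0.05, 10] ns) as nonlinear parameters.
`fit_image` drives a batched, damped Gauss–Newton over all foreground
pixels simultaneously (Kaufman approximation for the Jacobian, per-pixel
damping and convergence, FFT-based reconvolution); `fit_pixel` is the
single-decay reference route through `scipy.optimize.least_squares`, and
the two agree to numerical tolerance.

Numerical choices that matter:

* **Weights.** Counting (Neyman) weights σ² = max(counts, 1) bias TCSPC
  lifetimes several percent low (downward-fluctuating channels are
  over-weighted), so after a first pass the weights are refreshed from the
  fitted model (Pearson weighting; two IRLS passes, after which estimates
  are unbiased at binned budgets: 0.50/2.30 and 0.99/3.73 ns recovered on
  pure-compartment ensembles at 4500 photons).
* **No offset by default.** Under periodic re-excitation the wrapped tail
  of the 3.7 ns component is nearly flat, so a free constant is close to
  collinear with it; co-fitting an offset inflated the long-lifetime
  variance threefold and biased it low. Dark counts are negligible in the
  simulation and in well-shielded detectors; `fit_offset=True` restores
  the term.
* **Reported χ².** Pearson convention, σ² = fitted model (floored at 0.1
  counts), over channels − parameters degrees of freedom. Its expectation
  is 1 at every count level, where the Neyman convention collapses to ~0.5
  at the QC operating point. Note the irreducible spread: at the *true*
  model the reduced χ² over 256 channels has a standard deviation of
  ~0.15 at 500 photons and ~0.11 at 4500, so the conventional 0.9–1.3
  acceptance window retains at most ~54% and ~88% of perfectly-fit pixels
  respectively; the shipped QC keeps the bulk of binned in-cell pixels and
  the commercial-software window should be interpreted against its own
  (unknown) χ² convention.
* **Initialization.** Long lifetime from a log-linear tail slope, short
  fixed at 0.5 ns; lifetimes sorted ascending afterwards with their
  amplitudes carried along.
* **Binning.** Sliding k×k neighborhood *sums* with partial windows at the
  edges (no mirror padding); edge pixels are photon-poor and the QC floor
  discounts them naturally. The droplet rim after binning genuinely mixes
  in cytoplasm photons from neighboring pixels, so rim pixels may pass QC
  while droplet interiors never do.

## Lifetime pools and metrics

The intensity-weighted lifetime histogram (0.05 ns bins over 0–6 ns)
receives, from each QC pixel, its two lifetimes weighted by photons ×
fractional intensity, so its total equals the total QC intensity exactly.
The four-Gaussian decomposition is plain (unweighted) nonlinear least
squares, multi-started from smoothed-histogram maxima, weight quantiles,
and negative-curvature (shoulder) seeds, keeping the lowest-residual
solution; counting-weighted fits were tried and rejected because they
up-weight the low-count partial-volume pedestal between peaks and drag the
centers off the modes.

The number of *distinct* lifetime components is the mode count of the
smoothed histogram (0.1 ns smoothing, 8% prominence), clipped to the
candidate range {2, 3, 4}: a peak must rise visibly above the band it sits
on. An information-criterion route (BIC over candidate fits, reduced to
the resolved mode count of the winner) is available but not default — with
millions of photons per histogram any extra Gaussian wins the BIC by
slicing an asymmetric hump, and the slices' composite has knife-edge
spurious modes.

Pixels are classified into lifetime pairs by Mahalanobis distance (using
the component widths) to (C1, C3) vs (C2, C4); exact ties are left
unclassified. Component intensities assign each pixel's two contributions
to the nearest component center, conserving total intensity exactly; the
MCR is (C1+C3)/(C2+C4) of those totals, with the Gaussian-area version
available as a cross-check. The free-to-bound ratio is the
intensity-weighted mean per-pixel α₁/α₂; the redox ratio is pixel-wise
FAD/(FAD+NADH).

**Known residual.** At the native pitch the 3×3 footprint (1.2 µm) is
comparable to the tubule diameter, so 20–30% of mitochondria-dominated
windows carry 10–30% cytoplasm signal. The resulting asymmetric shoulders
bias the fitted Gaussian centers: on twenty-image batches the pools are
recovered at ≈ 0.54, 0.96, 2.43, 3.56 ns against truths 0.5, 1.0, 2.3,
3.7 — C1, C2, C4 within ±0.1/±0.15 ns, but C3 sits ~0.13 ns high. The bias
is structural (partial-volume mixing at the stated pixel pitch and
organelle size), not an estimator defect: pure-compartment ensembles are
recovered without bias, and no analysis variant explored (weighting
conventions, seeding, QC) removes it.

## Phasor analysis

First-harmonic cosine/sine moments at channel centers over one period;
because the decays are periodic, the discrete phasor of a mono-exponential
matches the continuous closed form `g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²)` to
well below 1%. Calibration divides the ideal phasor of a reference
lifetime (fluorescein, 4.0 ns, config-overridable) by the measured mean
phasor of a uniform reference cube; the `calibrated` flag guards against
double application. Lifetime extraction fits the first principal axis
(total least squares) through the masked cloud and intersects it with the
universal semicircle in closed form; complex roots raise a
no-intersection error carrying the line-to-circle distance rather than
silently projecting (projection is available behind a flag). The phasor
photon floor reuses the QC threshold (>100) for comparability with
fitting.

## Stress tests

Each condition simulates a batch of independent frames and runs the full
analysis. Comparisons are **paired** by default: every scenario reuses the
control's geometry seed stream (the repeated-measures design of an
injection series, where the same cultures are followed across conditions)
and a paired t-test is applied; image-to-image geometry variance in the
MCR (~15% across random cell layouts) otherwise swamps the smaller
browning effects at n = 20. Welch's unequal-variance t-test on independent
streams is available via `paired=False`. The four Gaussian pools are
fitted once to a pooled control histogram and held fixed across
conditions — they are molecular species whose positions do not move under
pharmacology — so per-condition analysis measures pool intensities only.

Directional expectations flag `match` when the effect is significant
(α = 0.05) with the right sign. "Flat" expectations are equivalence
claims and are tested TOST-style: the 90% CI of the relative difference
must lie inside a ±10% band. A plain failure-to-reject criterion is too
strict once comparisons are paired: brightening every pixel (glucose)
admits ~5% more mixed pixels through the fixed 100-photon QC floor and
shifts the measured MCR by ~−5% at unchanged ground truth — a real
sub-margin artifact of the method that an unpaired n = 40 comparison on
real data could never resolve.

The oxidative trend check regresses each scenario's declared
oxidative-activity proxy on 1/MCR (ordinary least squares plus Pearson
correlation); on the shipped presets the correlation is strongly positive,
mirroring the inverse MCR–respiration relationship the analysis is built
around.

## Problem sizes and determinism

Default batches are twenty 64×64 tiles per condition at 500 photons/pixel;
the full-frame 256×256 default remains available everywhere
(`AcquisitionMeta()`), and all footprint-dependent behavior is set by the
pixel pitch, which is identical. Every stochastic operation takes an
explicit seed; batch seeds derive deterministically from a base seed, and
identical seeds give bit-identical cubes and reports.

## What passing tests do and do not show

The generator emulates the statistical structure the analysis assumes —
compartment decay mixtures, Poisson counting noise, partial-volume mixing,
droplet voids, scenario-scaled amplitudes — with known ground truth, so
the tests demonstrate that the pipeline recovers what it claims to recover
under those assumptions. They do not validate the biology: real NADH
decays are not exactly bi-exponential per compartment, real mitochondrial
networks are not ribbons with a fixed period, detector afterpulsing,
dead-time, and spectral bleed-through are absent, and the
oxidative-activity proxies are declared numbers, not respirometry. The
direction table shows internal consistency of the scenario definitions
with the analysis, not a prediction of pharmacology.
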