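# flim4 — four-component NADH FLIM analysis of adipocyte metabolism

Label-free metabolic imaging measures the autofluorescence decay of NADH:
free NADH decays fast, enzyme-bound NADH slowly, and their balance tracks
cellular metabolism. In adipocytes the picture is richer — four lifetime
pools exist, a free/bound pair per compartment: mitochondria at
(0.5, 2.3) ns and cytoplasm at (1.0, 3.7) ns. Because a bi-exponential fit
of any single pixel returns one pair, the four pools only emerge across
pixels, and only when spatial binning is low enough that a fitted decay
stays inside one compartment. Mapping the pools to compartments yields the
**mitochondrial–cytoplasmic ratio**

```
MCR = (C1 + C3) / (C2 + C4)
```

of component fluorescence intensities — a metabolic readout that responds
to electron-transport-chain perturbations more strongly than the classic
free-to-bound (α₁/α₂) or redox (FAD/(FAD+NADH)) ratios, and inversely
tracks oxygen consumption.

`flim4` implements the full analysis and, because no public adipocyte FLIM
data exist, a synthetic TCSPC generator with known ground truth so every
stage is verifiable:

* `flim4.synth` — adipocyte geometry (cells, lipid-droplet voids, tubular
  mitochondrial ribbons), ground-truth compartment decays, pharmacological
  scenario presets, periodic IRF convolution, Poisson photon sampling,
  paired FAD/stain channels;
* `flim4.decay` — spatial binning, batched per-pixel bi-exponential
  reconvolution fitting (variable projection), χ²/photon QC, adaptive
  foreground;
* `flim4.components` — intensity-weighted lifetime histograms, Gaussian
  pool decomposition, distinct-component counting, pair classification,
  MCR / free-to-bound / redox;
* `flim4.phasor` — fit-free phasor transform, fluorescein calibration,
  universal-semicircle lifetime extraction by principal-axis line fitting;
* `flim4.segmentation` — lifetime-pair vs stain compartment masks, 2-D
  Pearson correlation (`corr2`);
* `flim4.pipeline` — batch orchestration, stress-test direction tables,
  the oxidative-activity vs 1/MCR trend.

The numbered scripts under `analysis/` walk through the study: simulate a
frame, reproduce the binning-dependent component collapse, validate the
lifetime localization against the stain channel, and run the
pharmacological stress tests. A thin CLI (`flim4 simulate|fit|components|
phasor|stress-test`) wraps the same library.

## Worked example

```
$ python analysis/02_binning_and_components.py
12 frames, 500 photons/pixel, native 0.41 µm pitch
mean Gaussian peak centers at 3×3 binning (1.5 µm² footprint):
  b1: 0.544 ns (generator truth 0.5 ns)
  b2: 1.058 ns (generator truth 1.0 ns)
  b3: 2.444 ns (generator truth 2.3 ns)
  b4: 3.560 ns (generator truth 3.7 ns)
distinct components at 3×3 (1.5 µm²): 4
distinct components at 9×9 (14 µm²): 2
```

Reading the output: at a 1.5 µm² binning footprint the fitted per-pixel
lifetime pairs cluster into four distinct pools near the ground-truth
compartment lifetimes (the long-mitochondrial pool sits ~0.1 ns high from
partial-volume mixing — see `docs/methods.md`); rebinning the *same*
photon data at 14 µm² blends mitochondrial and cytoplasmic decays inside
every fitted pixel and only two apparent lifetimes survive. That collapse
is why high-binning studies report two NADH lifetimes while
high-resolution analysis reveals four.

`python analysis/04_stress_tests.py` then reproduces the pharmacology
direction table (oligomycin: MCR and free-to-bound up, redox down; FCCP
and browning: MCR down; glucose: all ratios flat while component
intensities rise; 2-DG and rotenone/antimycin: MCR up) and the positive
correlation between each condition's oxidative-activity proxy and 1/MCR.

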