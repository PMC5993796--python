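"""The central binning result: four lifetime pools at 3x3, two at 9x9.

Simulates a batch of default adipocyte frames, fits every pixel at both
binning levels, decomposes the intensity-weighted lifetime histograms into
Gaussian pools, and writes the per-image peak centers and the pooled
histograms under results/.  The printed table is the desk-scale analogue
of the four-component analysis: the recovered centers estimate the
mitochondrial (0.5, 2.3 ns) and cytoplasmic (1.0, 3.7 ns) NADH pools, and
the selected peak count collapses from 4 to 2 when the binning footprint
grows past the mitochondrial domain size.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flim4.components import (
    LifetimeHistogram,
    fit_gaussians,
    lifetime_histogram,
    select_peak_count,
)
from flim4.decay import fit_image, format_footprint
from flim4.pipeline import RunConfig, simulate_scenario_image
from flim4.synth import load_scenario

N_IMAGES = 12
OUT = Path("results")


def main():
    config = RunConfig(tile=64, base_seed=1)
    scenario = load_scenario("control")
    rows = []
    pooled = {3: None, 9: None}
    bin_centers = None
    for seed in config.image_seeds(N_IMAGES, offset=901):
        cube, *_ = simulate_scenario_image(config, scenario, seed)
        for k in (3, 9):
            hist = lifetime_histogram(fit_image(cube, k=k))
            pooled[k] = hist.weights if pooled[k] is None else pooled[k] + hist.weights
            bin_centers = hist.bin_centers
            if k == 3:
                comps = fit_gaussians(hist, 4)
                rows.append(
                    dict(zip(["b1", "b2", "b3", "b4"], comps.centers))
                    | {"seed": int(seed)}
                )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "component_centers.csv", index=False)
    counts = {}
    for k in (3, 9):
        hist = LifetimeHistogram(bin_centers=bin_centers, weights=pooled[k])
        counts[k] = select_peak_count(hist)
        pd.DataFrame(
            {"lifetime_ns": bin_centers, "intensity": pooled[k]}
        ).to_csv(OUT / f"pooled_histogram_k{k}.csv", index=False)

    meta = config.meta()
    means = frame[["b1", "b2", "b3", "b4"]].mean()
    print(f"{N_IMAGES} frames, 500 photons/pixel, native 0.41 µm pitch")
    print("mean Gaussian peak centers at 3×3 binning "
          f"({format_footprint(3, meta)[1]} footprint):")
    for name, truth in zip(["b1", "b2", "b3", "b4"], [0.5, 1.0, 2.3, 3.7]):
        print(f"  {name}: {means[name]:.3f} ns (generator truth {truth} ns)")
    print(f"distinct components at 3×3 ({format_footprint(3, meta)[1]}): {counts[3]}")
    print(f"distinct components at 9×9 ({format_footprint(9, meta)[1]}): {counts[9]}")


if __name__ == "__main__":
    main()
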