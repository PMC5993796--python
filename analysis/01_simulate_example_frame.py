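"""Simulate one default adipocyte FLIM frame and write it to disk.

Produces the raw material every later step consumes: a decay cube
(TIFF + JSON sidecar), the ground-truth label image, and the paired FAD /
mitochondrial-stain channels, under results/frame/.
"""

from pathlib import Path

import numpy as np

from flim4 import io
from flim4.pipeline import RunConfig, simulate_scenario_image
from flim4.synth import load_scenario

OUT = Path("results/frame")


def main():
    config = RunConfig(tile=64, base_seed=1)
    cube, geom, fad, stain = simulate_scenario_image(
        config, load_scenario("control"), seed=1
    )
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_cube(OUT / "cube", cube)
    io.write_image(OUT / "labels", geom.label_image)
    io.write_image(OUT / "mito_fraction", geom.mito_fraction)
    io.write_image(OUT / "fad", fad)
    io.write_image(OUT / "stain", stain)
    cell = geom.cell_mask
    print(f"frame: {cube.meta.n_x}x{cube.meta.n_y} px, "
          f"{cube.counts.sum():.0f} photons total")
    print(f"cell area {cell.mean():.0%} of frame, "
          f"mitochondrial coverage {geom.mito_fraction[cell].mean():.0%} of cell")
    print(f"wrote cube + channels to {OUT}/")


if __name__ == "__main__":
    main()
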