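"""Synthetic adipocyte geometry: round cells, lipid-droplet voids, tubules.

Mitochondria are drawn as randomly oriented tubules ~1 um in diameter and
2-6 um long (2-3 pixels wide at the native 0.41 um pitch), embedded in the
cytoplasm of round cell footprints that contain elliptical lipid-droplet
voids.  ``mito_fraction`` is the (optionally blurred) mitochondria
indicator; the blur emulates sub-resolution boundary mixing and the motion
blur of live mitochondria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..meta import AcquisitionMeta

__all__ = [
    "GeometryLabels",
    "make_geometry",
    "BACKGROUND",
    "CYTOPLASM",
    "MITOCHONDRIA",
    "DROPLET",
    "LABEL_NAMES",
]

BACKGROUND, CYTOPLASM, MITOCHONDRIA, DROPLET = 0, 1, 2, 3
LABEL_NAMES = {
    BACKGROUND: "background",
    CYTOPLASM: "cytoplasm",
    MITOCHONDRIA: "mitochondria",
    DROPLET: "droplet",
}


@dataclass
class GeometryLabels:
    """Per-pixel compartment labels and fractional mitochondrial weight."""

    label_image: np.ndarray
    mito_fraction: np.ndarray

    def __post_init__(self):
        if self.label_image.shape != self.mito_fraction.shape:
            raise ValueError("label_image and mito_fraction shapes differ")
        if not np.isin(self.label_image, list(LABEL_NAMES)).all():
            raise ValueError("unknown label codes in label_image")
        if self.mito_fraction.min() < 0 or self.mito_fraction.max() > 1:
            raise ValueError("mito_fraction must lie in [0, 1]")
        if np.any(self.mito_fraction[self.label_image == DROPLET] != 0):
            raise ValueError("droplet pixels must have mito_fraction == 0")

    @property
    def cell_mask(self) -> np.ndarray:
        """Pixels inside a cell and not inside a droplet void."""
        return np.isin(self.label_image, (CYTOPLASM, MITOCHONDRIA))


def _segment_mask(shape, p0, p1, radius_px):
    """Boolean mask of pixels within ``radius_px`` of the segment p0-p1."""
    y0, x0 = p0
    y1, x1 = p1
    pad = int(math.ceil(radius_px)) + 1
    ylo = max(0, int(min(y0, y1)) - pad)
    yhi = min(shape[0], int(max(y0, y1)) + pad + 1)
    xlo = max(0, int(min(x0, x1)) - pad)
    xhi = min(shape[1], int(max(x0, x1)) + pad + 1)
    if ylo >= yhi or xlo >= xhi:
        return None, None
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    dy, dx = y1 - y0, x1 - x0
    seg2 = dy * dy + dx * dx
    if seg2 == 0:
        t = np.zeros_like(yy, dtype=float)
    else:
        t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / seg2, 0.0, 1.0)
    dist2 = (yy - (y0 + t * dy)) ** 2 + (xx - (x0 + t * dx)) ** 2
    return (slice(ylo, yhi), slice(xlo, xhi)), dist2 <= radius_px**2


def make_geometry(
    meta: AcquisitionMeta,
    n_cells: int | None = None,
    n_mito_per_cell: int | None = None,
    droplet_fraction: float = 0.25,
    mito_diameter_um: float = 1.2,
    mito_length_range_um: tuple[float, float] = (2.0, 6.0),
    blur_sigma_px: float = 0.5,
    tubules_per_bundle: int = 2,
    bundle_spacing_um: float = 6.0,
    bundle_stagger_um: float = 0.1,
    ribbon_fill: float = 0.85,
    seed: int = 0,
) -> GeometryLabels:
    """Generate a random adipocyte field.

    Parameters
    ----------
    n_cells
        Number of round cell footprints; default scales with the field of
        view (one cell per ~52 x 52 um patch, minimum 1).
    n_mito_per_cell
        Tubules per cell; default targets ~30% mitochondrial coverage of the
        (droplet-free) cytoplasm given the mean tubule area.
    droplet_fraction
        Target fraction of each cell's footprint occupied by lipid-droplet
        voids; must be < 1.
    blur_sigma_px
        Gaussian blur (pixels) applied to the binary tubule mask to form
        ``mito_fraction``; 0 keeps the indicator binary.
    """
    if not 0 <= droplet_fraction < 1:
        raise ValueError("droplet_fraction must lie in [0, 1)")
    if mito_diameter_um <= 0:
        raise ValueError("mito_diameter_um must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = meta.n_y, meta.n_x
    pitch = meta.pixel_pitch_um
    if n_cells is None:
        n_cells = max(1, round((meta.fov_um / 52.5) ** 2))
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")

    labels = np.full((ny, nx), BACKGROUND, dtype=np.uint8)
    yy, xx = np.mgrid[0:ny, 0:nx]

    # round cell footprints on a jittered grid
    grid = math.ceil(math.sqrt(n_cells))
    spacing = min(ny, nx) / grid
    cell_masks = []
    placed = 0
    for gy in range(grid):
        for gx in range(grid):
            if placed >= n_cells:
                break
            cy = (gy + 0.5) * spacing + rng.uniform(-0.08, 0.08) * spacing
            cx = (gx + 0.5) * spacing + rng.uniform(-0.08, 0.08) * spacing
            radius = 0.42 * spacing * rng.uniform(0.9, 1.1)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            labels[mask] = CYTOPLASM
            cell_masks.append((mask, cy, cx, radius))
            placed += 1

    # elliptical droplet voids inside each cell
    for mask, cy, cx, radius in cell_masks:
        cell_area = int(mask.sum())
        target = droplet_fraction * cell_area
        droplet_area = 0
        for _ in range(300):
            if droplet_area >= target:
                break
            a_um = rng.uniform(1.5, max(1.6, 0.35 * radius * pitch))
            b_um = a_um * rng.uniform(0.6, 1.0)
            a_px, b_px = a_um / pitch, b_um / pitch
            theta = rng.uniform(0, np.pi)
            r = rng.uniform(0, 0.8) * radius
            phi = rng.uniform(0, 2 * np.pi)
            dy0, dx0 = cy + r * np.sin(phi), cx + r * np.cos(phi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (yy - dy0) * ct + (xx - dx0) * st
            v = -(yy - dy0) * st + (xx - dx0) * ct
            ell = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
            ell &= mask
            new = ell & (labels == CYTOPLASM)
            labels[new] = DROPLET
            droplet_area += int(new.sum())

    # Tubular mitochondria confined to the cytoplasm.  Tubules are laid
    # down as oriented ribbons: pairs of abutting parallel tubules chained
    # end-to-end along a shared per-cell direction, with ribbons repeating
    # across that direction every ~bundle_spacing_um.  The cytoplasm is thus
    # striped by mitochondrial domains ~2 um wide separated by ~3 um
    # mitochondria-free channels.  This is the spatial structure the
    # four-component analysis rests on: a 3x3 binning footprint (1.2 um)
    # fits inside a ribbon or inside a channel and samples essentially pure
    # decays of either compartment, while a 9x9 footprint (3.7 um) always
    # spans ribbon and channel together and only ever sees blended
    # mixtures.
    mito_mask = np.zeros((ny, nx), dtype=bool)
    radius_px = 0.5 * mito_diameter_um / pitch
    lo_um, hi_um = mito_length_range_um
    across_px = bundle_spacing_um / pitch
    along_px = 2.5 / pitch
    for mask, cy, cx, radius in cell_masks:
        cyto = mask & (labels == CYTOPLASM)
        if not cyto.any():
            continue
        theta = rng.uniform(0, np.pi)  # ribbon direction for this cell
        ct, st = np.cos(theta), np.sin(theta)
        # cells differ in mitochondrial density: per-cell spacing jitter
        cell_across_px = across_px * rng.uniform(0.85, 1.15)
        n_along = int(np.ceil(2 * radius / along_px)) + 2
        n_across = int(np.ceil(2 * radius / cell_across_px)) + 2
        anchors = []
        for iv in range(n_across + 1):
            v = (iv - n_across / 2 + rng.uniform(-0.1, 0.1)) * cell_across_px
            for iu in range(n_along + 1):
                u = (iu - n_along / 2 + rng.uniform(-0.15, 0.15)) * along_px
                ay = cy + u * st + v * ct
                ax = cx + u * ct - v * st
                iy_px, ix_px = int(round(ay)), int(round(ax))
                if 0 <= iy_px < ny and 0 <= ix_px < nx and mask[iy_px, ix_px]:
                    # thin the chains: ribbons are dashed (fragmented
                    # networks), keeping mitochondrial coverage moderate
                    if rng.uniform() < ribbon_fill:
                        anchors.append((ay, ax))
        if n_mito_per_cell is not None:
            n_bundles = max(0, round(n_mito_per_cell / tubules_per_bundle))
            order = rng.permutation(len(anchors))
            anchors = [anchors[i] for i in order[:n_bundles]]
        for ay, ax in anchors:
            t_dir = theta + rng.normal(0.0, np.deg2rad(3.0))
            tc, ts = np.cos(t_dir), np.sin(t_dir)
            # perpendicular offsets of ~one diameter pack tubules side by side
            for j in range(tubules_per_bundle):
                off = (j - (tubules_per_bundle - 1) / 2.0) * 2.0 * radius_px
                off *= rng.uniform(0.8, 1.0)  # abutting, no sub-pixel gaps
                shift = (
                    rng.uniform(-bundle_stagger_um, bundle_stagger_um) / pitch
                )  # longitudinal stagger
                length_px = rng.uniform(lo_um, hi_um) / pitch
                y0 = ay - off * tc + (shift - length_px / 2) * ts
                x0 = ax + off * ts + (shift - length_px / 2) * tc
                y1 = y0 + length_px * ts
                x1 = x0 + length_px * tc
                window, seg = _segment_mask(
                    (ny, nx), (y0, x0), (y1, x1), radius_px
                )
                if window is None:
                    continue
                tubule = np.zeros((ny, nx), dtype=bool)
                tubule[window] = seg
                tubule &= cyto
                mito_mask |= tubule

    labels[mito_mask] = MITOCHONDRIA
    if blur_sigma_px > 0:
        mito_fraction = gaussian_filter(mito_mask.astype(float), blur_sigma_px)
        mito_fraction = np.clip(mito_fraction, 0.0, 1.0)
    else:
        mito_fraction = mito_mask.astype(float)
    mito_fraction[labels == DROPLET] = 0.0
    mito_fraction[labels == BACKGROUND] = 0.0
    return GeometryLabels(label_image=labels, mito_fraction=mito_fraction)
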