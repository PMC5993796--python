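"""Compartment masks from lifetime pairs or stains, and 2-D correlation.

The lifetime-pair classification provides a label-free segmentation of
mitochondrial vs cytoplasmic NADH; a mitochondrial-stain image provides the
conventional one.  The two are compared with the 2-D Pearson correlation
(MATLAB's corr2 convention: all pixels pooled into a single sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .components import PAIR_CYTO, PAIR_MITO
from .decay import adaptive_foreground

__all__ = ["CompartmentMask", "masks_from_pairs", "mask_from_stain", "corr2"]


@dataclass
class CompartmentMask:
    """Disjoint mitochondrial / cytoplasmic boolean masks."""

    mito_mask: np.ndarray
    cyto_mask: np.ndarray
    source: str

    def __post_init__(self):
        if self.mito_mask.shape != self.cyto_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.mito_mask & self.cyto_mask):
            raise ValueError("compartment masks must be disjoint")
        if self.source not in ("lifetime_pairs", "stain", "ground_truth"):
            raise ValueError(f"unknown mask source '{self.source}'")


def masks_from_pairs(pair_labels: np.ndarray) -> CompartmentMask:
    """Convert a pair-label image into compartment masks.

    Mitochondrial = pixels classified as the (C1, C3) pair; cytoplasmic =
    (C2, C4); unclassified pixels belong to neither mask.
    """
    return CompartmentMask(
        mito_mask=pair_labels == PAIR_MITO,
        cyto_mask=pair_labels == PAIR_CYTO,
        source="lifetime_pairs",
    )


def mask_from_stain(
    stain_image: np.ndarray,
    foreground: np.ndarray | None = None,
    block_size: int = 15,
    sensitivity: float = 1.0,
    floor_fraction: float = 0.3,
) -> CompartmentMask:
    """Threshold a mitochondrial-stain image into compartment masks.

    The adaptive intensity threshold (local mean x ``sensitivity`` plus a
    global floor) marks stained pixels as mitochondrial; the cytoplasm is
    the remaining foreground.  A flat stain yields a degenerate (empty or
    full) mitochondrial mask.
    """
    stain = np.asarray(stain_image, dtype=float)
    mito = adaptive_foreground(
        stain,
        block_size=block_size,
        sensitivity=sensitivity,
        floor_fraction=floor_fraction,
    )
    if foreground is None:
        foreground = np.ones_like(mito, dtype=bool)
    mito = mito & foreground
    return CompartmentMask(
        mito_mask=mito, cyto_mask=foreground & ~mito, source="stain"
    )


def corr2(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """2-D Pearson correlation of two images treated as one pooled sample.

    ``corr2(A, B) = sum (A - mean A)(B - mean B) / sqrt(sum (A - mean A)^2
    sum (B - mean B)^2)``.  Raises for constant images (the correlation is
    undefined) rather than returning NaN.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        raise ValueError("corr2 undefined for a constant image")
    return float((da * db).sum() / denom)
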