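"""File formats: decay cubes as multi-page TIFF + JSON sidecar, result tables.

A decay cube is stored as a multi-page grayscale TIFF with one page per
time channel (16-bit counts) next to a ``<stem>.json`` sidecar holding the
acquisition metadata, the IRF curve, and any ground-truth annotations.
Fit images are written as a multi-plane 32-bit TIFF (alpha1, alpha2, tau1,
tau2, chi2, photons) plus a CSV summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .decay import FitImage
from .meta import IRF, AcquisitionMeta, DecayCube

__all__ = [
    "write_cube",
    "read_cube",
    "write_image",
    "read_image",
    "write_fit_image",
    "write_metrics_csv",
]


def write_cube(path: str | Path, cube: DecayCube) -> Path:
    """Write a decay cube as TIFF pages (one per channel) + JSON sidecar."""
    path = Path(path).with_suffix(".tif")
    counts = np.asarray(cube.counts)
    if np.issubdtype(counts.dtype, np.floating):
        pages = counts.astype(np.float32).transpose(2, 0, 1)
    else:
        if counts.max() > np.iinfo(np.uint16).max:
            raise ValueError("counts exceed 16-bit TIFF range")
        pages = counts.astype(np.uint16).transpose(2, 0, 1)
    tifffile.imwrite(path, pages)
    meta = cube.meta
    sidecar = {
        "meta": {
            "n_x": meta.n_x,
            "n_y": meta.n_y,
            "fov_um": meta.fov_um,
            "n_channels": meta.n_channels,
            "rep_rate_hz": meta.rep_rate_hz,
            "channel_width_ns": meta.channel_width_ns,
        },
        "irf": list(map(float, cube.irf.curve)),
        "truth": _jsonable(cube.truth),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_cube(path: str | Path) -> DecayCube:
    """Read a decay cube written by :func:`write_cube`."""
    path = Path(path).with_suffix(".tif")
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    meta = AcquisitionMeta(**sidecar["meta"])
    return DecayCube(
        counts=np.asarray(pages).transpose(1, 2, 0),
        meta=meta,
        irf=IRF(curve=np.asarray(sidecar["irf"])),
        truth=sidecar.get("truth", {}),
    )


def write_image(path: str | Path, image: np.ndarray) -> Path:
    """Write a single-plane intensity or mask image as TIFF."""
    path = Path(path).with_suffix(".tif")
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    tifffile.imwrite(path, arr.astype(np.float32) if arr.dtype.kind == "f" else arr)
    return path


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_fit_image(path: str | Path, fit: FitImage) -> Path:
    """Write fit-parameter planes as a multi-page 32-bit TIFF + CSV summary."""
    path = Path(path).with_suffix(".tif")
    planes = np.stack(
        [fit.alpha1, fit.alpha2, fit.tau1, fit.tau2, fit.chi2, fit.photons]
    ).astype(np.float32)
    tifffile.imwrite(path, planes)
    qc = fit.qc_mask
    summary = pd.DataFrame(
        {
            "n_foreground": [int(fit.foreground_mask.sum())],
            "n_qc": [int(qc.sum())],
            "tau1_median_ns": [float(np.nanmedian(fit.tau1[qc])) if qc.any() else np.nan],
            "tau2_median_ns": [float(np.nanmedian(fit.tau2[qc])) if qc.any() else np.nan],
            "chi2_mean": [float(np.nanmean(fit.chi2[qc])) if qc.any() else np.nan],
            "binning": [fit.binning],
        }
    )
    summary.to_csv(path.with_suffix(".csv"), index=False)
    return path


def write_metrics_csv(path: str | Path, rows: pd.DataFrame) -> Path:
    path = Path(path).with_suffix(".csv")
    rows.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
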