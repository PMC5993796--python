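"""Fit-free phasor representation of FLIM decay cubes.

Each pixel's decay I(t) maps to a point in the phasor plane through the
first-harmonic cosine and sine moments

    g = sum I(t) cos(wt) / sum I(t),    s = sum I(t) sin(wt) / sum I(t)

at the laser repetition angular frequency ``w = 2 pi f``.  Mono-exponential
decays fall on the universal semicircle ``(g - 1/2)^2 + s^2 = 1/4``; any
mixture lies inside it on the chord connecting its components, so a
two-lifetime population spreads along a line whose two semicircle
intersections are the component lifetimes.  A measured cube is calibrated
against a reference fluorophore of known lifetime (fluorescein, 4.0 ns) to
remove the IRF's rotation and demodulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .meta import DecayCube

__all__ = [
    "PhasorCloud",
    "PhasorCalibration",
    "PhasorLine",
    "NoIntersectionError",
    "phasor_transform",
    "calibrate",
    "semicircle_point",
    "point_to_tau",
    "fit_phasor_line",
    "conditioned_cloud",
]


class NoIntersectionError(ValueError):
    """The fitted line misses the universal semicircle."""

    def __init__(self, message, distance=None):
        super().__init__(message)
        self.distance = distance


@dataclass
class PhasorCloud:
    """Per-pixel phasor coordinates at one harmonic of the repetition rate."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray
    omega: float  # rad/ns
    harmonic: int = 1
    calibrated: bool = False

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        return self.g[self.mask], self.s[self.mask]


@dataclass(frozen=True)
class PhasorCalibration:
    """Complex correction mapping measured phasors onto ideal positions."""

    reference_tau: float
    correction: complex

    def apply(self, g: np.ndarray, s: np.ndarray):
        z = (g + 1j * s) * self.correction
        return z.real, z.imag


@dataclass
class PhasorLine:
    """Total-least-squares line through a phasor cloud.

    ``lifetimes`` are the two semicircle-intersection lifetimes (ns,
    sorted); ``residual_rms`` is the RMS perpendicular scatter about the
    line (the collinearity of the cloud).
    """

    centroid: tuple[float, float]
    direction: tuple[float, float]
    intersections: tuple[tuple[float, float], tuple[float, float]]
    lifetimes: tuple[float, float]
    residual_rms: float
    ill_conditioned: bool = False


def semicircle_point(tau_ns: float, omega: float) -> tuple[float, float]:
    """Ideal phasor of a mono-exponential lifetime (on the semicircle)."""
    if tau_ns <= 0:
        raise ValueError("tau must be positive")
    wt = omega * tau_ns
    d = 1.0 + wt * wt
    return 1.0 / d, wt / d


def point_to_tau(g: float, s: float, omega: float) -> float:
    """Invert the semicircle map: tau = s / (g * omega)."""
    if g <= 0:
        raise ValueError("lifetime undefined for g <= 0")
    return s / (g * omega)


def phasor_transform(
    cube: DecayCube,
    harmonic: int = 1,
    calibration: PhasorCalibration | None = None,
    min_photons: float = 100.0,
) -> PhasorCloud:
    """Per-pixel discrete cosine/sine moments of the decay cube.

    Pixels whose total intensity is at or below ``min_photons`` (the same
    floor as the fitting QC) are masked out, not set to NaN.  If a
    calibration is supplied the phasors are complex-rotated/scaled by its
    correction and the cloud is flagged calibrated.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    meta = cube.meta
    omega = 2.0 * np.pi * harmonic / meta.period_ns  # rad/ns
    t = meta.times_ns
    counts = np.asarray(cube.counts, dtype=float)
    total = counts.sum(axis=-1)
    mask = total > min_photons
    safe_total = np.where(total > 0, total, 1.0)
    g = (counts * np.cos(omega * t)).sum(axis=-1) / safe_total
    s = (counts * np.sin(omega * t)).sum(axis=-1) / safe_total
    g = np.where(total > 0, g, 0.0)
    s = np.where(total > 0, s, 0.0)
    calibrated = False
    if calibration is not None:
        g, s = calibration.apply(g, s)
        calibrated = True
    return PhasorCloud(
        g=g,
        s=s,
        intensity=total,
        mask=mask,
        omega=omega,
        harmonic=harmonic,
        calibrated=calibrated,
    )


def calibrate(
    reference_cube: DecayCube,
    reference_tau: float = 4.0,
    harmonic: int = 1,
    min_total_photons: float = 1e4,
) -> PhasorCalibration:
    """Derive the IRF correction from a uniform mono-exponential reference.

    The correction is the complex ratio of the reference lifetime's ideal
    semicircle phasor to the intensity-weighted mean measured phasor.
    Applying it to a cube measured on the same instrument rotates the IRF's
    phase delay and rescales its demodulation away.
    """
    cloud = phasor_transform(reference_cube, harmonic=harmonic, min_photons=0.0)
    total = cloud.intensity.sum()
    if total <= min_total_photons:
        raise ValueError(
            f"reference cube too dim for calibration ({total:.0f} photons)"
        )
    w = cloud.intensity / total
    measured = (w * (cloud.g + 1j * cloud.s)).sum()
    if abs(measured) < 1e-12:
        raise ValueError("reference phasor vanishes; cannot calibrate")
    ideal = complex(*semicircle_point(reference_tau, cloud.omega))
    return PhasorCalibration(
        reference_tau=reference_tau, correction=ideal / measured
    )


def fit_phasor_line(
    cloud: PhasorCloud, mask: np.ndarray | None = None
) -> PhasorLine:
    """Principal-axis (total least squares) line through the masked cloud,
    intersected with the universal semicircle.

    The two intersection points are the lifetimes of an underlying
    two-component mixture.  Raises :class:`NoIntersectionError` (with the
    line-to-circle distance) if the line misses the semicircle; an
    isotropic cloud is flagged ``ill_conditioned``.
    """
    if not cloud.calibrated:
        raise ValueError("phasor line fitting requires a calibrated cloud")
    mask = cloud.mask if mask is None else (mask & cloud.mask)
    g, s = cloud.g[mask], cloud.s[mask]
    if g.size < 2:
        raise ValueError("need at least 2 masked phasor points")
    pts = np.stack([g, s], axis=1)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T) if g.size > 2 else np.eye(2) * 1e-12
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    direction = evecs[:, -1]
    ill = bool(evals[-1] <= 0 or (evals[0] / max(evals[-1], 1e-300)) > 0.5)
    perp = (pts - centroid) @ evecs[:, 0]
    residual_rms = float(np.sqrt((perp**2).mean()))

    # intersect centroid + t*direction with (g-1/2)^2 + s^2 = 1/4
    c = np.array([0.5, 0.0])
    d = direction / np.linalg.norm(direction)
    rel = centroid - c
    b = rel @ d
    const = rel @ rel - 0.25
    disc = b * b - const
    if disc < 0:
        distance = float(np.sqrt(rel @ rel - b * b) - 0.5)
        raise NoIntersectionError(
            f"phasor line misses the universal semicircle by {distance:.4f}",
            distance=distance,
        )
    roots = np.array([-b - np.sqrt(disc), -b + np.sqrt(disc)])
    points = [tuple(centroid + r * d) for r in roots]
    taus = sorted(point_to_tau(p[0], abs(p[1]), cloud.omega) for p in points)
    points = sorted(points, key=lambda p: -p[0])  # short lifetime = right
    return PhasorLine(
        centroid=tuple(centroid),
        direction=tuple(d),
        intersections=(points[0], points[1]),
        lifetimes=(taus[0], taus[1]),
        residual_rms=residual_rms,
        ill_conditioned=ill,
    )


def conditioned_cloud(
    cloud: PhasorCloud, pair_labels: np.ndarray, which
) -> PhasorCloud:
    """Restrict the cloud to one lifetime-pair compartment.

    ``which`` is "mitochondrial"/"cytoplasmic" (or the integer pair code).
    The subsets for the two compartments plus the unclassified remainder
    partition the original masked cloud.
    """
    from .components import PAIR_CYTO, PAIR_MITO, UNCLASSIFIED

    codes = {
        "mitochondrial": PAIR_MITO,
        "cytoplasmic": PAIR_CYTO,
        "unclassified": UNCLASSIFIED,
        PAIR_MITO: PAIR_MITO,
        PAIR_CYTO: PAIR_CYTO,
        UNCLASSIFIED: UNCLASSIFIED,
    }
    if which not in codes:
        raise KeyError(f"unknown compartment label {which!r}")
    if pair_labels.shape != cloud.g.shape:
        raise ValueError("pair label image shape differs from the cloud")
    return replace(cloud, mask=cloud.mask & (pair_labels == codes[which]))
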