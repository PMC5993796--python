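"""Lifetime-component decomposition and metabolic ratios.

Per-pixel bi-exponential fitting yields two lifetimes per pixel, but across
an adipocyte image the lifetimes cluster into four pools: the mitochondrial
free/bound pair C1 (~0.5 ns) / C3 (~2.3 ns) and the cytoplasmic pair
C2 (~1.0 ns) / C4 (~3.7 ns).  This module builds the intensity-weighted
lifetime histogram, decomposes it into Gaussian components
``a_i exp(-(x-b_i)^2 / (2 c_i^2))``, classifies pixels into lifetime pairs,
and computes the derived metabolic metrics:

* MCR, the mitochondrial-cytoplasmic ratio ``(C1 + C3) / (C2 + C4)`` of
  component fluorescence intensities;
* the classic free-to-bound ratio (short/long amplitude ratio); and
* the optical redox ratio ``FAD / (FAD + NADH)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .decay import FitImage

__all__ = [
    "LifetimeHistogram",
    "GaussianComponent",
    "ComponentSet",
    "MetricsReport",
    "lifetime_histogram",
    "fit_gaussians",
    "select_peak_count",
    "classify_pairs",
    "component_intensities",
    "mcr",
    "free_to_bound",
    "redox_image",
    "UNCLASSIFIED",
    "PAIR_MITO",
    "PAIR_CYTO",
]

UNCLASSIFIED, PAIR_MITO, PAIR_CYTO = 0, 1, 2


@dataclass
class LifetimeHistogram:
    """Intensity-weighted lifetime histogram (photon counts per bin)."""

    bin_centers: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if len(self.bin_centers) != len(self.weights):
            raise ValueError("bin_centers and weights must have equal length")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class GaussianComponent:
    """One lifetime pool: height ``a``, center ``b`` (ns), width ``c`` (ns)."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("height and width must be positive")

    @property
    def area(self) -> float:
        """Integrated intensity a * c * sqrt(2 pi)."""
        return self.a * self.c * np.sqrt(2.0 * np.pi)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-((x - self.b) ** 2) / (2.0 * self.c**2))


@dataclass
class ComponentSet:
    """Gaussian components sorted by center, C1..Cn.

    For the four-component NADH model the pairing convention is fixed:
    (C1, C3) are mitochondrial and (C2, C4) cytoplasmic.  ``degenerate``
    flags fits whose components overlap so strongly that fewer distinct
    lifetime pools are resolved than were requested.
    """

    components: tuple[GaussianComponent, ...]
    degenerate: bool = False
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        comps = tuple(sorted(self.components, key=lambda g: g.b))
        object.__setattr__(self, "components", comps)

    def __len__(self):
        return len(self.components)

    @property
    def centers(self) -> np.ndarray:
        return np.array([g.b for g in self.components])

    @property
    def widths(self) -> np.ndarray:
        return np.array([g.c for g in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([g.area for g in self.components])

    @property
    def assignment(self) -> dict[int, str]:
        """Component index (0-based) -> compartment tag; 4-component only."""
        if len(self.components) != 4:
            raise ValueError("pair assignment requires exactly 4 components")
        return {0: "mitochondrial", 1: "cytoplasmic", 2: "mitochondrial", 3: "cytoplasmic"}

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return sum(g(x) for g in self.components)

    @property
    def resolved_count(self) -> int:
        """Number of distinct lifetime pools the fit actually resolves.

        Counted as the local maxima (modes) of the fitted composite curve:
        strongly overlapping Gaussians that carve one asymmetric hump into
        slices form a single mode and count once.  This implements "number
        of unique lifetime components" — a 4-Gaussian fit collapsing onto
        two humps counts as 2.  Modes need a prominence of 2% of the curve
        maximum, which ignores negligible-area components.
        """
        lo = min(g.b - 4 * g.c for g in self.components)
        hi = max(g.b + 4 * g.c for g in self.components)
        step = max(min(g.c for g in self.components) / 4.0, 1e-4)
        x = np.arange(lo, hi + step, step)
        curve = self(x)
        peaks, _ = find_peaks(curve, prominence=0.02 * curve.max())
        return len(peaks)


@dataclass
class MetricsReport:
    """Per-image metabolic metrics."""

    mcr: float
    free_to_bound: float
    redox: float
    component_intensities: np.ndarray
    n_qc_pixels: int
    extras: dict = field(default_factory=dict)


def lifetime_histogram(
    fit: FitImage,
    mask: np.ndarray | None = None,
    bin_width_ns: float = 0.05,
    range_ns: tuple[float, float] = (0.0, 6.0),
) -> LifetimeHistogram:
    """Intensity-weighted lifetime histogram over QC-passing pixels.

    Each pixel contributes its two fitted lifetimes, weighted by the
    photon intensity of the respective component (photons x fractional
    intensity), so the histogram total equals the total fitted fluorescence
    intensity of the masked pixels (weight conservation; lifetimes fitted
    outside ``range_ns`` are clipped into the edge bins to preserve it).
    """
    if mask is None:
        mask = fit.qc_mask
    lo, hi = range_ns
    n_bins = int(round((hi - lo) / bin_width_ns))
    edges = lo + bin_width_ns * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    taus = np.concatenate([fit.tau1[mask], fit.tau2[mask]])
    weights = np.concatenate(
        [
            fit.photons[mask] * fit.frac_intensity1[mask],
            fit.photons[mask] * fit.frac_intensity2[mask],
        ]
    )
    good = np.isfinite(taus) & np.isfinite(weights)
    taus = np.clip(taus[good], lo, hi - 0.5 * bin_width_ns)
    hist, _ = np.histogram(taus, bins=edges, weights=weights[good])
    return LifetimeHistogram(bin_centers=centers, weights=hist)


def _seed_centers(hist: LifetimeHistogram, n_peaks: int) -> np.ndarray:
    """Initial peak positions: n largest local maxima of the smoothed
    histogram (ties broken by weight), padded with weight quantiles."""
    smooth = gaussian_filter1d(hist.weights.astype(float), 2.0)
    peaks, props = find_peaks(smooth, height=0.0)
    order = np.argsort(props["peak_heights"])[::-1]
    centers = list(hist.bin_centers[peaks[order][:n_peaks]])
    if len(centers) < n_peaks:
        total = hist.weights.sum()
        if total > 0:
            cdf = np.cumsum(hist.weights) / total
            qs = np.linspace(0.15, 0.85, n_peaks)
            fill = [hist.bin_centers[np.searchsorted(cdf, q)] for q in qs]
        else:
            fill = list(np.linspace(hist.bin_centers[0], hist.bin_centers[-1], n_peaks))
        for v in fill:
            if len(centers) >= n_peaks:
                break
            centers.append(v)
    return np.sort(np.asarray(centers[:n_peaks]))


def _curvature_seeds(hist: LifetimeHistogram, n_peaks: int) -> np.ndarray:
    """Peak seeds from negative-curvature maxima of the smoothed histogram.

    Detects shoulders: a lifetime pool riding on the flank of a stronger
    neighbor has no local maximum but still a curvature dip.
    """
    smooth = gaussian_filter1d(hist.weights.astype(float), 2.0)
    curvature = -np.gradient(np.gradient(smooth))
    peaks, props = find_peaks(curvature, height=0.0)
    if peaks.size == 0:
        return _quantile_seeds(hist, n_peaks)
    weights = smooth[peaks]
    order = np.argsort(weights)[::-1]
    centers = list(hist.bin_centers[peaks[order][:n_peaks]])
    fill = _quantile_seeds(hist, n_peaks)
    for v in fill:
        if len(centers) >= n_peaks:
            break
        centers.append(v)
    return np.sort(np.asarray(centers[:n_peaks]))


def _quantile_seeds(hist: LifetimeHistogram, n_peaks: int) -> np.ndarray:
    total = hist.weights.sum()
    cdf = np.cumsum(hist.weights) / total
    qs = (np.arange(n_peaks) + 0.5) / n_peaks
    return np.array([hist.bin_centers[np.searchsorted(cdf, q)] for q in qs])


def fit_gaussians(
    hist: LifetimeHistogram,
    n_peaks: int,
    init_centers=None,
) -> ComponentSet:
    """Decompose the histogram into a sum of ``n_peaks`` Gaussians.

    Plain (unweighted) nonlinear least squares of
    ``sum_i a_i exp(-(x - b_i)^2 / (2 c_i^2))``; counting weights would
    up-weight the low-count blend pedestal between peaks and drag the
    centers away from the modes.  Without explicit
    ``init_centers`` the fit is multi-started from smoothed-histogram local
    maxima and from weight quantiles, keeping the solution with the lowest
    weighted residual; peaks of very unequal area make a single seeding
    unreliable.  Returns components sorted by center; requesting more peaks
    than the histogram resolves yields a converged fit with overlapping
    centers, flagged ``degenerate``.
    """
    if hist.total_weight <= 0:
        raise ValueError("cannot fit an empty histogram")
    if init_centers is not None:
        return _fit_gaussians_once(hist, n_peaks, init_centers)
    seedings = [
        _seed_centers(hist, n_peaks),
        _quantile_seeds(hist, n_peaks),
        _curvature_seeds(hist, n_peaks),
    ]
    # hybrid: local maxima merged with quantiles, n largest-weight kept
    hybrid = np.concatenate(seedings)
    order = np.argsort(
        [-hist.weights[np.argmin(np.abs(hist.bin_centers - b))] for b in hybrid]
    )
    dedup = []
    for b in hybrid[order]:
        if all(abs(b - d) > 0.15 for d in dedup):
            dedup.append(b)
    if len(dedup) >= n_peaks:
        seedings.append(np.sort(np.asarray(dedup[:n_peaks])))
    best = None
    for seeds in seedings:
        cs = _fit_gaussians_once(hist, n_peaks, seeds)
        if best is None or cs.fit_info["chisqr"] < best.fit_info["chisqr"]:
            best = cs
    return best


def _fit_gaussians_once(
    hist: LifetimeHistogram,
    n_peaks: int,
    init_centers,
) -> ComponentSet:
    if not 1 <= n_peaks <= 5:
        raise ValueError("n_peaks must be in 1..5")
    if hist.total_weight <= 0:
        raise ValueError("cannot fit an empty histogram")
    x, y = hist.bin_centers, hist.weights.astype(float)
    init_centers = np.sort(np.asarray(init_centers, dtype=float))
    span = x[-1] - x[0]

    model = None
    params = None
    for i, b0 in enumerate(init_centers):
        g = GaussianModel(prefix=f"g{i}_")
        p = g.make_params()
        p[f"g{i}_center"].set(value=b0, min=x[0], max=x[-1])
        p[f"g{i}_sigma"].set(value=0.1, min=hist.bin_width / 2, max=span / 2)
        height = max(y[np.argmin(np.abs(x - b0))], y.max() * 0.05)
        p[f"g{i}_amplitude"].set(
            value=height * 0.1 * np.sqrt(2 * np.pi), min=0.0
        )
        model = g if model is None else model + g
        params = p if params is None else params.update(p) or params

    result = model.fit(y, params, x=x)
    comps = []
    for i in range(n_peaks):
        sigma = max(result.params[f"g{i}_sigma"].value, 1e-6)
        area = max(result.params[f"g{i}_amplitude"].value, 1e-12)
        comps.append(
            GaussianComponent(
                a=area / (sigma * np.sqrt(2 * np.pi)),
                b=float(result.params[f"g{i}_center"].value),
                c=float(sigma),
            )
        )
    cs = ComponentSet(
        components=tuple(comps),
        fit_info={
            "chisqr": float(result.chisqr),
            "ndata": int(result.ndata),
            "nvarys": int(result.nvarys),
            "success": bool(result.success),
        },
    )
    cs.degenerate = cs.resolved_count < n_peaks
    return cs


def select_peak_count(
    hist: LifetimeHistogram,
    candidates=(2, 3, 4),
    method: str = "modes",
    smooth_ns: float = 0.1,
    prominence: float = 0.08,
) -> int:
    """Number of unique lifetime components supported by the histogram.

    High spatial binning mixes compartment decays within each fitted pixel
    and collapses the four lifetime pools to two; low binning resolves all
    four.  The default rule counts the modes of the smoothed
    intensity-weighted histogram (Gaussian smoothing ``smooth_ns``, mode
    prominence at least ``prominence`` of the maximum — a peak must rise
    visibly above the band it sits on to count as a distinct component),
    clipped to the candidate range; a histogram with fewer
    modes than the smallest candidate (e.g. a mono-exponential cube)
    reports the candidate floor, and the corresponding Gaussian fit carries
    the ``degenerate`` flag.

    ``method="bic"`` instead fits every candidate count and selects by the
    Bayesian information criterion on the weighted residuals, reduced to
    the resolved mode count of the winning fit.  With many millions of
    photons per histogram the BIC route tends to prefer extra components
    that slice a single asymmetric hump, so the mode count is the default.
    """
    if hist.total_weight <= 0:
        raise ValueError("cannot select a peak count for an empty histogram")
    candidates = sorted(candidates)
    if method == "modes":
        sigma_bins = max(smooth_ns / hist.bin_width, 1e-6)
        smooth = gaussian_filter1d(hist.weights.astype(float), sigma_bins)
        peaks, _ = find_peaks(smooth, prominence=prominence * smooth.max())
        n_modes = len(peaks)
        return int(np.clip(n_modes, candidates[0], candidates[-1]))
    if method == "bic":
        best = None
        for n in candidates:
            cs = fit_gaussians(hist, n)
            m = cs.fit_info["ndata"]
            chisqr = max(cs.fit_info["chisqr"], 1e-12)
            bic = m * np.log(chisqr / m) + 3 * n * np.log(m)
            if best is None or bic < best[0]:
                best = (bic, cs)
        return best[1].resolved_count
    raise ValueError("method must be 'modes' or 'bic'")


def classify_pairs(
    fit: FitImage, comps: ComponentSet, mask: np.ndarray | None = None
) -> np.ndarray:
    """Label each QC pixel by its nearest lifetime pair.

    A pixel with fitted pair (tau1, tau2) is mitochondrial when it is closer
    (Mahalanobis distance using the component widths) to (C1, C3) than to
    (C2, C4), cytoplasmic in the opposite case, and unclassified on an
    exact tie.  Returns an integer image with UNCLASSIFIED / PAIR_MITO /
    PAIR_CYTO codes.
    """
    if len(comps) != 4:
        raise ValueError("pair classification requires a 4-component set")
    if mask is None:
        mask = fit.qc_mask
    b = comps.centers
    c = comps.widths
    labels = np.full(fit.tau1.shape, UNCLASSIFIED, dtype=np.uint8)
    t1, t2 = fit.tau1[mask], fit.tau2[mask]
    d_mito = ((t1 - b[0]) / c[0]) ** 2 + ((t2 - b[2]) / c[2]) ** 2
    d_cyto = ((t1 - b[1]) / c[1]) ** 2 + ((t2 - b[3]) / c[3]) ** 2
    out = np.where(d_mito < d_cyto, PAIR_MITO, np.where(d_cyto < d_mito, PAIR_CYTO, UNCLASSIFIED))
    labels[mask] = out
    return labels


def component_intensities(
    fit: FitImage, comps: ComponentSet, mask: np.ndarray | None = None
) -> np.ndarray:
    """Total fluorescence intensity assigned to each component C1..Cn.

    Every pixel's two intensity contributions (photons x fractional
    intensity) are assigned to the component with the nearest center, so the
    totals sum exactly to the histogram's total intensity.
    """
    if mask is None:
        mask = fit.qc_mask
    centers = comps.centers
    totals = np.zeros(len(centers))
    for tau, weight in (
        (fit.tau1[mask], fit.photons[mask] * fit.frac_intensity1[mask]),
        (fit.tau2[mask], fit.photons[mask] * fit.frac_intensity2[mask]),
    ):
        good = np.isfinite(tau) & np.isfinite(weight)
        nearest = np.argmin(
            np.abs(tau[good][:, None] - centers[None, :]), axis=1
        )
        np.add.at(totals, nearest, weight[good])
    return totals


def mcr(intensities: np.ndarray) -> float:
    """Mitochondrial-cytoplasmic ratio (C1 + C3) / (C2 + C4)."""
    intensities = np.asarray(intensities, dtype=float)
    if intensities.shape != (4,):
        raise ValueError("MCR requires the four component intensities C1..C4")
    denom = intensities[1] + intensities[3]
    if denom <= 0:
        raise ZeroDivisionError("MCR undefined: cytoplasmic intensity is zero")
    return float((intensities[0] + intensities[2]) / denom)


def free_to_bound(fit: FitImage, mask: np.ndarray | None = None) -> float:
    """Intensity-weighted mean of the per-pixel short/long amplitude ratio.

    The classic optical biomarker: alpha_1 / alpha_2 with tau_1 < tau_2
    (free over enzyme-bound NADH).  Pixels with a vanishing long-component
    amplitude are skipped (their count is available via ``np.isfinite``).
    """
    if mask is None:
        mask = fit.qc_mask
    if not np.any(mask):
        raise ValueError("no QC-passing pixels")
    a1, a2 = fit.alpha1[mask], fit.alpha2[mask]
    w = fit.photons[mask]
    good = np.isfinite(a1) & np.isfinite(a2) & (a2 > 0)
    if not np.any(good):
        raise ValueError("no pixels with a nonzero long-component amplitude")
    return float(np.average(a1[good] / a2[good], weights=w[good]))


def redox_image(
    fad_image: np.ndarray,
    nadh_intensity: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Pixel-wise optical redox ratio FAD / (FAD + NADH) and its mean.

    Pixels where the denominator vanishes are masked (NaN).  The mean is
    taken over ``mask`` (default: all pixels with a positive denominator).
    """
    fad = np.asarray(fad_image, dtype=float)
    nadh = np.asarray(nadh_intensity, dtype=float)
    if fad.shape != nadh.shape:
        raise ValueError("FAD and NADH images must have the same shape")
    denom = fad + nadh
    ratio = np.full(fad.shape, np.nan)
    valid = denom > 0
    ratio[valid] = fad[valid] / denom[valid]
    if mask is None:
        mask = valid
    sel = mask & valid
    mean = float(ratio[sel].mean()) if np.any(sel) else np.nan
    return ratio, mean
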