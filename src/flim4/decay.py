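"""Spatial binning and per-pixel bi-exponential reconvolution fitting.

The measured decay at a pixel is modeled as a sum of periodically re-excited
exponentials circularly convolved with the normalized IRF, optionally plus a
constant offset (dark counts):

    m(t) = sum_i A_i * S(t; tau_i) [+ offset]

The offset is off by default: under periodic re-excitation the wrapped tail
of the long-lifetime component is itself nearly flat, so a free constant is
close to collinear with it and inflates the variance of the long lifetime
roughly threefold while biasing it low; dark counts in well-shielded TCSPC
detectors (and in the simulator) are negligible by comparison.

where ``S(t; tau)`` is the unit-sum channel profile of a wrapped exponential
convolved with the IRF, so ``A_i`` is directly the photon total (intensity)
of component i and the fractional intensity is ``A_i / sum_j A_j``
(equivalently ``alpha_i tau_i / sum alpha_j tau_j`` in rate-amplitude
terms).  The lifetimes enter nonlinearly; the amplitudes and offset are
linear and are solved exactly at every step (variable projection), so a fit
has only ``n_components`` nonlinear parameters.

Weighting and fit quality: the linear solves use fixed counting weights
(sigma^2 = max(counts, 1)); the reported reduced chi-square uses Pearson
weighting (sigma^2 = fitted model), whose expectation is 1 at all count
levels, keeping the conventional 0.9-1.3 acceptance window meaningful even
at ~1 photon per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import least_squares

from .meta import IRF, AcquisitionMeta, DecayCube

__all__ = [
    "NoSignalError",
    "PixelFit",
    "FitImage",
    "bin_decays",
    "binned_footprint",
    "format_footprint",
    "fit_pixel",
    "fit_image",
    "qc_filter",
    "adaptive_foreground",
]

TAU_BOUNDS_NS = (0.05, 10.0)
_CHI2_MODEL_FLOOR = 0.1  # counts; guards Pearson terms where the model -> 0


class NoSignalError(ValueError):
    """Raised when a decay contains no photons to fit."""


# ---------------------------------------------------------------------------
# spatial binning


def _box_sum(arr: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Sliding-window sum of width k along ``axis`` with partial edges."""
    n = arr.shape[axis]
    h = k // 2
    cs = np.cumsum(arr, axis=axis)
    cs = np.concatenate([np.zeros_like(np.take(cs, [0], axis=axis)), cs], axis=axis)
    idx = np.arange(n)
    hi = np.clip(idx + h + 1, 0, n)
    lo = np.clip(idx - h, 0, n)
    return np.take(cs, hi, axis=axis) - np.take(cs, lo, axis=axis)


def bin_decays(cube: DecayCube, k: int) -> DecayCube:
    """Sum each pixel's k x k neighborhood of decay curves onto the pixel.

    Edges use the available partial neighborhood (no mirror padding), so
    photon counts near the border are lower and the photon-count QC filter
    naturally discounts them.  ``k`` must be odd; ``k=1`` is the identity.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("binning width k must be a positive odd integer")
    if k == 1:
        return cube
    counts = _box_sum(_box_sum(cube.counts, k, axis=0), k, axis=1)
    return DecayCube(counts=counts, meta=cube.meta, irf=cube.irf, truth=dict(cube.truth))


def binned_footprint(k: int, meta: AcquisitionMeta) -> tuple[float, float]:
    """Physical side length (um) and area (um^2) of a k x k binning window."""
    if k < 1:
        raise ValueError("k must be >= 1")
    side = k * meta.pixel_pitch_um
    return side, side**2


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def format_footprint(k: int, meta: AcquisitionMeta) -> tuple[str, str]:
    """Reporting helper: footprint rounded to two significant figures."""
    side, area = binned_footprint(k, meta)
    side_r, area_r = _round_sig(side), _round_sig(area)

    def fmt(v):
        return f"{v:g}"

    return f"{fmt(side_r)} µm", f"{fmt(area_r)} µm²"


# ---------------------------------------------------------------------------
# decay model


class _DecayModel:
    """Shared machinery: IRF-convolved periodic exponential bases."""

    def __init__(self, irf: IRF, meta: AcquisitionMeta):
        if len(irf.curve) != meta.n_channels:
            raise ValueError("IRF length must equal n_channels")
        self.meta = meta
        self.t = meta.times_ns
        self.nch = meta.n_channels
        self.kernel = np.fft.rfft(irf.normalized())

    def _conv(self, curves: np.ndarray) -> np.ndarray:
        return np.fft.irfft(
            np.fft.rfft(curves, axis=-1) * self.kernel, n=self.nch, axis=-1
        )

    def basis(self, taus: np.ndarray) -> np.ndarray:
        """Unit-sum convolved profiles S(tau); taus of any leading shape."""
        taus = np.asarray(taus, dtype=float)
        p = np.exp(-self.t / taus[..., None])
        p /= p.sum(axis=-1, keepdims=True)
        return self._conv(p)

    def basis_and_dlog(self, taus: np.ndarray):
        """S(tau) and its derivative with respect to log tau."""
        taus = np.asarray(taus, dtype=float)[..., None]
        p = np.exp(-self.t / taus)
        psum = p.sum(axis=-1, keepdims=True)
        shape = p / psum
        dp = p * (self.t / taus**2)
        dshape = (dp - shape * dp.sum(axis=-1, keepdims=True)) / psum
        return self._conv(shape), taus * self._conv(dshape)


def _solve_linear(basis: np.ndarray, y: np.ndarray, w: np.ndarray, fit_offset: bool = False):
    """Weighted least-squares coefficients for [bases..., (const)] per pixel.

    basis: (..., n_comp, nch); y, w: (..., nch).  Returns coefficients
    (..., n_comp [+ 1]), with the constant offset last when ``fit_offset``.
    """
    if fit_offset:
        ones = np.ones_like(y[..., None, :])
        X = np.concatenate([basis, ones], axis=-2)  # (..., p, nch)
    else:
        X = basis
    Xw = X * w[..., None, :]
    G = Xw @ np.swapaxes(Xw, -1, -2)
    b = (Xw * (y * w)[..., None, :]).sum(axis=-1)
    # tiny ridge for numerically degenerate bases (tau1 == tau2)
    eye = np.eye(G.shape[-1])
    G = G + 1e-10 * np.trace(G, axis1=-2, axis2=-1)[..., None, None] * eye
    try:
        c = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        c = (np.linalg.pinv(G) @ b[..., None])[..., 0]
    return c, X


def _tail_tau_estimate(y: np.ndarray, model: _DecayModel) -> np.ndarray:
    """Log-linear slope of the decay tail; batched long-lifetime start value."""
    peak = int(np.argmax(y.mean(axis=0))) if y.ndim == 2 else int(np.argmax(y))
    nch = model.nch
    lo = min(peak + max(4, nch // 32), nch - 8)
    hi = min(lo + nch // 2, nch - 1)
    t = model.t[lo:hi]
    z = np.log(np.clip(y[..., lo:hi], 0.5, None))
    t0 = t - t.mean()
    denom = (t0**2).sum()
    slope = (z * t0).sum(axis=-1) / denom
    with np.errstate(divide="ignore"):
        tau = np.where(slope < -1e-6, -1.0 / slope, 3.0)
    return np.clip(tau, 0.8, 8.0)


def _batched_varpro_fit(
    y: np.ndarray,
    model: _DecayModel,
    n_components: int,
    init_taus: np.ndarray | None = None,
    max_iter: int = 40,
    fit_offset: bool = False,
):
    """Damped Gauss-Newton variable-projection fit of many decays at once.

    y: (N, nch) counts.  Returns dict of per-decay arrays: taus (N, n_comp)
    sorted ascending, intensities (N, n_comp) matched to the sorted taus,
    offset, chi2 (Pearson, reduced), converged.
    """
    y = np.asarray(y, dtype=float)
    N, nch = y.shape

    if init_taus is None:
        tau_long = _tail_tau_estimate(y, model)
        if n_components == 1:
            theta = np.log(tau_long)[:, None]
        elif n_components == 2:
            theta = np.stack([np.full(N, np.log(0.5)), np.log(tau_long)], axis=1)
        else:
            mid = np.sqrt(0.5 * tau_long)
            theta = np.stack(
                [np.full(N, np.log(0.3)), np.log(mid), np.log(tau_long)], axis=1
            )
    else:
        init_taus = np.broadcast_to(
            np.asarray(init_taus, dtype=float), (N, n_components)
        )
        theta = np.log(init_taus).copy()

    log_lo, log_hi = np.log(TAU_BOUNDS_NS[0]), np.log(TAU_BOUNDS_NS[1])

    def cost_and_linear(theta, w):
        basis = model.basis(np.exp(theta))  # (N, p, nch)
        c, X = _solve_linear(basis, y, w, fit_offset)
        resid = (y - np.einsum("...p,...pc->...c", c, X)) * w
        return (resid**2).sum(axis=-1), c, basis, resid

    def gn_pass(theta, w, n_iter):
        """One damped Gauss-Newton descent at fixed weights; in-place theta."""
        cost, c, _, resid = cost_and_linear(theta, w)
        lam = np.full(N, 1e-3)
        idx = np.arange(N)
        diag = np.arange(n_components)
        for _ in range(n_iter):
            if idx.size == 0:
                break
            th_a, w_a, y_a = theta[idx], w[idx], y[idx]
            S, dS = model.basis_and_dlog(np.exp(th_a))
            # Kaufman approximation: hold linear coefficients fixed in J
            Jw = c[idx, :n_components, None] * dS * w_a[:, None, :]
            H = Jw @ np.swapaxes(Jw, -1, -2)
            g = np.einsum("npc,nc->np", Jw, resid[idx])
            Hd = H.copy()
            Hd[:, diag, diag] *= (1.0 + lam[idx])[:, None]
            Hd[:, diag, diag] += 1e-12
            try:
                step = np.linalg.solve(Hd, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = (np.linalg.pinv(Hd) @ g[..., None])[..., 0]
            new_theta = np.clip(th_a + step, log_lo, log_hi)
            basis_a = model.basis(np.exp(new_theta))
            c_a, X_a = _solve_linear(basis_a, y_a, w_a, fit_offset)
            resid_a = (y_a - np.einsum("np,npc->nc", c_a, X_a)) * w_a
            cost_a = (resid_a**2).sum(axis=-1)
            accept = cost_a < cost[idx]
            rel = np.abs(cost[idx] - cost_a) / np.maximum(cost[idx], 1e-12)
            upd = idx[accept]
            theta[upd] = new_theta[accept]
            c[upd] = c_a[accept]
            resid[upd] = resid_a[accept]
            cost[upd] = cost_a[accept]
            lam[idx] = np.where(accept, lam[idx] / 3.0, lam[idx] * 10.0)
            lam = np.clip(lam, 1e-7, 1e7)
            done = (accept & (rel < 1e-11)) | (lam[idx] >= 1e6)
            idx = idx[~done]
        return theta, c, cost

    # Outer loop: iteratively reweighted least squares.  Counting (Neyman)
    # weights bias the lifetimes several percent low at TCSPC count levels
    # (downward-fluctuating channels are over-weighted), so after each pass
    # the weights are refreshed from the fitted model (Pearson weighting).
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))
    c = None
    for reweight, n_iter in enumerate((max_iter, max_iter)):
        theta, c, cost = gn_pass(theta, w, n_iter)
        if reweight < 2:
            fitted = np.einsum(
                "np,npc->nc", c[..., :n_components], model.basis(np.exp(theta))
            )
            if fit_offset:
                fitted = fitted + np.clip(c[..., n_components], 0.0, None)[..., None]
            w = 1.0 / np.sqrt(np.maximum(fitted, 0.5))

    taus = np.exp(theta)
    intensities = np.clip(c[..., :n_components], 0.0, None)
    offset = (
        np.clip(c[..., n_components], 0.0, None) if fit_offset else np.zeros(N)
    )

    # sort lifetimes ascending, carrying their amplitudes along
    order = np.argsort(taus, axis=-1)
    taus = np.take_along_axis(taus, order, axis=-1)
    intensities = np.take_along_axis(intensities, order, axis=-1)

    # Pearson reduced chi-square at the fitted model
    basis = model.basis(taus)
    fitted = np.einsum("np,npc->nc", intensities, basis) + offset[..., None]
    dof = nch - (2 * n_components + int(fit_offset))
    chi2 = ((y - fitted) ** 2 / np.maximum(fitted, _CHI2_MODEL_FLOOR)).sum(-1) / dof
    converged = np.isfinite(cost)
    chi2 = np.where(converged, chi2, np.inf)
    return {
        "taus": taus,
        "intensities": intensities,
        "offset": offset,
        "chi2": chi2,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# public fitting API


@dataclass
class PixelFit:
    """Fitted decay parameters of one (possibly binned) pixel.

    ``alphas`` are rate amplitudes in counts/channel (A_i * dt / tau_i);
    ``intensities`` are the photon totals A_i of each component; lifetimes
    are sorted ascending with the amplitude pairing preserved.
    """

    alphas: tuple[float, ...]
    taus: tuple[float, ...]
    intensities: tuple[float, ...]
    offset: float
    chi2: float
    photons: float
    converged: bool = True

    @property
    def frac_intensity(self) -> tuple[float, ...]:
        total = sum(self.intensities)
        if total <= 0:
            return tuple(np.nan for _ in self.intensities)
        return tuple(a / total for a in self.intensities)

    @property
    def mean_tau(self) -> float:
        """Intensity-weighted mean lifetime (ns)."""
        return float(np.dot(self.frac_intensity, self.taus))


def fit_pixel(
    decay: np.ndarray,
    irf: IRF,
    meta: AcquisitionMeta,
    n_components: int = 2,
    init: tuple[float, ...] | None = None,
    fit_offset: bool = False,
) -> PixelFit:
    """Reconvolution fit of a single decay via scipy's trust-region solver.

    This is the reference single-pixel route; :func:`fit_image` uses a
    batched Gauss-Newton implementation of the identical model and the two
    are interchangeable to numerical tolerance.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.ndim != 1 or decay.size != meta.n_channels:
        raise ValueError("decay length must equal n_channels")
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2, or 3")
    if decay.sum() <= 0:
        raise NoSignalError("decay contains no photons")
    model = _DecayModel(irf, meta)

    if init is None:
        tau_long = float(_tail_tau_estimate(decay[None, :], model)[0])
        starts = {1: [tau_long], 2: [0.5, tau_long], 3: [0.3, np.sqrt(0.5 * tau_long), tau_long]}
        init = starts[n_components]

    def make_residual(w):
        def residual(log_taus):
            basis = model.basis(np.exp(log_taus))
            c, X = _solve_linear(basis, decay, w, fit_offset)
            return (decay - c @ X) * w

        return residual

    # IRLS: counting weights first, then weights refreshed from the model
    w = 1.0 / np.sqrt(np.maximum(decay, 1.0))
    x0 = np.log(np.asarray(init, dtype=float))
    for reweight in range(2):
        sol = least_squares(
            make_residual(w),
            x0=x0,
            bounds=(np.log(TAU_BOUNDS_NS[0]), np.log(TAU_BOUNDS_NS[1])),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
        )
        x0 = sol.x
        taus = np.exp(sol.x)
        basis = model.basis(taus)
        c, X = _solve_linear(basis, decay, w, fit_offset)
        if reweight < 1:
            fitted = np.clip(c @ X, 0.5, None)
            w = 1.0 / np.sqrt(fitted)
    intensities = np.clip(c[:n_components], 0.0, None)
    offset = float(np.clip(c[n_components], 0.0, None)) if fit_offset else 0.0
    order = np.argsort(taus)
    taus, intensities = taus[order], intensities[order]
    fitted = intensities @ model.basis(taus) + offset
    dof = meta.n_channels - (2 * n_components + int(fit_offset))
    chi2 = float(
        ((decay - fitted) ** 2 / np.maximum(fitted, _CHI2_MODEL_FLOOR)).sum() / dof
    )
    if not sol.success:
        chi2 = np.inf
    alphas = intensities * meta.channel_width_ns / taus
    return PixelFit(
        alphas=tuple(alphas),
        taus=tuple(taus),
        intensities=tuple(intensities),
        offset=offset,
        chi2=chi2,
        photons=float(decay.sum()),
        converged=bool(sol.success),
    )


@dataclass
class FitImage:
    """Per-pixel bi-exponential fit results over a (binned) decay cube.

    Parameter planes are NaN outside the fitted (foreground) region.
    ``qc_mask`` marks pixels passing the photon-count and chi-square
    filters; it is always a subset of ``foreground_mask``.
    """

    tau1: np.ndarray
    tau2: np.ndarray
    intensity1: np.ndarray
    intensity2: np.ndarray
    offset: np.ndarray
    chi2: np.ndarray
    photons: np.ndarray
    foreground_mask: np.ndarray
    qc_mask: np.ndarray
    meta: AcquisitionMeta
    binning: int = 1
    settings: dict = field(default_factory=dict)

    @property
    def alpha1(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.intensity1 * self.meta.channel_width_ns / self.tau1

    @property
    def alpha2(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.intensity2 * self.meta.channel_width_ns / self.tau2

    @property
    def frac_intensity1(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.intensity1 / (self.intensity1 + self.intensity2)

    @property
    def frac_intensity2(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.intensity2 / (self.intensity1 + self.intensity2)

    @property
    def mean_tau(self) -> np.ndarray:
        """Intensity-weighted mean lifetime map (ns)."""
        return self.frac_intensity1 * self.tau1 + self.frac_intensity2 * self.tau2


def adaptive_foreground(
    intensity: np.ndarray,
    block_size: int = 31,
    sensitivity: float = 0.5,
    floor_fraction: float = 0.25,
) -> np.ndarray:
    """Locally adaptive intensity threshold marking NADH-emitting regions.

    A pixel is foreground when its intensity exceeds both ``sensitivity``
    times the local mean (``block_size`` window) and ``floor_fraction``
    times the global mean; the second term rejects dim-but-locally-uniform
    regions such as lipid droplets and background.  A constant positive
    image is all foreground whenever ``sensitivity + floor_fraction < 1``
    (the defaults); an all-zero image is all background.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity image must be non-negative")
    local_mean = uniform_filter(intensity, size=block_size, mode="reflect")
    return intensity > (sensitivity * local_mean + floor_fraction * intensity.mean())


def fit_image(
    cube: DecayCube,
    k: int = 3,
    n_components: int = 2,
    min_photons: float = 100.0,
    chi2_range: tuple[float, float] = (0.9, 1.3),
    foreground: np.ndarray | None = None,
    fit_offset: bool = False,
) -> FitImage:
    """Bin the cube and fit every foreground pixel's decay.

    Deterministic given the cube and settings.  Pixels whose fit fails are
    flagged (chi2 = inf) rather than aborting the image.
    """
    if n_components != 2 and n_components not in (1, 3):
        raise ValueError("n_components must be 1, 2, or 3")
    binned = bin_decays(cube, k)
    intensity = binned.intensity.astype(float)
    if foreground is None:
        foreground = adaptive_foreground(intensity)
    foreground = foreground & (intensity > 0)
    model = _DecayModel(cube.irf, cube.meta)
    ny, nx = intensity.shape

    shape = (ny, nx)
    planes = {
        name: np.full(shape, np.nan)
        for name in ("tau1", "tau2", "intensity1", "intensity2", "offset", "chi2")
    }
    idx = np.flatnonzero(foreground)
    if idx.size:
        y = binned.counts.reshape(-1, cube.meta.n_channels)[idx]
        res = _batched_varpro_fit(
            y, model, n_components=n_components, fit_offset=fit_offset
        )
        taus, inten = res["taus"], res["intensities"]
        if n_components == 1:
            taus = np.concatenate([taus, taus], axis=1)
            inten = np.concatenate([inten, np.zeros_like(inten)], axis=1)
        elif n_components == 3:
            # keep the two largest-intensity components for the 2-plane image
            keep = np.argsort(inten, axis=1)[:, -2:]
            keep.sort(axis=1)
            taus = np.take_along_axis(taus, keep, axis=1)
            inten = np.take_along_axis(inten, keep, axis=1)
        for name, values in (
            ("tau1", taus[:, 0]),
            ("tau2", taus[:, 1]),
            ("intensity1", inten[:, 0]),
            ("intensity2", inten[:, 1]),
            ("offset", res["offset"]),
            ("chi2", res["chi2"]),
        ):
            planes[name].flat[idx] = values

    fit = FitImage(
        tau1=planes["tau1"],
        tau2=planes["tau2"],
        intensity1=planes["intensity1"],
        intensity2=planes["intensity2"],
        offset=planes["offset"],
        chi2=planes["chi2"],
        photons=intensity,
        foreground_mask=foreground,
        qc_mask=np.zeros_like(foreground),
        meta=cube.meta,
        binning=k,
        settings={
            "n_components": n_components,
            "min_photons": min_photons,
            "chi2_range": chi2_range,
            "fit_offset": fit_offset,
        },
    )
    fit.qc_mask = qc_filter(fit, min_photons=min_photons, chi2_range=chi2_range)
    return fit


def qc_filter(
    fit: FitImage,
    min_photons: float = 100.0,
    chi2_range: tuple[float, float] = (0.9, 1.3),
) -> np.ndarray:
    """Quality-control mask: photons strictly above the floor, chi-square
    inside the inclusive window, and inside the foreground."""
    lo, hi = chi2_range
    with np.errstate(invalid="ignore"):
        ok = (
            (fit.photons > min_photons)
            & (fit.chi2 >= lo)
            & (fit.chi2 <= hi)
            & fit.foreground_mask
        )
    return ok
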