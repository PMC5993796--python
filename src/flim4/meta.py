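"""Acquisition metadata, instrument response, and decay-cube containers.

A TCSPC FLIM measurement is a 3-D histogram of photon arrival times: for
every pixel, photons are binned into time channels spanning one laser pulse
period.  :class:`AcquisitionMeta` carries the frame geometry and timing,
:class:`IRF` the recorded instrument response, and :class:`DecayCube` the
photon-count cube itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "IRF",
    "DecayCube",
    "gaussian_irf",
    "delta_irf",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Frame geometry and TCSPC timing.

    Defaults match a two-photon FLIM frame of 256 x 256 pixels over a
    105 x 105 um field of view at an 80 MHz repetition rate, with the full
    12.5 ns pulse period divided into 256 time channels (~48.8 ps each).
    """

    n_x: int = 256
    n_y: int = 256
    fov_um: float = 105.0
    n_channels: int = 256
    rep_rate_hz: float = 80e6
    channel_width_ns: float | None = None

    def __post_init__(self):
        if self.n_x < 1 or self.n_y < 1 or self.n_channels < 1:
            raise ValueError("pixel and channel counts must be positive")
        if self.fov_um <= 0:
            raise ValueError("fov_um must be positive")
        if self.rep_rate_hz <= 0:
            raise ValueError("rep_rate_hz must be positive")
        if self.channel_width_ns is None:
            object.__setattr__(
                self, "channel_width_ns", self.period_ns / self.n_channels
            )
        if self.n_channels * self.channel_width_ns > self.period_ns * (1 + 1e-9):
            raise ValueError(
                "time window exceeds the pulse period "
                f"({self.n_channels * self.channel_width_ns:.3f} ns > "
                f"{self.period_ns:.3f} ns)"
            )

    @property
    def period_ns(self) -> float:
        """Pulse period 1/f in ns."""
        return 1e9 / self.rep_rate_hz

    @property
    def pixel_pitch_um(self) -> float:
        return self.fov_um / self.n_x

    @property
    def times_ns(self) -> np.ndarray:
        """Channel-center times in ns."""
        return (np.arange(self.n_channels) + 0.5) * self.channel_width_ns

    def tile(self, n: int) -> "AcquisitionMeta":
        """A smaller n x n frame at the same pixel pitch and timing."""
        return AcquisitionMeta(
            n_x=n,
            n_y=n,
            fov_um=self.pixel_pitch_um * n,
            n_channels=self.n_channels,
            rep_rate_hz=self.rep_rate_hz,
            channel_width_ns=self.channel_width_ns,
        )


@dataclass(frozen=True)
class IRF:
    """Instrument response function sampled on the acquisition time axis."""

    curve: np.ndarray

    def __post_init__(self):
        curve = np.asarray(self.curve, dtype=float)
        if curve.ndim != 1:
            raise ValueError("IRF curve must be 1-D")
        if np.any(curve < 0):
            raise ValueError("IRF curve must be non-negative")
        if curve.sum() <= 0:
            raise ValueError("IRF curve must have positive total")
        object.__setattr__(self, "curve", curve)

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.curve))

    def normalized(self) -> np.ndarray:
        return self.curve / self.curve.sum()


def gaussian_irf(
    meta: AcquisitionMeta, fwhm_ns: float = 0.25, center_ns: float = 2.0
) -> IRF:
    """Gaussian pulse of the given FWHM, peaking ``center_ns`` into the window."""
    sigma = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = meta.times_ns
    curve = np.exp(-0.5 * ((t - center_ns) / sigma) ** 2)
    return IRF(curve=curve)


def delta_irf(meta: AcquisitionMeta, channel: int = 0) -> IRF:
    """Idealized instantaneous response: all weight in one channel."""
    curve = np.zeros(meta.n_channels)
    curve[channel] = 1.0
    return IRF(curve=curve)


@dataclass
class DecayCube:
    """Photon-count decay histogram indexed (y, x, channel).

    ``counts`` holds integers for sampled (Poisson) cubes and floats for
    noise-free expectation cubes; both flow through the same analysis.
    """

    counts: np.ndarray
    meta: AcquisitionMeta
    irf: IRF
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("counts must be 3-D (y, x, channel)")
        if counts.shape != (self.meta.n_y, self.meta.n_x, self.meta.n_channels):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with meta "
                f"({self.meta.n_y}, {self.meta.n_x}, {self.meta.n_channels})"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.irf.curve) != self.meta.n_channels:
            raise ValueError("IRF length must equal n_channels")
        self.counts = counts

    @property
    def intensity(self) -> np.ndarray:
        """Per-pixel total photon count (channel sum)."""
        return self.counts.sum(axis=-1)
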