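"""Drifting grating, plaid and correlated-noise stimulus synthesis.

All stimuli are luminance movies on a flat display spanning (by default)
120 deg of azimuth and 90 deg of elevation, with luminance in [0, 1] and
0.5 = mid-gray.  Direction convention: 0 deg = rightward drift, angles
increase counter-clockwise (so 90 deg drifts upward along +elevation).
Movies are generated at a reduced spatial resolution (default 64 x 48
pixels); a Nyquist guard enforces at least 4 samples per cycle of the
grating spatial frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "DisplayGeometry",
    "StimulusMovie",
    "make_grating",
    "make_plaid",
    "make_noise_movie",
    "PROTOCOL_DIRECTIONS",
]

#: the 12 drift directions of the recording protocol (deg)
PROTOCOL_DIRECTIONS = np.arange(0.0, 360.0, 30.0)

# HWHM of a Gaussian autocorrelation exp(-r^2 / (4 sigma_f^2)) in units of the
# filter sigma_f: r_half = 2 sigma_f sqrt(ln 2)
_HWHM_PER_SIGMA = 2.0 * np.sqrt(np.log(2.0))


@dataclass(frozen=True)
class DisplayGeometry:
    """Geometry of the stimulation display (flat-screen approximation).

    Pixels are square in degrees; ``degrees_per_pixel`` is derived from the
    azimuth extent and must tile the elevation extent to within one pixel.
    """

    azimuth_extent: float = 120.0
    elevation_extent: float = 90.0
    pixels_x: int = 64
    pixels_y: int = 48

    def __post_init__(self) -> None:
        if self.pixels_x <= 0 or self.pixels_y <= 0:
            raise ValueError("pixel counts must be positive")
        dpp = self.azimuth_extent / self.pixels_x
        if dpp <= 0:
            raise ValueError("degrees_per_pixel must be positive")
        if abs(self.pixels_y * dpp - self.elevation_extent) > dpp:
            raise ValueError(
                "pixels_y * degrees_per_pixel must match elevation_extent "
                "to within one pixel (square pixels assumed)"
            )

    @property
    def degrees_per_pixel(self) -> float:
        return self.azimuth_extent / self.pixels_x

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) pixel-center coordinate grids in degrees.

        x runs along azimuth (columns), y along elevation (rows, ascending
        with row index); both are centered on the display center.
        """
        d = self.degrees_per_pixel
        x = (np.arange(self.pixels_x) + 0.5) * d - self.azimuth_extent / 2.0
        y = (np.arange(self.pixels_y) + 0.5) * d - self.elevation_extent / 2.0
        return np.meshgrid(x, y)

    @property
    def n_pixels(self) -> int:
        return self.pixels_x * self.pixels_y


@dataclass
class StimulusMovie:
    """A luminance frame stack with geometry and rate metadata.

    frames has shape (n_frames, pixels_y, pixels_x) with values in [0, 1].
    """

    frames: np.ndarray
    frame_rate: float
    geometry: DisplayGeometry
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def contrast_frames(self) -> np.ndarray:
        """Luminance-contrast representation (luminance - 0.5)."""
        return self.frames - 0.5

    def to_hdf5(self, path, name: str = "movie") -> None:
        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            d = f.create_dataset(name, data=self.frames.astype(np.float32))
            d.attrs["frame_rate"] = self.frame_rate
            d.attrs["azimuth_extent"] = self.geometry.azimuth_extent
            d.attrs["elevation_extent"] = self.geometry.elevation_extent
            for k, v in self.meta.items():
                if v is not None:
                    d.attrs[f"meta_{k}"] = v

    @classmethod
    def from_hdf5(cls, path, name: str = "movie") -> "StimulusMovie":
        with h5py.File(path, "r") as f:
            d = f[name]
            frames = d[...]
            geom = DisplayGeometry(
                azimuth_extent=float(d.attrs["azimuth_extent"]),
                elevation_extent=float(d.attrs["elevation_extent"]),
                pixels_x=frames.shape[2],
                pixels_y=frames.shape[1],
            )
            meta = {
                k[5:]: v for k, v in d.attrs.items() if k.startswith("meta_")
            }
            return cls(frames, float(d.attrs["frame_rate"]), geom, meta)


def _n_frames(duration: float, frame_rate: float) -> int:
    if duration <= 0 or frame_rate <= 0:
        raise ValueError("duration and frame_rate must be positive")
    n = int(round(duration * frame_rate))
    if n < 1:
        raise ValueError("duration too short for one frame")
    return n


def _check_nyquist(sf: float, geometry: DisplayGeometry) -> None:
    # require >= 4 samples per cycle of the grating spatial frequency
    if sf > 0 and geometry.degrees_per_pixel > 1.0 / (4.0 * sf):
        raise ValueError(
            f"spatial frequency {sf} cpd undersampled at "
            f"{geometry.degrees_per_pixel:.3f} deg/pixel (need >= 4 "
            "samples per cycle)"
        )


def make_grating(
    direction: float,
    sf: float,
    tf: float,
    contrast: float = 1.0,
    duration: float = 1.5,
    frame_rate: float = 60.0,
    geometry: Optional[DisplayGeometry] = None,
    phase0: float = 0.0,
) -> StimulusMovie:
    """Full-field drifting sinusoidal grating.

    L(x, y, t) = 0.5 + 0.5 * contrast * cos(2 pi (sf * u - tf * t) + phase0)
    with u the spatial coordinate along the drift direction, so the pattern
    drifts toward ``direction`` at speed tf / sf deg/s.
    """
    if geometry is None:
        geometry = DisplayGeometry()
    if sf <= 0:
        raise ValueError("sf must be positive")
    if tf < 0:
        raise ValueError("tf must be non-negative")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    _check_nyquist(sf, geometry)
    direction = float(direction) % 360.0
    n = _n_frames(duration, frame_rate)

    x, y = geometry.grids()
    theta = np.deg2rad(direction)
    u = x * np.cos(theta) + y * np.sin(theta)
    t = np.arange(n) / frame_rate
    phase = (
        2.0 * np.pi * (sf * u[None, :, :] - tf * t[:, None, None]) + phase0
    )
    frames = 0.5 + 0.5 * contrast * np.cos(phase)
    return StimulusMovie(
        frames.astype(np.float32),
        frame_rate,
        geometry,
        meta={
            "kind": "grating",
            "direction": direction,
            "sf": sf,
            "tf": tf,
            "contrast": contrast,
        },
    )


def make_plaid(
    pattern_direction: float,
    cross_angle: float = 120.0,
    component_contrast: float = 0.5,
    sf: float = 0.02,
    tf: float = 2.0,
    duration: float = 1.5,
    frame_rate: float = 60.0,
    geometry: Optional[DisplayGeometry] = None,
    phase0: float = 0.0,
) -> StimulusMovie:
    """Plaid: additive superposition (around mid-gray) of two gratings
    drifting at pattern_direction +/- cross_angle / 2."""
    if not 0.0 <= cross_angle < 180.0:
        raise ValueError("cross_angle must lie in [0, 180)")
    if geometry is None:
        geometry = DisplayGeometry()
    half = cross_angle / 2.0
    comps = [
        make_grating(
            pattern_direction + s * half,
            sf,
            tf,
            component_contrast,
            duration,
            frame_rate,
            geometry,
            phase0,
        )
        for s in (-1.0, +1.0)
    ]
    frames = 0.5 + (comps[0].frames - 0.5) + (comps[1].frames - 0.5)
    lo, hi = frames.min(), frames.max()
    if lo < -1e-7 or hi > 1.0 + 1e-7:
        warnings.warn(
            "plaid luminance exceeds displayable range; clipping to [0, 1]",
            stacklevel=2,
        )
        frames = np.clip(frames, 0.0, 1.0)
    return StimulusMovie(
        frames.astype(np.float32),
        frame_rate,
        geometry,
        meta={
            "kind": "plaid",
            "direction": float(pattern_direction) % 360.0,
            "sf": sf,
            "tf": tf,
            "contrast": component_contrast,
            "cross_angle": cross_angle,
        },
    )


def make_noise_movie(
    seed: int,
    duration: float = 60.0,
    frame_rate: float = 30.0,
    spatial_corr: float = 12.0,
    temporal_corr: float = 0.08,
    contrast_mod_period: float = 10.0,
    contrast_mod_depth: float = 0.3,
    geometry: Optional[DisplayGeometry] = None,
) -> StimulusMovie:
    """Spatially and temporally correlated, contrast-modulated noise.

    Gaussian white noise is filtered with a recursive exponential (AR(1))
    kernel in time -- so the lag-1 frame correlation is exp(-dt /
    temporal_corr) -- and with a Gaussian kernel in space whose width is set
    so that ``spatial_corr`` is the half-width at half maximum of the spatial
    autocorrelation.  The field is then multiplied by a slow sinusoidal
    contrast envelope, clipped at 3 sigma, and mapped affinely into [0, 1]
    with mean 0.5.  The same seed always yields a bit-identical movie.
    """
    if geometry is None:
        geometry = DisplayGeometry()
    if spatial_corr <= 0 or temporal_corr <= 0 or contrast_mod_period <= 0:
        raise ValueError("correlation/modulation scales must be positive")
    if spatial_corr > min(geometry.azimuth_extent, geometry.elevation_extent):
        raise ValueError("spatial_corr exceeds the display extent")
    n = _n_frames(duration, frame_rate)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, geometry.pixels_y, geometry.pixels_x))

    # AR(1) along time: unit variance, lag-1 correlation a
    a = np.exp(-1.0 / (temporal_corr * frame_rate))
    x[0] /= np.sqrt(1.0 - a**2)  # start from the stationary distribution
    for i in range(1, n):
        x[i] = a * x[i - 1] + x[i]
    x *= np.sqrt(1.0 - a**2)

    sigma_px = (spatial_corr / _HWHM_PER_SIGMA) / geometry.degrees_per_pixel
    x = ndimage.gaussian_filter(x, sigma=(0.0, sigma_px, sigma_px), mode="wrap")
    x /= x.std()

    t = np.arange(n) / frame_rate
    envelope = 1.0 - contrast_mod_depth * 0.5 * (
        1.0 + np.sin(2.0 * np.pi * t / contrast_mod_period)
    )
    x *= envelope[:, None, None]
    np.clip(x, -3.0, 3.0, out=x)
    frames = 0.5 + x / 6.0
    return StimulusMovie(
        frames.astype(np.float32),
        frame_rate,
        geometry,
        meta={
            "kind": "noise",
            "seed": int(seed),
            "spatial_corr": spatial_corr,
            "temporal_corr": temporal_corr,
            "contrast_mod_period": contrast_mod_period,
        },
    )
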