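"""Spike-triggered-average receptive-field estimation from noise movies.

Pipeline per unit: raw STA at 10 time lags -> spectral decorrelation
(whitening by the stimulus spatial power spectrum, ridge-regularized) ->
pixelwise z-scoring against a permutation null (spike times redistributed
uniformly within the noise epochs) -> scalar summaries: contrast index
(CI), 2-D Gabor fit R^2, lobe count at 3.5 sigma, and the dominant
spatial frequency of the best frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, optimize
from skimage import measure

from .stimuli import DisplayGeometry, StimulusMovie

__all__ = [
    "STASequence",
    "GaborFit",
    "compute_sta",
    "stimulus_power_spectrum",
    "decorrelate",
    "permutation_zscore",
    "contrast_index",
    "fit_gabor",
    "count_lobes",
    "sta_spatial_frequency",
    "sta_for_unit",
    "spikes_to_frame_counts",
]

#: minimum spike count below which the STA is flagged low-confidence
MIN_SPIKES = 100
#: binarization threshold (|z|) for lobe counting
LOBE_THRESHOLD = 3.5
#: minimum connected-component area (pixels) counted as a lobe
LOBE_MIN_AREA = 4


@dataclass
class STASequence:
    """Lag-indexed STA frames with permutation z-scores and summaries."""

    z_frames: np.ndarray  # (n_lags, ny, nx) pixelwise z-scores
    raw_frames: np.ndarray  # decorrelated STA, contrast units
    lag_times: np.ndarray  # seconds before spike generation
    ci_per_lag: np.ndarray
    geometry: DisplayGeometry
    n_spikes: int
    n_permutations: int
    seed: Optional[int] = None
    null_ci: Optional[np.ndarray] = None  # (n_perm, n_lags) null CI draws
    low_confidence: bool = False

    @property
    def n_lags(self) -> int:
        return self.z_frames.shape[0]

    @property
    def best_lag(self) -> int:
        return int(np.argmax(self.ci_per_lag))

    def to_hdf5(self, path, name: str = "sta") -> None:
        import h5py

        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.create_dataset("z_frames", data=self.z_frames)
            g.create_dataset("raw_frames", data=self.raw_frames)
            g.create_dataset("lag_times", data=self.lag_times)
            g.create_dataset("ci_per_lag", data=self.ci_per_lag)
            if self.null_ci is not None:
                g.create_dataset("null_ci", data=self.null_ci)
            g.attrs["n_spikes"] = self.n_spikes
            g.attrs["n_permutations"] = self.n_permutations
            g.attrs["seed"] = -1 if self.seed is None else self.seed
            g.attrs["low_confidence"] = self.low_confidence
            g.attrs["azimuth_extent"] = self.geometry.azimuth_extent
            g.attrs["elevation_extent"] = self.geometry.elevation_extent

    @classmethod
    def from_hdf5(cls, path, name: str = "sta") -> "STASequence":
        import h5py

        with h5py.File(path, "r") as f:
            g = f[name]
            z = g["z_frames"][...]
            geom = DisplayGeometry(
                azimuth_extent=float(g.attrs["azimuth_extent"]),
                elevation_extent=float(g.attrs["elevation_extent"]),
                pixels_x=z.shape[2],
                pixels_y=z.shape[1],
            )
            seed = int(g.attrs["seed"])
            return cls(
                z_frames=z,
                raw_frames=g["raw_frames"][...],
                lag_times=g["lag_times"][...],
                ci_per_lag=g["ci_per_lag"][...],
                geometry=geom,
                n_spikes=int(g.attrs["n_spikes"]),
                n_permutations=int(g.attrs["n_permutations"]),
                seed=None if seed < 0 else seed,
                null_ci=g["null_ci"][...] if "null_ci" in g else None,
                low_confidence=bool(g.attrs["low_confidence"]),
            )


@dataclass
class GaborFit:
    center: tuple  # (x, y) deg
    orientation: float  # deg, mod 180
    sf: float  # cpd
    phase: float  # rad
    sigma_major: float  # deg
    sigma_minor: float  # deg
    amplitude: float
    r2: float
    converged: bool = True


def spikes_to_frame_counts(
    spikes: np.ndarray, onset: float, n_frames: int, frame_rate: float
) -> np.ndarray:
    """Bin a spike train into per-frame counts of one movie presentation."""
    rel = spikes[(spikes >= onset) & (spikes < onset + n_frames / frame_rate)]
    idx = np.floor((rel - onset) * frame_rate).astype(int)
    counts = np.bincount(idx, minlength=n_frames)
    return counts[:n_frames]


def compute_sta(
    counts_per_movie: list,
    movies: list,
    n_lags: int = 10,
) -> tuple[np.ndarray, int]:
    """Raw spike-triggered average at ``n_lags`` time lags.

    The frame at lag k is the spike-count-weighted mean of the contrast
    frames k steps before each spike; movie boundaries are respected (lags
    never reach across presentations).  Returns (frames, n_spikes); a
    warning flags spike counts below :data:`MIN_SPIKES`.
    """
    geom = movies[0].geometry
    shape = (n_lags, geom.pixels_y, geom.pixels_x)
    sums = np.zeros(shape)
    wsum = np.zeros(n_lags)
    total = 0
    for counts, movie in zip(counts_per_movie, movies):
        counts = np.asarray(counts, dtype=float)
        C = movie.contrast_frames().reshape(movie.n_frames, -1)
        total += int(counts.sum())
        for k in range(n_lags):
            c = counts[k:]
            if not len(c):
                continue
            sums[k] += (c @ C[: len(c)]).reshape(shape[1:])
            wsum[k] += c.sum()
    if total < MIN_SPIKES:
        warnings.warn(
            f"only {total} spikes during noise stimulation; STA is "
            "low-confidence",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        frames = sums / wsum[:, None, None]
    frames[wsum == 0] = 0.0
    return frames, total


def stimulus_power_spectrum(movies: list) -> np.ndarray:
    """Spatial power spectrum of the noise ensemble (mean over frames)."""
    acc = None
    n = 0
    for movie in movies:
        C = movie.contrast_frames()
        F = np.fft.fft2(C, axes=(1, 2))
        p = (np.abs(F) ** 2).sum(axis=0)
        acc = p if acc is None else acc + p
        n += C.shape[0]
    return acc / n


def stimulus_temporal_autocorr(movies: list, n_lags: int = 10) -> np.ndarray:
    """Mean pixelwise temporal autocorrelation of the ensemble at frame
    lags 0..n_lags-1 (normalized to rho[0] = 1)."""
    acc = np.zeros(n_lags)
    norm = np.zeros(n_lags)
    for movie in movies:
        C = movie.contrast_frames().reshape(movie.n_frames, -1).astype(float)
        C = C - C.mean(axis=0)
        for k in range(n_lags):
            T = C.shape[0] - k
            if T <= 0:
                continue
            acc[k] += (C[k:] * C[:T]).sum()
            norm[k] += T
    rho = acc / np.maximum(norm, 1)
    if rho[0] <= 0:
        raise ValueError("degenerate stimulus temporal autocorrelation")
    return rho / rho[0]


def _temporal_whitener(
    temporal_autocorr: np.ndarray, ridge_fraction: float
) -> np.ndarray:
    from scipy.linalg import toeplitz

    R = toeplitz(temporal_autocorr)
    return np.linalg.inv(R + ridge_fraction * np.eye(len(R)))


def decorrelate(
    raw_frames: np.ndarray,
    power_spectrum: np.ndarray,
    ridge_fraction: float = 0.1,
    temporal_autocorr: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Whiten STA frames by the stimulus correlation structure.

    Per lag, the STA's 2-D spectrum is divided by the stimulus spatial
    power spectrum (P + ridge_fraction * max(P)); if a temporal
    autocorrelation vector is given, the lag axis is additionally
    deconvolved by the (ridge-regularized) Toeplitz correlation matrix.
    Output is rescaled to the raw frames' norm (scale is immaterial
    downstream).  For a white stimulus this is the identity up to scale.
    """
    P = np.asarray(power_spectrum, dtype=float)
    if P.max() <= 0:
        raise ValueError("degenerate stimulus power spectrum")
    denom = P + ridge_fraction * P.max()
    out = np.empty_like(raw_frames, dtype=float)
    for k, frame in enumerate(raw_frames):
        F = np.fft.fft2(frame)
        out[k] = np.real(np.fft.ifft2(F / denom))
    if temporal_autocorr is not None:
        W = _temporal_whitener(temporal_autocorr, ridge_fraction)
        out = np.tensordot(W, out, axes=(1, 0))
    norm_in = np.linalg.norm(raw_frames)
    norm_out = np.linalg.norm(out)
    if norm_out > 0:
        out *= norm_in / norm_out
    return out


def permutation_zscore(
    counts_per_movie: list,
    movies: list,
    n_perm: int = 200,
    seed: int = 0,
    n_lags: int = 10,
    ridge_fraction: float = 0.1,
    power_spectrum: Optional[np.ndarray] = None,
    temporal_whitening: bool = False,
) -> STASequence:
    """STA sequence z-scored pixelwise against a permutation null.

    The null redistributes the observed number of spikes uniformly over
    the noise-stimulation frames (per permutation), recomputes the
    decorrelated STA, and z-scores the observed decorrelated STA by the
    null mean and SD at each pixel and lag.  Pixels with zero null SD get
    z = 0 with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    geom = movies[0].geometry
    P_pix = geom.n_pixels

    raw, n_spikes = compute_sta(counts_per_movie, movies, n_lags)
    if power_spectrum is None:
        power_spectrum = stimulus_power_spectrum(movies)
    obs = decorrelate(
        raw, power_spectrum, ridge_fraction,
        stimulus_temporal_autocorr(movies, n_lags) if temporal_whitening
        else None,
    )

    lens = [len(c) for c in counts_per_movie]
    edges = np.concatenate([[0], np.cumsum(lens)])
    total_frames = edges[-1]

    # permutation spike counts: n_spikes uniform draws over all frames
    null_sums = np.zeros((n_perm, n_lags, P_pix), dtype=np.float32)
    null_w = np.zeros((n_perm, n_lags))
    draws = rng.integers(0, total_frames, size=(n_perm, n_spikes))
    for m, movie in enumerate(movies):
        lo, hi = edges[m], edges[m + 1]
        T = hi - lo
        C = np.ascontiguousarray(
            movie.contrast_frames().reshape(T, -1), dtype=np.float32
        )
        counts = np.zeros((n_perm, T), dtype=np.float32)
        inside = (draws >= lo) & (draws < hi)
        rows = np.repeat(np.arange(n_perm), inside.sum(axis=1))
        cols = draws[inside] - lo
        np.add.at(counts, (rows, cols), 1.0)
        for k in range(n_lags):
            ck = counts[:, k:]
            if ck.shape[1] == 0:
                continue
            null_sums[:, k, :] += ck @ C[: ck.shape[1]]
            null_w[:, k] += ck.sum(axis=1)

    with np.errstate(invalid="ignore"):
        null_sta = null_sums / null_w[:, :, None]
    null_sta[null_w == 0] = 0.0

    # decorrelate the null STAs with the same whitening filter
    denom = power_spectrum + ridge_fraction * power_spectrum.max()
    ny, nx = geom.pixels_y, geom.pixels_x
    null_dec = np.real(
        np.fft.ifft2(
            np.fft.fft2(null_sta.reshape(n_perm, n_lags, ny, nx), axes=(2, 3))
            / denom,
            axes=(2, 3),
        )
    )
    if temporal_whitening:
        W = _temporal_whitener(
            stimulus_temporal_autocorr(movies, n_lags), ridge_fraction
        )
        null_dec = np.einsum("kl,plyx->pkyx", W, null_dec)
    # match the observed decorrelation's rescaling convention per draw
    raw_norm = np.linalg.norm(
        null_sta.reshape(n_perm, -1), axis=1, keepdims=True
    )
    dec_norm = np.linalg.norm(
        null_dec.reshape(n_perm, -1), axis=1, keepdims=True
    )
    scale = np.where(dec_norm > 0, raw_norm / np.maximum(dec_norm, 1e-30), 1.0)
    null_dec *= scale.reshape(n_perm, 1, 1, 1)

    mu = null_dec.mean(axis=0)
    sd = null_dec.std(axis=0, ddof=0)
    z = np.zeros_like(obs)
    bad = sd == 0
    if bad.any():
        warnings.warn("zero null SD at some pixels; their z set to 0",
                      stacklevel=2)
    np.divide(obs - mu, sd, out=z, where=~bad)

    null_z = np.zeros_like(null_dec)
    np.divide(
        null_dec - mu[None], sd[None], out=null_z,
        where=~np.broadcast_to(bad, null_dec.shape),
    )
    null_ci = np.array(
        [[contrast_index(f) for f in perm] for perm in null_z]
    )

    lag_step = 1.0 / movies[0].frame_rate
    return STASequence(
        z_frames=z,
        raw_frames=obs,
        lag_times=np.arange(n_lags) * lag_step,
        ci_per_lag=np.array([contrast_index(f) for f in z]),
        geometry=geom,
        n_spikes=n_spikes,
        n_permutations=n_perm,
        seed=seed,
        null_ci=null_ci,
        low_confidence=n_spikes < MIN_SPIKES,
    )


def contrast_index(z_frame: np.ndarray, top_fraction: float = 0.01) -> float:
    """CI: mean of the top ``top_fraction`` of |z| values in the frame."""
    a = np.abs(np.asarray(z_frame, dtype=float)).ravel()
    k = max(1, int(round(top_fraction * a.size)))
    return float(np.mean(np.partition(a, -k)[-k:]))


def _gabor_model(params, x, y):
    x0, y0, theta, sf, phase, s_maj, s_min, amp = params
    xr = (x - x0) * np.cos(theta) + (y - y0) * np.sin(theta)
    yr = -(x - x0) * np.sin(theta) + (y - y0) * np.cos(theta)
    env = np.exp(-(xr**2) / (2 * s_min**2) - (yr**2) / (2 * s_maj**2))
    return amp * env * np.cos(2 * np.pi * sf * xr + phase)


def fit_gabor(
    z_frame: np.ndarray,
    geometry: Optional[DisplayGeometry] = None,
    n_starts: int = 8,
) -> GaborFit:
    """Least-squares 2-D Gabor fit of an STA frame.

    Multi-start over ``n_starts`` seed orientations; R^2 is the fraction of
    variance explained.  A fit that fails everywhere is returned with
    converged=False and r2 = nan.
    """
    if geometry is None:
        geometry = DisplayGeometry(
            pixels_x=z_frame.shape[1],
            pixels_y=z_frame.shape[0],
            azimuth_extent=float(z_frame.shape[1]),
            elevation_extent=float(z_frame.shape[0]),
        )
    x, y = geometry.grids()
    z = np.asarray(z_frame, dtype=float)
    ss_tot = float(((z - z.mean()) ** 2).sum())
    if ss_tot == 0:
        return GaborFit((0, 0), 0, 0, 0, 1, 1, 0, float("nan"), False)

    iy, ix = np.unravel_index(np.argmax(np.abs(z)), z.shape)
    x0, y0 = x[iy, ix], y[iy, ix]
    amp0 = z[iy, ix]
    half_x = geometry.azimuth_extent / 2.0
    half_y = geometry.elevation_extent / 2.0
    sig0 = min(half_x, half_y) / 3.0
    dpp = geometry.degrees_per_pixel
    sf_hi = 1.0 / (2.0 * dpp)
    lb = [-half_x, -half_y, -np.pi, 1e-4, -np.pi, dpp, dpp, -10 * abs(amp0)]
    ub = [half_x, half_y, 2 * np.pi, sf_hi, np.pi, 2 * half_y, 2 * half_y,
          10 * abs(amp0)]

    best = None
    best_cost = np.inf
    for theta0 in np.linspace(0, np.pi, n_starts, endpoint=False):
        p0 = [x0, y0, theta0, 0.02, 0.0, sig0, sig0 / 2.0, amp0]
        p0 = np.clip(p0, lb, ub)
        try:
            res = optimize.least_squares(
                lambda p: (_gabor_model(p, x, y) - z).ravel(),
                p0,
                bounds=(lb, ub),
                max_nfev=300,
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        return GaborFit((x0, y0), 0, 0, 0, 1, 1, 0, float("nan"), False)
    x0, y0, theta, sf, phase, s_maj, s_min, amp = best.x
    r2 = 1.0 - 2.0 * best.cost / ss_tot
    # orientation of the carrier stripes, mod 180 deg
    orientation = (np.rad2deg(theta) + 90.0) % 180.0
    return GaborFit(
        center=(float(x0), float(y0)),
        orientation=float(orientation),
        sf=float(sf),
        phase=float(phase),
        sigma_major=float(max(s_maj, s_min)),
        sigma_minor=float(min(s_maj, s_min)),
        amplitude=float(amp),
        r2=float(np.clip(r2, 0.0, 1.0)),
        converged=True,
    )


def count_lobes(
    z_frames: np.ndarray,
    threshold: float = LOBE_THRESHOLD,
    min_area: int = LOBE_MIN_AREA,
    ci_per_lag: Optional[np.ndarray] = None,
) -> tuple[int, int]:
    """(best_frame_index, n_lobes): connected suprathreshold regions
    (positive and negative counted separately, 8-connectivity, area >=
    ``min_area``) in the frame with the largest CI."""
    z_frames = np.asarray(z_frames, dtype=float)
    if z_frames.ndim == 2:
        z_frames = z_frames[None]
    if ci_per_lag is None:
        ci_per_lag = np.array([contrast_index(f) for f in z_frames])
    best = int(np.argmax(ci_per_lag))
    frame = z_frames[best]
    n = 0
    for mask in (frame > threshold, frame < -threshold):
        labels = measure.label(mask, connectivity=2)
        for region in measure.regionprops(labels):
            if region.area >= min_area:
                n += 1
    return best, n


def sta_spatial_frequency(
    z_frames: np.ndarray,
    geometry: DisplayGeometry,
    ci_per_lag: Optional[np.ndarray] = None,
    pad_factor: int = 4,
) -> float:
    """Dominant spatial frequency (cpd) of the best-CI STA frame.

    Radial peak of the zero-padded 2-D amplitude spectrum, excluding DC;
    invariant to frame amplitude scaling.
    """
    z_frames = np.asarray(z_frames, dtype=float)
    if z_frames.ndim == 2:
        z_frames = z_frames[None]
    if ci_per_lag is None:
        ci_per_lag = np.array([contrast_index(f) for f in z_frames])
    frame = z_frames[int(np.argmax(ci_per_lag))]
    ny, nx = frame.shape
    d = geometry.degrees_per_pixel
    # mean-subtract and window to keep DC leakage out of the low rings
    frame = frame - frame.mean()
    frame = frame * np.outer(np.hanning(ny), np.hanning(nx))
    amp = np.abs(np.fft.rfft2(frame, s=(ny * pad_factor, nx * pad_factor)))
    fy = np.fft.fftfreq(ny * pad_factor, d=d)
    fx = np.fft.rfftfreq(nx * pad_factor, d=d)
    fr = np.hypot(fy[:, None], fx[None, :])
    # dominant SF = radial position of the global spectral peak (DC masked);
    # a ring average would bias low for oriented spectra (1/r arc dilution)
    df = 1.0 / (max(nx, ny) * pad_factor * d)
    amp = np.where(fr < df, 0.0, amp)
    iy, ix = np.unravel_index(np.argmax(amp), amp.shape)
    return float(fr[iy, ix])


def sta_for_unit(
    session,
    unit_id: int,
    n_perm: int = 200,
    n_lags: int = 10,
    ridge_fraction: float = 0.1,
    seed: int = 0,
    movies: Optional[list] = None,
    power_spectrum: Optional[np.ndarray] = None,
) -> STASequence:
    """Convenience wrapper: STA sequence of one session unit from the
    session's noise presentations."""
    noise = session.noise_trials().sort_values("noise_index")
    if movies is None:
        movies = [session.noise_movie(int(i)) for i in noise.noise_index]
    spikes = session.unit_spikes(unit_id)
    counts = [
        spikes_to_frame_counts(
            spikes, float(row.onset), m.n_frames, m.frame_rate
        )
        for (_, row), m in zip(noise.iterrows(), movies)
    ]
    return permutation_zscore(
        counts,
        movies,
        n_perm=n_perm,
        seed=seed,
        n_lags=n_lags,
        ridge_fraction=ridge_fraction,
        power_spectrum=power_spectrum,
    )
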