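"""Synthetic model neurons with known ground-truth class.

Four unit kinds exercise the full analysis pipeline:

``ln_component``
    Linear-nonlinear unit with a high-aspect-ratio space-time Gabor filter:
    an elongated, direction-selective edge detector.  Classified component.
``ln_blobby``
    Same LN architecture with a low-aspect-ratio ("blobby") filter whose
    broad direction tuning merges the two plaid peaks -- a purely linear
    pattern mimic.
``energy_complex``
    Phase-invariant energy unit: sum of squared outputs of a quadrature
    Gabor pair (complex-cell analog, weak response modulation).
``pooled_pattern``
    Nonlinear motion integrator: motion-energy (quadrature-pair) subunits
    spanning the direction circle are pooled with signed cosine weights
    centered on the unit's preferred direction (motion-opponent pooling),
    then rectified.  Its plaid tuning follows the pattern prediction, and
    no single linear filter reproduces it.

Spiking is inhomogeneous Poisson on top of a spontaneous baseline rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .stimuli import (
    DisplayGeometry,
    PROTOCOL_DIRECTIONS,
    StimulusMovie,
    make_grating,
    make_noise_movie,
    make_plaid,
)

__all__ = [
    "SpaceTimeFilter",
    "ModelUnit",
    "Session",
    "make_drifting_gabor_filter",
    "make_unit",
    "simulate_rate",
    "generate_spikes",
    "make_session",
    "make_regressor_bank",
    "default_population_config",
    "default_protocol_config",
]

UNIT_KINDS = ("ln_component", "ln_blobby", "energy_complex", "pooled_pattern")
GROUND_TRUTH_LABEL = {
    "ln_component": "component",
    "ln_blobby": "blobby_linear",
    "energy_complex": "complex",
    "pooled_pattern": "pattern",
}


@dataclass
class SpaceTimeFilter:
    """Spatiotemporal linear filter in luminance-contrast units.

    weights has shape (n_lags, pixels_y, pixels_x); lag k acts on the
    stimulus k * lag_step seconds before the present.
    """

    weights: np.ndarray
    lag_step: float
    geometry: DisplayGeometry

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")
        if self.weights.shape[1:] != (
            self.geometry.pixels_y,
            self.geometry.pixels_x,
        ):
            raise ValueError("filter shape does not match geometry")

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]


@dataclass
class ModelUnit:
    unit_id: int
    kind: str
    filters: list
    nonlinearity: dict
    gain: float
    baseline_rate: float
    ground_truth_label: str
    pooling: Optional[dict] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.kind == "pooled_pattern":
            dirs = np.asarray(self.pooling["subunit_directions"])
            if len(dirs) < 3 or np.ptp(dirs) < 90.0:
                raise ValueError(
                    "pooled_pattern needs >= 3 subunits spanning >= 90 deg"
                )


def make_drifting_gabor_filter(
    pref_direction: float,
    sf: float = 0.02,
    tf: float = 2.0,
    aspect_ratio: float = 3.0,
    envelope_sigma: float = 10.0,
    n_lags: int = 10,
    lag_step: float = 1.0 / 30.0,
    geometry: Optional[DisplayGeometry] = None,
    phase0: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> SpaceTimeFilter:
    """Space-time-oriented Gabor filter preferring drift along pref_direction.

    The spatial carrier phase advances across lags at rate ``tf`` so that
    stimulus energy drifting toward ``pref_direction`` sums coherently over
    lags while the opposite direction cancels.  ``envelope_sigma`` (deg) is
    the Gaussian envelope width along the drift axis; the width along the
    orthogonal (orientation) axis is ``aspect_ratio * envelope_sigma``:
    high aspect ratio = elongated edge detector, low = blobby.  A Hann
    window over lags keeps the temporal support compact; ``tf = 0`` yields
    a static (non-direction-selective) filter.
    """
    if geometry is None:
        geometry = DisplayGeometry()
    if aspect_ratio <= 0:
        raise ValueError("aspect_ratio must be positive")
    if envelope_sigma <= 0:
        raise ValueError("envelope_sigma must be positive")
    sigma_u = envelope_sigma
    sigma_v = aspect_ratio * envelope_sigma
    half_extent = min(geometry.azimuth_extent, geometry.elevation_extent) / 2.0
    if max(sigma_u, sigma_v) > half_extent:
        raise ValueError("filter spatial support exceeds the display")

    x, y = geometry.grids()
    x = x - center[0]
    y = y - center[1]
    theta = np.deg2rad(float(pref_direction) % 360.0)
    u = x * np.cos(theta) + y * np.sin(theta)  # along drift
    v = -x * np.sin(theta) + y * np.cos(theta)  # along orientation
    envelope = np.exp(-(u**2) / (2 * sigma_u**2) - (v**2) / (2 * sigma_v**2))

    lags = np.arange(n_lags) * lag_step
    # temporal Hann envelope peaking at the middle lag
    g = np.hanning(n_lags + 2)[1:-1]
    weights = np.empty((n_lags, *u.shape))
    for k in range(n_lags):
        carrier = np.cos(2 * np.pi * sf * u + 2 * np.pi * tf * lags[k] + phase0)
        weights[k] = g[k] * envelope * carrier
    weights /= np.linalg.norm(weights)
    return SpaceTimeFilter(weights, lag_step, geometry)


def _lag_step_frames(lag_step: float, frame_rate: float) -> int:
    s = lag_step * frame_rate
    step = int(round(s))
    if step < 1 or abs(s - step) > 1e-6:
        raise ValueError(
            "movie frame rate must be an integer multiple of 1 / lag_step"
        )
    return step


def filter_drive(filt: SpaceTimeFilter, movie: StimulusMovie) -> np.ndarray:
    """Linear drive time series of one filter applied to a movie.

    drive[t] = sum_k <w_k, contrast(t - k * lag_step)>; frames before movie
    onset are treated as mid-gray (zero contrast).
    """
    if (
        movie.geometry.pixels_x != filt.geometry.pixels_x
        or movie.geometry.pixels_y != filt.geometry.pixels_y
    ):
        raise ValueError("movie geometry does not match filter geometry")
    step = _lag_step_frames(filt.lag_step, movie.frame_rate)
    T = movie.n_frames
    C = movie.contrast_frames().reshape(T, -1)
    W = filt.weights.reshape(filt.n_lags, -1)
    proj = C @ W.T.astype(C.dtype)  # (T, n_lags)
    drive = np.zeros(T)
    for k in range(filt.n_lags):
        off = k * step
        if off >= T:
            break
        drive[off:] += proj[: T - off, k]
    return drive


def _rectify(x: np.ndarray, threshold: float, exponent: float) -> np.ndarray:
    r = np.maximum(x - threshold, 0.0)
    if exponent != 1.0:
        r = r**exponent
    return r


def pooled_contrast(
    movie: StimulusMovie, smooth_window: float = 1.0 / 3.0
) -> np.ndarray:
    """Per-frame RMS luminance contrast of the stimulus, smoothed over
    ``smooth_window`` seconds -- the unselective normalization pool."""
    C = movie.contrast_frames().reshape(movie.n_frames, -1)
    rms = np.sqrt((C.astype(float) ** 2).mean(axis=1))
    n = max(1, int(round(smooth_window * movie.frame_rate)))
    if n > 1:
        from scipy.ndimage import uniform_filter1d

        rms = uniform_filter1d(rms, n, mode="nearest")
    return rms


def unit_drive(unit: ModelUnit, movie: StimulusMovie) -> np.ndarray:
    """Nonlinear drive (before gain and baseline) of a unit to a movie.

    Filter outputs are divisively normalized by the pooled stimulus
    contrast (plus a semi-saturation constant c50) before the output
    nonlinearity -- the standard contrast-gain-control stage.  The pool is
    unselective, so it rescales responses per stimulus without changing
    direction-tuning shapes.
    """
    nl = unit.nonlinearity
    c50 = nl.get("normalization_c50", 0.0)
    if c50 > 0:
        norm = pooled_contrast(movie) + c50
    else:
        norm = np.ones(movie.n_frames)

    if unit.kind in ("ln_component", "ln_blobby"):
        d = filter_drive(unit.filters[0], movie) / norm
        return _rectify(d, nl["threshold"], nl["exponent"])
    if unit.kind == "energy_complex":
        d0 = filter_drive(unit.filters[0], movie) / norm
        d1 = filter_drive(unit.filters[1], movie) / norm
        return d0**2 + d1**2
    if unit.kind == "pooled_pattern":
        w = np.asarray(unit.pooling["weights"])
        leak = unit.pooling.get("linear_leak", 0.0)
        pooled = np.zeros(movie.n_frames)
        for i, wi in enumerate(w):
            d0 = filter_drive(unit.filters[2 * i], movie) / norm
            d1 = filter_drive(unit.filters[2 * i + 1], movie) / norm
            energy = d0**2 + d1**2
            if leak > 0:
                energy = energy + leak * np.maximum(d0, 0.0) ** 2
            pooled += wi * energy
        return _rectify(pooled, nl["threshold"], nl["exponent"])
    raise ValueError(f"unknown unit kind: {unit.kind}")


def simulate_rate(unit: ModelUnit, movie: StimulusMovie) -> np.ndarray:
    """Firing rate (spikes/s per frame): baseline + gain * N(drive)."""
    if movie.n_frames * (1.0 / movie.frame_rate) <= unit.filters[0].n_lags * (
        unit.filters[0].lag_step
    ):
        raise ValueError("movie shorter than the filter lag span")
    return unit.baseline_rate + unit.gain * unit_drive(unit, movie)


def make_unit(
    kind: str,
    params: Optional[dict] = None,
    seed: int = 0,
    unit_id: int = 0,
    geometry: Optional[DisplayGeometry] = None,
) -> ModelUnit:
    """Factory for the four synthetic unit kinds.

    The output gain is calibrated so that the noiseless response to the
    unit's preferred full-contrast grating peaks at ``target_peak_rate``
    spikes/s above baseline.
    """
    if kind not in UNIT_KINDS:
        raise ValueError(f"unknown unit kind: {kind}")
    if geometry is None:
        geometry = DisplayGeometry()
    p = {
        "pref_direction": 0.0,
        "sf": 0.02,
        "tf": 2.0,
        "aspect_ratio": 3.0 if kind != "ln_blobby" else 0.3,
        "envelope_sigma": 10.0,
        "n_lags": 10,
        "lag_step": 1.0 / 30.0,
        "phase0": 0.0,
        "center": (0.0, 0.0),
        "threshold": 0.0,
        # expansive output nonlinearity (half-wave rectification to a power);
        # the blobby mimics get a stronger expansion, which sharpens their
        # merged plaid peak and stabilizes their pattern-like readout; the
        # pooled pattern units operate on energies (already squared)
        "exponent": {"ln_blobby": 3.0, "pooled_pattern": 1.0}.get(kind, 2.0),
        "normalization_c50": 0.01,  # contrast-gain-control semi-saturation
        "baseline_rate": 1.0,
        "target_peak_rate": 30.0,
        # pooled_pattern only: subunit ring and signed cosine weights
        "subunit_step": 30.0,
        "fan_half_width": 180.0,
        "subunit_aspect_ratio": 3.0,
        "subunit_linear_leak": 0.2,
    }
    if params:
        p.update(params)

    common = dict(
        sf=p["sf"],
        tf=p["tf"],
        envelope_sigma=p["envelope_sigma"],
        n_lags=p["n_lags"],
        lag_step=p["lag_step"],
        geometry=geometry,
        center=tuple(p["center"]),
    )
    pooling = None
    if kind in ("ln_component", "ln_blobby"):
        filters = [
            make_drifting_gabor_filter(
                p["pref_direction"],
                aspect_ratio=p["aspect_ratio"],
                phase0=p["phase0"],
                **common,
            )
        ]
    elif kind == "energy_complex":
        filters = [
            make_drifting_gabor_filter(
                p["pref_direction"],
                aspect_ratio=p["aspect_ratio"],
                phase0=p["phase0"] + q,
                **common,
            )
            for q in (0.0, np.pi / 2.0)
        ]
    else:  # pooled_pattern
        offsets = np.arange(
            -p["fan_half_width"], p["fan_half_width"] + 1e-9, p["subunit_step"]
        )
        # avoid duplicating the -180/+180 subunit on a full ring
        if p["fan_half_width"] >= 180.0:
            offsets = offsets[offsets < 180.0]
        dirs = (p["pref_direction"] + offsets) % 360.0
        weights = np.cos(np.deg2rad(offsets))
        # motion-energy afferents: each subunit is a quadrature Gabor pair
        # (phase-invariant), so the pooled unit inherits no dominant linear
        # kernel and its STA largely cancels; a small linear leak on the
        # in-phase filter leaves the weak residual RF structure seen in
        # real pattern cells.  Random spatial phases decorrelate residues.
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, len(dirs))
        filters = []
        for d, ph in zip(dirs, phases):
            for q in (0.0, np.pi / 2.0):
                filters.append(
                    make_drifting_gabor_filter(
                        d,
                        aspect_ratio=p["subunit_aspect_ratio"],
                        phase0=p["phase0"] + ph + q,
                        **common,
                    )
                )
        pooling = {
            "subunit_directions": dirs,
            "weights": weights,
            "n_subunits": len(dirs),
            "linear_leak": p["subunit_linear_leak"],
        }

    unit = ModelUnit(
        unit_id=unit_id,
        kind=kind,
        filters=filters,
        nonlinearity={
            "threshold": p["threshold"],
            "exponent": p["exponent"],
            "normalization_c50": p["normalization_c50"],
        },
        gain=1.0,
        baseline_rate=p["baseline_rate"],
        ground_truth_label=GROUND_TRUTH_LABEL[kind],
        pooling=pooling,
        params=p,
    )

    # gain calibration on the preferred grating, at the filter's native rate
    cal = make_grating(
        p["pref_direction"],
        p["sf"],
        p["tf"],
        contrast=1.0,
        duration=1.5,
        frame_rate=1.0 / p["lag_step"],
        geometry=geometry,
    )
    peak = unit_drive(unit, cal).max()
    if peak <= 0:
        raise ValueError("unit does not respond to its preferred grating")
    unit.gain = p["target_peak_rate"] / peak
    return unit


def generate_spikes(
    rate_trace: np.ndarray,
    frame_rate: float,
    n_trials: int = 20,
    seed: int = 0,
) -> list[np.ndarray]:
    """Inhomogeneous Poisson spike trains from a frame-rate trace.

    Returns one sorted array of spike times (s, relative to trace onset)
    per trial; counts per frame are Poisson with mean rate * dt and spike
    times are uniform within the frame.
    """
    rate_trace = np.asarray(rate_trace, dtype=float)
    if np.any(rate_trace < 0):
        raise ValueError("rates must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    lam = rate_trace * dt
    trials = []
    for _ in range(n_trials):
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            trials.append(np.empty(0))
            continue
        frame_idx = np.repeat(np.arange(len(lam)), counts)
        times = (frame_idx + rng.random(total)) * dt
        trials.append(np.sort(times))
    return trials


def default_protocol_config() -> dict:
    """The recording-session stimulus protocol used throughout."""
    return {
        "sfs": [0.02, 0.04],
        "tfs": [2.0, 6.0],
        "directions": list(PROTOCOL_DIRECTIONS),
        "cross_angle": 120.0,
        "component_contrast": 0.5,
        "n_trials": 20,
        "duration": 1.5,
        "isi": 1.0,
        "grating_frame_rate": 60.0,
        "noise": {
            "n_movies": 20,
            "duration": 60.0,
            "frame_rate": 30.0,
            "spatial_corr": 12.0,
            "temporal_corr": 0.08,
            "contrast_mod_period": 10.0,
            "contrast_mod_depth": 0.3,
        },
    }


def default_population_config() -> dict:
    return {
        "n_component": 20,
        "n_blobby": 10,
        "n_pattern": 10,
        "n_complex": 10,
        "aspect_component": (2.5, 3.5),
        "aspect_blobby": (0.2, 0.3),
        "aspect_complex": (2.5, 3.5),
        "envelope_sigma": 10.0,
        "baseline_rate": 1.0,
        "target_peak_rate": 30.0,
    }


@dataclass
class Session:
    """A complete synthetic recording: spikes, trials and ground truth."""

    units: list
    spike_times: dict
    trials: pd.DataFrame
    isi_windows: np.ndarray
    ground_truth: pd.DataFrame
    protocol: dict
    geometry: DisplayGeometry
    seed: int
    noise_seeds: list

    def noise_movie(self, index: int) -> StimulusMovie:
        """Regenerate the index-th noise movie from its stored seed."""
        noise = self.protocol["noise"]
        return make_noise_movie(
            self.noise_seeds[index],
            duration=noise["duration"],
            frame_rate=noise["frame_rate"],
            spatial_corr=noise["spatial_corr"],
            temporal_corr=noise["temporal_corr"],
            contrast_mod_period=noise["contrast_mod_period"],
            contrast_mod_depth=noise.get("contrast_mod_depth", 0.3),
            geometry=self.geometry,
        )

    def noise_trials(self) -> pd.DataFrame:
        return self.trials[self.trials.kind == "noise"]

    def unit_spikes(self, unit_id: int) -> np.ndarray:
        return self.spike_times[unit_id]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.attrs["protocol"] = json.dumps(self.protocol)
            f.attrs["noise_seeds"] = json.dumps(self.noise_seeds)
            f.attrs["geometry"] = json.dumps(
                {
                    "azimuth_extent": self.geometry.azimuth_extent,
                    "elevation_extent": self.geometry.elevation_extent,
                    "pixels_x": self.geometry.pixels_x,
                    "pixels_y": self.geometry.pixels_y,
                }
            )
            f.attrs["unit_specs"] = json.dumps(
                [
                    {
                        "unit_id": u.unit_id,
                        "kind": u.kind,
                        "params": _jsonable(u.params),
                    }
                    for u in self.units
                ]
            )
            g = f.create_group("spikes")
            for uid, st in self.spike_times.items():
                g.create_dataset(str(uid), data=st)
            f.create_dataset("isi_windows", data=self.isi_windows)
            tg = f.create_group("trials")
            for col in self.trials.columns:
                data = self.trials[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                tg.create_dataset(col, data=data)

    @classmethod
    def from_hdf5(cls, path) -> "Session":
        with h5py.File(path, "r") as f:
            geom = DisplayGeometry(**json.loads(f.attrs["geometry"]))
            specs = json.loads(f.attrs["unit_specs"])
            units = [
                make_unit(
                    s["kind"],
                    s["params"],
                    unit_id=s["unit_id"],
                    geometry=geom,
                )
                for s in specs
            ]
            spikes = {int(k): v[...] for k, v in f["spikes"].items()}
            cols = {}
            for col, d in f["trials"].items():
                v = d[...]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[col] = v
            trials = pd.DataFrame(cols)
            sess = cls(
                units=units,
                spike_times=spikes,
                trials=trials.sort_values("onset").reset_index(drop=True),
                isi_windows=f["isi_windows"][...],
                ground_truth=_ground_truth_table(units),
                protocol=json.loads(f.attrs["protocol"]),
                geometry=geom,
                seed=int(f.attrs["seed"]),
                noise_seeds=json.loads(f.attrs["noise_seeds"]),
            )
        return sess


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out


def _ground_truth_table(units: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "kind": [u.kind for u in units],
            "ground_truth_label": [u.ground_truth_label for u in units],
            "pref_direction": [u.params["pref_direction"] for u in units],
            "pref_sf": [u.params["sf"] for u in units],
            "pref_tf": [u.params["tf"] for u in units],
            "aspect_ratio": [u.params["aspect_ratio"] for u in units],
        }
    )


def _build_population(
    config: dict, geometry: DisplayGeometry, rng: np.random.Generator
) -> list:
    units = []
    uid = 0
    # carrier scales sit at the low-SF / low-TF protocol condition: rodent
    # RFs are coarse (spatial scales cluster near 0.02 cpd) and prefer low
    # temporal frequencies, and this is also the regime in which the noise
    # movies carry power, i.e. where linear RFs are recoverable at all --
    # the 0.04 cpd / 6 Hz battery conditions probe the units off-peak
    sftf = [(0.02, 2.0)]
    plan = [
        ("ln_component", config["n_component"], config["aspect_component"]),
        ("ln_blobby", config["n_blobby"], config["aspect_blobby"]),
        ("pooled_pattern", config["n_pattern"], None),
        ("energy_complex", config["n_complex"], config["aspect_complex"]),
    ]
    for kind, n, aspect_range in plan:
        for i in range(n):
            params = {
                "pref_direction": PROTOCOL_DIRECTIONS[
                    i % len(PROTOCOL_DIRECTIONS)
                ],
                "envelope_sigma": config["envelope_sigma"],
                "baseline_rate": config["baseline_rate"],
                "target_peak_rate": config["target_peak_rate"],
            }
            if kind == "ln_blobby":
                # the blobby pattern-mimicking geometry only exists at a low
                # SF relative to the RF envelope; these units prefer the
                # low-SF / low-TF protocol condition by construction
                params["sf"], params["tf"] = 0.02, 2.0
            else:
                params["sf"], params["tf"] = sftf[i % len(sftf)]
            if aspect_range is not None:
                lo, hi = aspect_range
                params["aspect_ratio"] = float(rng.uniform(lo, hi))
            units.append(
                make_unit(kind, params, unit_id=uid, geometry=geometry)
            )
            uid += 1
    return units


def make_session(
    population_config: Optional[dict] = None,
    protocol_config: Optional[dict] = None,
    seed: int = 0,
    geometry: Optional[DisplayGeometry] = None,
) -> Session:
    """Simulate a complete recording session.

    All parametric trials (gratings and plaids at every SF x TF x direction
    combination) and the noise-movie presentations are randomly interleaved
    with 1-s interstimulus intervals; every unit's spikes are drawn from its
    noiseless rate trace by an independent Poisson process, and spontaneous
    spikes at the baseline rate fill the interstimulus gaps.
    """
    pop = default_population_config()
    if population_config:
        pop.update(population_config)
    proto = default_protocol_config()
    if protocol_config:
        noise_override = protocol_config.get("noise")
        proto.update({k: v for k, v in protocol_config.items() if k != "noise"})
        if noise_override:
            proto["noise"].update(noise_override)
    if geometry is None:
        geometry = DisplayGeometry()

    ss = np.random.SeedSequence(seed)
    pop_rng, order_rng, spike_ss, noise_ss = (
        np.random.default_rng(ss.spawn(1)[0]),
        np.random.default_rng(ss.spawn(1)[0]),
        ss.spawn(1)[0],
        ss.spawn(1)[0],
    )
    units = _build_population(pop, geometry, pop_rng)

    n_noise = proto["noise"]["n_movies"]
    noise_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in noise_ss.spawn(n_noise)
    ]

    # enumerate trials
    rows = []
    for kind in ("grating", "plaid"):
        for sf in proto["sfs"]:
            for tf in proto["tfs"]:
                for d in proto["directions"]:
                    for _ in range(proto["n_trials"]):
                        rows.append(
                            {
                                "kind": kind,
                                "direction": float(d),
                                "sf": float(sf),
                                "tf": float(tf),
                                "duration": proto["duration"],
                                "noise_index": -1,
                            }
                        )
    for i in range(n_noise):
        rows.append(
            {
                "kind": "noise",
                "direction": np.nan,
                "sf": np.nan,
                "tf": np.nan,
                "duration": proto["noise"]["duration"],
                "noise_index": i,
            }
        )
    order = order_rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    onset = proto["isi"]
    for r in rows:
        r["onset"] = onset
        r["offset"] = onset + r["duration"]
        onset = r["offset"] + proto["isi"]
    trials = pd.DataFrame(rows)
    trials["trial_id"] = np.arange(len(trials))

    isi_starts = np.concatenate([[0.0], trials["offset"].to_numpy()])
    isi_ends = np.concatenate(
        [trials["onset"].to_numpy(), [trials["offset"].iloc[-1] + proto["isi"]]]
    )
    isi_windows = np.column_stack([isi_starts, isi_ends])

    spike_rngs = {
        u.unit_id: np.random.default_rng(s)
        for u, s in zip(units, spike_ss.spawn(len(units)))
    }
    spikes: dict[int, list] = {u.unit_id: [] for u in units}

    # spontaneous activity in every interstimulus gap
    for u in units:
        rng = spike_rngs[u.unit_id]
        durs = isi_windows[:, 1] - isi_windows[:, 0]
        counts = rng.poisson(u.baseline_rate * durs)
        for (t0, t1), c in zip(isi_windows, counts):
            if c:
                spikes[u.unit_id].append(t0 + rng.random(c) * (t1 - t0))

    # evoked activity, grouped by unique stimulus condition
    param = trials[trials.kind != "noise"]
    for (kind, sf, tf, d), grp in param.groupby(
        ["kind", "sf", "tf", "direction"], sort=True
    ):
        if kind == "grating":
            movie = make_grating(
                d,
                sf,
                tf,
                1.0,
                proto["duration"],
                proto["grating_frame_rate"],
                geometry,
            )
        else:
            movie = make_plaid(
                d,
                proto["cross_angle"],
                proto["component_contrast"],
                sf,
                tf,
                proto["duration"],
                proto["grating_frame_rate"],
                geometry,
            )
        for u in units:
            rate = simulate_rate(u, movie)
            trains = generate_spikes(
                rate,
                movie.frame_rate,
                n_trials=len(grp),
                seed=spike_rngs[u.unit_id].integers(2**31),
            )
            for onset_t, train in zip(grp["onset"], trains):
                if len(train):
                    spikes[u.unit_id].append(onset_t + train)

    noise_trials = trials[trials.kind == "noise"]
    for _, row in noise_trials.iterrows():
        movie = make_noise_movie(
            noise_seeds[int(row.noise_index)],
            duration=proto["noise"]["duration"],
            frame_rate=proto["noise"]["frame_rate"],
            spatial_corr=proto["noise"]["spatial_corr"],
            temporal_corr=proto["noise"]["temporal_corr"],
            contrast_mod_period=proto["noise"]["contrast_mod_period"],
            contrast_mod_depth=proto["noise"].get("contrast_mod_depth", 0.3),
            geometry=geometry,
        )
        for u in units:
            rate = simulate_rate(u, movie)
            train = generate_spikes(
                rate,
                movie.frame_rate,
                n_trials=1,
                seed=spike_rngs[u.unit_id].integers(2**31),
            )[0]
            if len(train):
                spikes[u.unit_id].append(row.onset + train)

    spike_times = {
        uid: np.sort(np.concatenate(s)) if s else np.empty(0)
        for uid, s in spikes.items()
    }
    return Session(
        units=units,
        spike_times=spike_times,
        trials=trials,
        isi_windows=isi_windows,
        ground_truth=_ground_truth_table(units),
        protocol=proto,
        geometry=geometry,
        seed=seed,
        noise_seeds=noise_seeds,
    )


def noiseless_tuning(
    unit: ModelUnit,
    sf: float = 0.02,
    tf: float = 2.0,
    cross_angle: float = 120.0,
    duration: float = 1.5,
    frame_rate: float = 30.0,
    directions: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (rate-based) grating and plaid direction tuning curves.

    Responses are the time-averaged evoked rate (above baseline) over the
    presentation window, one value per direction.
    """
    if directions is None:
        directions = PROTOCOL_DIRECTIONS
    g = np.empty(len(directions))
    p = np.empty(len(directions))
    for i, d in enumerate(directions):
        movie = make_grating(
            d, sf, tf, 1.0, duration, frame_rate, unit.filters[0].geometry
        )
        g[i] = simulate_rate(unit, movie).mean() - unit.baseline_rate
        movie = make_plaid(
            d,
            cross_angle,
            0.5,
            sf,
            tf,
            duration,
            frame_rate,
            unit.filters[0].geometry,
        )
        p[i] = simulate_rate(unit, movie).mean() - unit.baseline_rate
    return g, p


def make_regressor_bank(
    n_units: int,
    cls: str,
    seed: int = 0,
    direction_coverage: int = 12,
    sf: float = 0.02,
    tf: float = 2.0,
    geometry: Optional[DisplayGeometry] = None,
    envelope_sigma: float = 10.0,
):
    """Bank of normalized grating+plaid tuning curves of synthetic units.

    Members' preferred directions tile 0-330 deg.  ``cls`` selects the unit
    construction: 'component' (high-aspect LN), 'pattern' (opponent pooled),
    or 'unclassified' (pooled units with random signed weights, resampled
    until they fail both classification criteria).
    """
    from .classification import classify_curve_pair
    from .regression import RegressorBank

    if cls not in ("component", "pattern", "unclassified"):
        raise ValueError(f"unknown bank class: {cls}")
    if n_units < direction_coverage:
        raise ValueError("n_units must cover all direction bins")
    if geometry is None:
        geometry = DisplayGeometry()
    rng = np.random.default_rng(seed)
    curves = np.empty((n_units, 24))
    prefs = np.arange(n_units) * (360.0 / n_units)
    # snap preferred directions onto the 30-deg protocol grid
    prefs = np.round(prefs / 30.0) * 30.0 % 360.0

    if cls == "component":
        for i, pref in enumerate(prefs):
            unit = make_unit(
                "ln_component",
                {"pref_direction": float(pref), "sf": sf, "tf": tf,
                 "envelope_sigma": envelope_sigma},
                geometry=geometry,
            )
            curves[i] = _normalized_pair(*noiseless_tuning(unit, sf, tf))
    else:
        # pooled units over the full direction ring share one bank of 12
        # energy subunits; a member is just a weight vector over the ring
        energies = _ring_subunit_energies(
            sf, tf, envelope_sigma, geometry
        )  # (12 subunits, 24 stimuli, T)

        def pooled_curve(weights):
            pooled = np.maximum(
                np.tensordot(weights, energies, axes=(0, 0)), 0.0
            )
            return pooled.mean(axis=1)  # 24-vector

        ring = np.arange(0.0, 360.0, 30.0)
        for i, pref in enumerate(prefs):
            if cls == "pattern":
                w = np.cos(np.deg2rad(ring - pref))
                resp = pooled_curve(w)
            else:
                for _ in range(500):
                    resp = pooled_curve(rng.normal(0.0, 1.0, len(ring)))
                    if resp.max() <= 0:
                        continue
                    cl = classify_curve_pair(resp[:12], resp[12:])
                    if cl.label == "unclassified":
                        break
            curves[i] = _normalized_pair(resp[:12], resp[12:])
    return RegressorBank(
        bank_id=cls, cls=cls, curves=curves, pref_directions=prefs
    )


def _normalized_pair(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    peak = max(g.max(), p.max())
    if peak <= 0:
        raise ValueError("bank member produced no response")
    return np.concatenate([g, p]) / peak


def _ring_subunit_energies(
    sf: float,
    tf: float,
    envelope_sigma: float,
    geometry: DisplayGeometry,
    duration: float = 1.5,
    frame_rate: float = 30.0,
) -> np.ndarray:
    """Energy time series of 12 quadrature subunits (one per protocol
    direction) for the 12-grating + 12-plaid battery; shape (12, 24, T)."""
    movies = []
    for d in PROTOCOL_DIRECTIONS:
        movies.append(
            make_grating(d, sf, tf, 1.0, duration, frame_rate, geometry)
        )
    for d in PROTOCOL_DIRECTIONS:
        movies.append(
            make_plaid(d, 120.0, 0.5, sf, tf, duration, frame_rate, geometry)
        )
    norms = [pooled_contrast(m) + 0.01 for m in movies]
    T = movies[0].n_frames
    out = np.empty((len(PROTOCOL_DIRECTIONS), len(movies), T))
    for i, d in enumerate(PROTOCOL_DIRECTIONS):
        pair = [
            make_drifting_gabor_filter(
                d, sf, tf, 3.0, envelope_sigma, geometry=geometry, phase0=q
            )
            for q in (0.0, np.pi / 2.0)
        ]
        for s, (movie, norm) in enumerate(zip(movies, norms)):
            d0 = filter_drive(pair[0], movie) / norm
            d1 = filter_drive(pair[1], movie) / norm
            out[i, s] = d0**2 + d1**2
    return out
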