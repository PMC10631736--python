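"""LN-model tuning prediction from STA-estimated filters.

The decisive test separating true nonlinear motion integrators from
linear pattern mimics: feed the grating/plaid battery through each unit's
decorrelated, spline-interpolated STA sequence in a linear-nonlinear
model, recompute Zc'/Zp' on the predicted curves, and summarize how
classifications survive the round trip.  Linear units (any aspect ratio)
should retain their label; pooled pattern units should lose it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .classification import classify_curve_pair
from .metrics import best_condition, compute_all_curves
from .sta import STASequence
from .stimuli import DisplayGeometry, PROTOCOL_DIRECTIONS, make_grating, make_plaid
from .units import SpaceTimeFilter, filter_drive, _rectify

__all__ = [
    "LNPrediction",
    "ln_predict_tuning",
    "reclassify_from_prediction",
    "transition_summary",
    "predict_session",
]

#: prediction stimuli use the lower protocol SF (matches typical STA scale)
PREDICTION_SF = 0.02
#: peak-normalized curves below this dynamic range are flagged flat
FLAT_TOL = 1e-9


@dataclass
class LNPrediction:
    unit_id: int
    grating_curve: np.ndarray
    plaid_curve: np.ndarray
    zc_prime: float
    zp_prime: float
    predicted_label: str
    observed_label: Optional[str] = None
    flat: bool = False

    @property
    def transition(self) -> Optional[str]:
        if self.observed_label is None:
            return None
        if self.predicted_label == self.observed_label:
            return "to_same"
        if self.predicted_label == "unclassified":
            return "to_unclassified"
        return "to_opposite"


def _upsample_geometry(geometry: DisplayGeometry, factor: int) -> DisplayGeometry:
    return DisplayGeometry(
        azimuth_extent=geometry.azimuth_extent,
        elevation_extent=geometry.elevation_extent,
        pixels_x=geometry.pixels_x * factor,
        pixels_y=geometry.pixels_y * factor,
    )


def _significance_mask(
    z_frames: np.ndarray, threshold: float, min_area: int = 4
) -> np.ndarray:
    """Pixels with |z| above threshold, keeping only connected regions of
    at least ``min_area`` pixels (8-connectivity) -- isolated speckle at
    the false-positive rate carries no RF structure."""
    from skimage import measure

    mask = np.zeros_like(z_frames, dtype=bool)
    for k, frame in enumerate(z_frames):
        raw = np.abs(frame) > threshold
        labels = measure.label(raw, connectivity=2)
        for region in measure.regionprops(labels):
            if region.area >= min_area:
                mask[k][labels == region.label] = True
    return mask


def sta_filter(
    sta: STASequence,
    spline_factor: int = 2,
    z_mask_threshold: float = 3.0,
    smooth_sigma: float = 1.5,
) -> SpaceTimeFilter:
    """Significance-weighted STA reconstruction as an LN input filter.

    The filter is the pixelwise z-scored STA (weighting each pixel by its
    SNR), with pixels whose |z| does not exceed ``z_mask_threshold``
    zeroed (only statistically significant RF structure drives the model;
    without this, off-peak estimation noise dominates the predictions of
    broadly tuned units), lightly smoothed (``smooth_sigma`` pixels) and
    bicubic-upsampled by ``spline_factor``.
    """
    frames = sta.z_frames
    if z_mask_threshold > 0:
        frames = frames * _significance_mask(sta.z_frames, z_mask_threshold)
    if smooth_sigma > 0:
        frames = np.stack(
            [ndimage.gaussian_filter(f, smooth_sigma) for f in frames]
        )
    if spline_factor > 1:
        frames = np.stack(
            [ndimage.zoom(f, spline_factor, order=3) for f in frames]
        )
    geom = _upsample_geometry(sta.geometry, spline_factor)
    lag_step = float(sta.lag_times[1] - sta.lag_times[0]) if len(
        sta.lag_times
    ) > 1 else 1.0 / 30.0
    norm = np.linalg.norm(frames)
    if norm > 0:
        frames = frames / norm
    return SpaceTimeFilter(frames, lag_step, geom)


def ln_predict_tuning(
    sta: STASequence,
    tf: float = 2.0,
    sf: float = PREDICTION_SF,
    cross_angle: float = 120.0,
    duration: float = 1.5,
    spline_factor: int = 2,
    exponent: float = 3.0,
    threshold: float = 0.0,
    z_mask_threshold: float = 3.0,
    smooth_sigma: float = 1.5,
    directions: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Predicted grating and plaid tuning curves of an STA-based LN model.

    Each stimulus is convolved with the STA filter, passed through a
    rectifying static nonlinearity and time-averaged over the presentation
    window; curves are peak-normalized.  Returns (grating, plaid, flat);
    ``flat`` marks an unpredictable (all-noise, zero-drive) STA.
    """
    if directions is None:
        directions = PROTOCOL_DIRECTIONS
    filt = sta_filter(sta, spline_factor, z_mask_threshold, smooth_sigma)
    frame_rate = 1.0 / filt.lag_step
    g = np.empty(len(directions))
    p = np.empty(len(directions))
    for i, d in enumerate(directions):
        movie = make_grating(
            d, sf, tf, 1.0, duration, frame_rate, filt.geometry
        )
        g[i] = _rectify(
            filter_drive(filt, movie), threshold, exponent
        ).mean()
        movie = make_plaid(
            d, cross_angle, 0.5, sf, tf, duration, frame_rate, filt.geometry
        )
        p[i] = _rectify(
            filter_drive(filt, movie), threshold, exponent
        ).mean()
    peak = max(g.max(), p.max())
    flat = peak <= FLAT_TOL or (np.ptp(g) <= FLAT_TOL * peak and
                                np.ptp(p) <= FLAT_TOL * peak)
    if peak > 0:
        g, p = g / peak, p / peak
    return g, p, flat


def reclassify_from_prediction(
    grating_curve: np.ndarray,
    plaid_curve: np.ndarray,
    flat: bool = False,
    cross_angle: float = 120.0,
) -> tuple[float, float, str]:
    """Apply the Zp/Zc machinery verbatim to predicted curves."""
    if flat:
        return float("nan"), float("nan"), "unclassified"
    cl = classify_curve_pair(grating_curve, plaid_curve, cross_angle)
    return cl.zc, cl.zp, cl.label


def transition_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Fractions {to_same, to_opposite, to_unclassified} per observed class.

    ``labels`` needs columns observed_label and predicted_label; rows with
    observed 'unclassified' are ignored.  Empty classes yield NaN rows.
    """
    out = []
    opposite = {"component": "pattern", "pattern": "component"}
    for cls in ("component", "pattern"):
        sub = labels[labels.observed_label == cls]
        n = len(sub)
        if n == 0:
            out.append(
                {"observed_label": cls, "n": 0, "to_same": np.nan,
                 "to_opposite": np.nan, "to_unclassified": np.nan}
            )
            continue
        out.append(
            {
                "observed_label": cls,
                "n": n,
                "to_same": (sub.predicted_label == cls).mean(),
                "to_opposite": (sub.predicted_label == opposite[cls]).mean(),
                "to_unclassified": (
                    sub.predicted_label == "unclassified"
                ).mean(),
            }
        )
    return pd.DataFrame(out)


def observed_classification(
    session, strict: bool = False
) -> pd.DataFrame:
    """Observed Zp/Zc classification table for every session unit.

    At the unit's best SF/TF condition; in strict mode the label is kept
    only if the unit classifies identically at both SFs (each at its own
    best TF), mirroring the consistency requirement used before comparing
    observed with LN-predicted labels.
    """
    from .metrics import direction_selectivity_index

    rows = []
    for unit in session.units:
        spikes = session.unit_spikes(unit.unit_id)
        curves = compute_all_curves(spikes, session.trials, session.isi_windows)
        bsf, btf = best_condition(curves)
        g = curves[("grating", bsf, btf)]
        p = curves[("plaid", bsf, btf)]
        dsi = direction_selectivity_index(g)
        cl = classify_curve_pair(g.responses, p.responses, dsi=dsi)
        label = cl.label
        consistent = True
        if strict:
            sfs = sorted({k[1] for k in curves})
            per_sf = []
            for sf in sfs:
                sub = {k: v for k, v in curves.items() if k[1] == sf}
                ssf, stf = best_condition(sub)
                c = classify_curve_pair(
                    sub[("grating", ssf, stf)].responses,
                    sub[("plaid", ssf, stf)].responses,
                )
                per_sf.append(c.label)
            consistent = len(set(per_sf)) == 1
        rows.append(
            {
                "unit_id": unit.unit_id,
                "ground_truth_label": unit.ground_truth_label,
                "rc": cl.rc,
                "rp": cl.rp,
                "zc": cl.zc,
                "zp": cl.zp,
                "pi": cl.pi,
                "label": label,
                "dsi": dsi,
                "direction_selective": cl.direction_selective,
                "best_sf": bsf,
                "best_tf": btf,
                "consistent_across_sf": consistent,
                "grating_curve": g.responses,
                "plaid_curve": p.responses,
            }
        )
    return pd.DataFrame(rows)


def predict_session(
    session,
    sta_by_unit: dict,
    observed: Optional[pd.DataFrame] = None,
    ci_floor_quantile: float = 0.95,
    spline_factor: int = 2,
    exponent: float = 3.0,
    strict: bool = True,
) -> pd.DataFrame:
    """LN predictions and label transitions for all units with an STA.

    Units whose best-frame CI falls below the ``ci_floor_quantile``
    quantile of their permutation-null CI distribution are excluded
    (column ``excluded`` = True) but still reported.
    """
    if observed is None:
        observed = observed_classification(session, strict=strict)
    rows = []
    for _, obs in observed.iterrows():
        uid = int(obs.unit_id)
        sta = sta_by_unit.get(uid)
        if sta is None:
            continue
        excluded = False
        if sta.null_ci is not None and ci_floor_quantile is not None:
            # the observed statistic is a max over lags, so the null must
            # be the per-permutation max CI (multiple-comparison corrected)
            null_max = np.asarray(sta.null_ci).max(axis=1)
            floor = np.quantile(null_max, ci_floor_quantile)
            excluded = sta.ci_per_lag.max() < floor
        g, p, flat = ln_predict_tuning(
            sta,
            tf=float(obs.best_tf),
            spline_factor=spline_factor,
            exponent=exponent,
        )
        zc_p, zp_p, pred_label = reclassify_from_prediction(g, p, flat)
        pred = LNPrediction(
            unit_id=uid,
            grating_curve=g,
            plaid_curve=p,
            zc_prime=zc_p,
            zp_prime=zp_p,
            predicted_label=pred_label,
            observed_label=obs.label,
            flat=flat,
        )
        rows.append(
            {
                "unit_id": uid,
                "ground_truth_label": obs.ground_truth_label,
                "observed_label": obs.label,
                "predicted_label": pred.predicted_label,
                "transition": pred.transition,
                "zc": obs.zc,
                "zp": obs.zp,
                "zc_prime": zc_p,
                "zp_prime": zp_p,
                "flat": flat,
                "excluded": excluded,
                "consistent_across_sf": obs.consistent_across_sf,
            }
        )
    return pd.DataFrame(rows)
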