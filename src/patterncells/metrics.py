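"""Tuning curves and scalar response metrics (responsiveness, DSI, MI, CSI).

Responses R_x are trial-averaged firing rates over the full stimulus
window, z-scored against the distribution of firing rates in the 1-s
interstimulus intervals (negatives clipped to zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TuningCurve",
    "UnitMetrics",
    "baseline_statistics",
    "compute_tuning_curve",
    "compute_all_curves",
    "is_responsive",
    "direction_selectivity_index",
    "compute_psth",
    "modulation_index",
    "cross_suppression_index",
    "csi_from_curves",
    "best_condition",
    "unit_metrics_table",
]

#: SD floor (spikes/s) for baseline z-scoring, to avoid division blow-ups
BASELINE_SD_FLOOR = 0.1
#: responsiveness thresholds: baseline-subtracted rate and z-score
RESPONSIVE_RATE = 2.0
RESPONSIVE_Z = 6.0
#: MI threshold separating simple-like (>) from complex-like (<) units
MI_SIMPLE_THRESHOLD = 3.0


@dataclass
class TuningCurve:
    """12-direction tuning curve for one stimulus class x SF x TF."""

    directions: np.ndarray
    responses: np.ndarray  # z-scored, clipped at 0
    raw_rates: np.ndarray  # baseline-subtracted spikes/s (unclipped)
    stimulus_class: str
    sf: float
    tf: float
    n_trials: int

    def __post_init__(self) -> None:
        if len(self.directions) != len(self.responses):
            raise ValueError("directions/responses length mismatch")
        if np.any(np.diff(self.directions) <= 0):
            raise ValueError("directions must be strictly increasing")
        if np.any(self.responses < 0):
            raise ValueError("z-scored responses must be clipped at zero")


@dataclass
class UnitMetrics:
    unit_id: int
    responsive: bool
    dsi: float
    mi: float
    csi: float
    best_sf: float
    best_tf: float
    baseline_rate: float


def _counts_in_windows(
    spikes: np.ndarray, starts: np.ndarray, stops: np.ndarray
) -> np.ndarray:
    return np.searchsorted(spikes, stops) - np.searchsorted(spikes, starts)


def baseline_statistics(
    spikes: np.ndarray, isi_windows: np.ndarray
) -> tuple[float, float]:
    """Mean and SD of the firing rate across interstimulus windows."""
    durs = isi_windows[:, 1] - isi_windows[:, 0]
    ok = durs > 0
    counts = _counts_in_windows(
        spikes, isi_windows[ok, 0], isi_windows[ok, 1]
    )
    rates = counts / durs[ok]
    mean = float(rates.mean()) if len(rates) else 0.0
    sd = float(rates.std(ddof=0)) if len(rates) else 0.0
    return mean, max(sd, BASELINE_SD_FLOOR)


def compute_tuning_curve(
    spikes: np.ndarray,
    trials: pd.DataFrame,
    stimulus_class: str,
    sf: float,
    tf: float,
    baseline: tuple[float, float],
) -> TuningCurve:
    """Direction tuning curve from a spike train and the session trial table.

    ``baseline`` is the (mean, sd) of ISI firing rates from
    :func:`baseline_statistics`.
    """
    sel = trials[
        (trials.kind == stimulus_class)
        & np.isclose(trials.sf, sf)
        & np.isclose(trials.tf, tf)
    ]
    if sel.empty:
        raise ValueError(
            f"no trials for {stimulus_class} at sf={sf}, tf={tf}"
        )
    b_mean, b_sd = baseline
    directions = np.sort(sel.direction.unique())
    mean_rates = np.empty(len(directions))
    n_trials = 0
    for i, d in enumerate(directions):
        t = sel[np.isclose(sel.direction, d)]
        counts = _counts_in_windows(
            spikes, t.onset.to_numpy(), t.offset.to_numpy()
        )
        rates = counts / (t.offset - t.onset).to_numpy()
        mean_rates[i] = rates.mean()
        n_trials = len(t)
    z = (mean_rates - b_mean) / b_sd
    return TuningCurve(
        directions=directions,
        responses=np.clip(z, 0.0, None),
        raw_rates=mean_rates - b_mean,
        stimulus_class=stimulus_class,
        sf=sf,
        tf=tf,
        n_trials=n_trials,
    )


def compute_all_curves(
    spikes: np.ndarray,
    trials: pd.DataFrame,
    isi_windows: np.ndarray,
) -> dict:
    """All 2 class x 2 SF x 2 TF curves of a unit, keyed (class, sf, tf)."""
    baseline = baseline_statistics(spikes, isi_windows)
    param = trials[trials.kind != "noise"]
    curves = {}
    for cls in ("grating", "plaid"):
        for sf in np.sort(param.sf.unique()):
            for tf in np.sort(param.tf.unique()):
                curves[(cls, float(sf), float(tf))] = compute_tuning_curve(
                    spikes, trials, cls, sf, tf, baseline
                )
    return curves


def is_responsive(curves: dict) -> bool:
    """True iff some grating or plaid condition exceeds both 2 spikes/s
    (baseline-subtracted) and 6 z-scored points."""
    for c in curves.values():
        if c.raw_rates.max() > RESPONSIVE_RATE and (
            c.responses.max() > RESPONSIVE_Z
        ):
            return True
    return False


def direction_selectivity_index(curve: TuningCurve) -> float:
    """DSI = (R_pref - R_opposite) / (R_pref + R_opposite), on z responses."""
    r = curve.responses
    if r.max() <= 0:
        return float("nan")
    i_pref = int(np.argmax(r))
    i_opp = (i_pref + len(r) // 2) % len(r)
    denom = r[i_pref] + r[i_opp]
    return float((r[i_pref] - r[i_opp]) / denom)


def compute_psth(
    spikes: np.ndarray,
    trials: pd.DataFrame,
    bin_width: float = 0.01,
) -> np.ndarray:
    """Trial-averaged firing rate in fixed-width bins over the stimulus
    window (10-ms bins by default)."""
    dur = float((trials.offset - trials.onset).iloc[0])
    n_bins = int(round(dur / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    acc = np.zeros(n_bins)
    for onset in trials.onset:
        rel = spikes[
            (spikes >= onset) & (spikes < onset + n_bins * bin_width)
        ] - onset
        acc += np.histogram(rel, bins=edges)[0]
    return acc / (len(trials) * bin_width)


def modulation_index(
    psth: np.ndarray, f1: float, bin_width: float = 0.01
) -> float:
    """MI = |PS(f1) - <PS>_f| / sqrt(<PS^2>_f - <PS>_f^2).

    PS is the periodogram of the mean-subtracted PSTH; the DC bin is
    excluded from the averages and f1 is mapped to the nearest frequency
    bin.  MI > 3 marks strong stimulus-locked modulation (simple-like),
    MI < 3 weak modulation (complex-like).
    """
    psth = np.asarray(psth, dtype=float)
    if psth.size < 4 or np.allclose(psth, psth[0]):
        return float("nan") if np.allclose(psth, 0) else 0.0
    fs = 1.0 / bin_width
    freqs, ps = signal.periodogram(psth - psth.mean(), fs=fs)
    freqs, ps = freqs[1:], ps[1:]  # drop DC
    if f1 > freqs[-1] or f1 <= 0:
        raise ValueError("f1 outside the resolvable frequency range")
    i1 = int(np.argmin(np.abs(freqs - f1)))
    sd = ps.std(ddof=0)
    if sd == 0:
        return 0.0
    return float(abs(ps[i1] - ps.mean()) / sd)


def cross_suppression_index(rg: float, rp: float) -> float:
    """CSI = (Rg - Rp) / (Rg + Rp) from peak grating and plaid responses.

    +1: responds to gratings only (full suppression); -1: plaids only
    (full enhancement); 0: equal peak responses.
    """
    if rg < 0 or rp < 0:
        raise ValueError("peak responses must be non-negative")
    if rg == 0 and rp == 0:
        return float("nan")
    return float((rg - rp) / (rg + rp))


def csi_from_curves(grating_curve: TuningCurve, plaid_curve: TuningCurve) -> float:
    rg = max(float(grating_curve.raw_rates.max()), 0.0)
    rp = max(float(plaid_curve.raw_rates.max()), 0.0)
    return cross_suppression_index(rg, rp)


def best_condition(curves: dict) -> tuple[float, float]:
    """(SF, TF) pair maximizing the peak grating response; ties resolve to
    the lowest SF then the lowest TF."""
    grating_keys = sorted(
        [k for k in curves if k[0] == "grating"], key=lambda k: (k[1], k[2])
    )
    if not grating_keys:
        raise ValueError("no grating curves available")
    best = grating_keys[0]
    best_peak = curves[best].responses.max()
    for k in grating_keys[1:]:
        peak = curves[k].responses.max()
        if peak > best_peak:  # strict: ties keep the earlier (lower) key
            best, best_peak = k, peak
    return best[1], best[2]


def unit_metrics_table(session) -> pd.DataFrame:
    """Tidy per-unit metrics table for a synthetic session."""
    rows = []
    for unit in session.units:
        spikes = session.unit_spikes(unit.unit_id)
        curves = compute_all_curves(
            spikes, session.trials, session.isi_windows
        )
        bsf, btf = best_condition(curves)
        g = curves[("grating", bsf, btf)]
        p = curves[("plaid", bsf, btf)]
        # PSTH of the most effective grating condition
        sel = session.trials[
            (session.trials.kind == "grating")
            & np.isclose(session.trials.sf, bsf)
            & np.isclose(session.trials.tf, btf)
            & np.isclose(
                session.trials.direction,
                g.directions[int(np.argmax(g.responses))],
            )
        ]
        psth = compute_psth(spikes, sel)
        mi = modulation_index(psth, btf)
        b_mean, _ = baseline_statistics(spikes, session.isi_windows)
        rows.append(
            {
                "unit_id": unit.unit_id,
                "responsive": is_responsive(curves),
                "dsi": direction_selectivity_index(g),
                "mi": mi,
                "csi": csi_from_curves(g, p),
                "best_sf": bsf,
                "best_tf": btf,
                "baseline_rate": b_mean,
            }
        )
    return pd.DataFrame(rows)
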