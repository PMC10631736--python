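"""Pattern/component classification via Fisher-transformed partial
correlations (Zp, Zc) between observed plaid tuning and ideal predictions.

The ideal component prediction for a 120-deg plaid is the sum of the
grating curve shifted by +/-60 deg (bin-exact on the 30-deg grid); the
ideal pattern prediction is the grating curve itself.  Partial
correlations follow the standard dorsal-stream formulation, Fisher
z-scored with n - 3 degrees of freedom, and a one-sided 90% criterion
(1.28) separates the pattern / component / unclassified regions of the
Zp/Zc plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PatternClassification",
    "component_prediction",
    "pattern_prediction",
    "partial_correlations",
    "fisher_z",
    "classify",
    "pattern_index",
    "classify_curve_pair",
    "population_average_curves",
    "SIGNIFICANCE_Z",
    "DSI_CRITERION",
]

#: one-sided 90% significance criterion on Fisher-z scores
SIGNIFICANCE_Z = 1.28
#: direction-selectivity criterion on the DSI
DSI_CRITERION = 0.33
#: correlation clipping bound before atanh
_R_CLIP = 1.0 - 1e-6


@dataclass
class PatternClassification:
    rc: float
    rp: float
    zc: float
    zp: float
    pi: float
    label: str
    direction_selective: Optional[bool] = None
    n_directions: int = 12


def component_prediction(
    grating_curve: np.ndarray, cross_angle: float = 120.0
) -> np.ndarray:
    """Ideal component plaid prediction: sum of the grating curve shifted by
    +/- cross_angle / 2 (circular, bin-exact)."""
    c = np.asarray(grating_curve, dtype=float)
    bin_width = 360.0 / len(c)
    shift = (cross_angle / 2.0) / bin_width
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(
            "cross_angle / 2 must be a multiple of the direction bin width"
        )
    s = int(round(shift))
    return np.roll(c, s) + np.roll(c, -s)


def pattern_prediction(grating_curve: np.ndarray) -> np.ndarray:
    """Ideal pattern prediction: identical tuning for plaids and gratings."""
    return np.asarray(grating_curve, dtype=float).copy()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0 or nb == 0:
        return float("nan")
    return float((a @ b) / (na * nb))


def partial_correlations(
    observed_plaid: np.ndarray,
    comp_pred: np.ndarray,
    patt_pred: np.ndarray,
) -> tuple[float, float]:
    """(rc, rp): correlation of the observed plaid curve with each ideal
    prediction, partialling out the other prediction.

    rc = (r_c - r_p r_pc) / sqrt((1 - r_p^2)(1 - r_pc^2)), and symmetrically
    for rp, where r_c and r_p are the Pearson correlations of the observed
    curve with the component and pattern predictions and r_pc the
    correlation between the two predictions.
    """
    r_c = _pearson(observed_plaid, comp_pred)
    r_p = _pearson(observed_plaid, patt_pred)
    r_pc = _pearson(comp_pred, patt_pred)
    if np.isnan(r_c) or np.isnan(r_p) or np.isnan(r_pc):
        return float("nan"), float("nan")
    r_c, r_p, r_pc = (np.clip(r, -_R_CLIP, _R_CLIP) for r in (r_c, r_p, r_pc))
    rc = (r_c - r_p * r_pc) / np.sqrt((1 - r_p**2) * (1 - r_pc**2))
    rp = (r_p - r_c * r_pc) / np.sqrt((1 - r_c**2) * (1 - r_pc**2))
    return float(np.clip(rc, -1.0, 1.0)), float(np.clip(rp, -1.0, 1.0))


def fisher_z(r: float, n: int = 12) -> float:
    """Fisher-transformed, dof-scaled correlation: atanh(r) * sqrt(n - 3)."""
    if n <= 3:
        raise ValueError("n must exceed 3")
    if np.isnan(r):
        return float("nan")
    r = float(np.clip(r, -_R_CLIP, _R_CLIP))
    return float(np.arctanh(r) * np.sqrt(n - 3))


def classify(
    zp: float,
    zc: float,
    dsi: Optional[float] = None,
    threshold: float = SIGNIFICANCE_Z,
) -> tuple[str, Optional[bool]]:
    """Label a unit pattern / component / unclassified from (Zp, Zc).

    Pattern: Zp significantly above zero and above Zc (both margins at
    ``threshold``); component symmetric.  The DSI > 0.33 flag is reported
    separately so analyses can include or exclude it.
    """
    if np.isnan(zp) or np.isnan(zc):
        label = "unclassified"
    elif zp - max(zc, 0.0) > threshold and zp > threshold:
        label = "pattern"
    elif zc - max(zp, 0.0) > threshold and zc > threshold:
        label = "component"
    else:
        label = "unclassified"
    ds = None if dsi is None else bool(
        not np.isnan(dsi) and dsi > DSI_CRITERION
    )
    return label, ds


def pattern_index(zp: float, zc: float) -> float:
    """PI = Zp - Zc, scalar patternness."""
    return float(zp - zc)


def classify_curve_pair(
    grating_curve: np.ndarray,
    plaid_curve: np.ndarray,
    cross_angle: float = 120.0,
    dsi: Optional[float] = None,
) -> PatternClassification:
    """Full classification of one unit from its grating and plaid curves."""
    cp = component_prediction(grating_curve, cross_angle)
    pp = pattern_prediction(grating_curve)
    rc, rp = partial_correlations(np.asarray(plaid_curve, float), cp, pp)
    n = len(grating_curve)
    zc = fisher_z(rc, n)
    zp = fisher_z(rp, n)
    label, ds = classify(zp, zc, dsi)
    return PatternClassification(
        rc=rc,
        rp=rp,
        zc=zc,
        zp=zp,
        pi=pattern_index(zp, zc) if np.isfinite(zp) and np.isfinite(zc)
        else float("nan"),
        label=label,
        direction_selective=ds,
        n_directions=n,
    )


def population_average_curves(
    curve_pairs: list,
    normalize: bool = True,
) -> dict:
    """Aligned population-average grating and plaid curves.

    Each unit's pair of curves is circularly shifted so its preferred
    grating direction sits at 0 deg, peak-normalized (by the joint peak of
    the pair), and averaged across units; Zc/Zp/PI are recomputed on the
    averaged pair.
    """
    if len(curve_pairs) < 2:
        raise ValueError("need >= 2 units to average")
    gs, ps = [], []
    for g, p in curve_pairs:
        g = np.asarray(g, dtype=float)
        p = np.asarray(p, dtype=float)
        shift = -int(np.argmax(g))
        g = np.roll(g, shift)
        p = np.roll(p, shift)
        if normalize:
            peak = max(g.max(), p.max())
            if peak > 0:
                g = g / peak
                p = p / peak
        gs.append(g)
        ps.append(p)
    g_mean = np.mean(gs, axis=0)
    p_mean = np.mean(ps, axis=0)
    cl = classify_curve_pair(g_mean, p_mean)
    return {
        "grating": g_mean,
        "plaid": p_mean,
        "zc": cl.zc,
        "zp": cl.zp,
        "pi": cl.pi,
    }
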