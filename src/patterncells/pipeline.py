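"""End-to-end orchestration: simulate -> metrics -> classify -> STA ->
LN-predict -> regress, with deterministic seeding and summary outputs.

A single master seed spawns per-stage substreams via
``numpy.random.SeedSequence`` so each stage is independently
reproducible.  ``run_pipeline`` writes tidy CSV tables plus a summary
JSON stamped with the config hash and seed; ``make_report`` renders the
standard figure panels from a result bundle.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import lnmodel, metrics, regression, sta, units
from .classification import SIGNIFICANCE_Z

__all__ = ["default_config", "smoke_config", "run_pipeline", "make_report"]


def default_config() -> dict:
    """Full-protocol configuration (the recording-session scale)."""
    return {
        "population": units.default_population_config(),
        "protocol": units.default_protocol_config(),
        "geometry": {"pixels_x": 64, "pixels_y": 48},
        "sta": {"n_perm": 200, "n_lags": 10, "ridge_fraction": 0.1},
        "ln": {"spline_factor": 2, "exponent": 3.0,
               "ci_floor_quantile": 0.95},
        "regression": {"bank_size": 12, "ridge_lambda": None},
        "seed": 0,
    }


def desk_config() -> dict:
    """Reduced problem size for desk-scale runs: 24 units at 48 x 36
    pixels.  The noise protocol stays at full scale (20 x 60 s) -- STA
    quality is the one thing that cannot be scaled down."""
    cfg = default_config()
    cfg["population"].update(
        {"n_component": 8, "n_blobby": 6, "n_pattern": 6, "n_complex": 4}
    )
    cfg["geometry"] = {"pixels_x": 48, "pixels_y": 36}
    return cfg


def smoke_config() -> dict:
    """Minimal configuration for fast end-to-end checks."""
    cfg = default_config()
    cfg["population"].update(
        {"n_component": 2, "n_blobby": 2, "n_pattern": 1, "n_complex": 1}
    )
    cfg["protocol"].update({"n_trials": 5})
    cfg["protocol"]["noise"].update({"n_movies": 3, "duration": 15.0})
    cfg["geometry"] = {"pixels_x": 32, "pixels_y": 24}
    cfg["sta"]["n_perm"] = 100
    return cfg


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _geometry(config: dict):
    from .stimuli import DisplayGeometry

    return DisplayGeometry(**config.get("geometry", {}))


def build_session(config: dict, seed: Optional[int] = None):
    if seed is None:
        seed = config.get("seed", 0)
    return units.make_session(
        population_config=config.get("population"),
        protocol_config=config.get("protocol"),
        seed=seed,
        geometry=_geometry(config),
    )


def compute_stas(session, config: dict, seed: int) -> dict:
    """STA sequences for every unit, sharing movies and power spectrum."""
    noise = session.noise_trials().sort_values("noise_index")
    movies = [session.noise_movie(int(i)) for i in noise.noise_index]
    power = sta.stimulus_power_spectrum(movies)
    out = {}
    children = np.random.SeedSequence(seed).spawn(len(session.units))
    for unit, child in zip(session.units, children):
        out[unit.unit_id] = sta.sta_for_unit(
            session,
            unit.unit_id,
            n_perm=config["sta"]["n_perm"],
            n_lags=config["sta"]["n_lags"],
            ridge_fraction=config["sta"]["ridge_fraction"],
            seed=int(child.generate_state(1)[0] % (2**31)),
            movies=movies,
            power_spectrum=power,
        )
    return out


def sta_summary_table(stas: dict, session) -> pd.DataFrame:
    rows = []
    gt = session.ground_truth.set_index("unit_id")
    for uid, s in stas.items():
        best = s.best_lag
        fit = sta.fit_gabor(s.z_frames[best], s.geometry)
        _, n_lobes = sta.count_lobes(
            s.z_frames, ci_per_lag=s.ci_per_lag
        )
        rows.append(
            {
                "unit_id": uid,
                "ground_truth_label": gt.loc[uid, "ground_truth_label"],
                "n_spikes": s.n_spikes,
                "best_lag": best,
                "ci_best": float(s.ci_per_lag[best]),
                "ci_mean": float(s.ci_per_lag.mean()),
                "gabor_r2": fit.r2,
                "gabor_orientation": fit.orientation,
                "n_lobes": n_lobes,
                "sta_sf": sta.sta_spatial_frequency(
                    s.z_frames, s.geometry, s.ci_per_lag
                ),
                "low_confidence": s.low_confidence,
            }
        )
    return pd.DataFrame(rows)


def regression_stage(session, observed: pd.DataFrame, config: dict,
                     seed: int) -> pd.DataFrame:
    """Fit classified units' observed 24-vectors with the three synthetic
    regressor banks."""
    bank_size = config["regression"]["bank_size"]
    ss = np.random.SeedSequence(seed).spawn(3)
    banks = [
        units.make_regressor_bank(
            bank_size, cls, seed=int(s.generate_state(1)[0] % (2**31)),
            geometry=session.geometry,
        )
        for cls, s in zip(("component", "pattern", "unclassified"), ss)
    ]
    targets = []
    for _, row in observed.iterrows():
        curve = np.concatenate([row.grating_curve, row.plaid_curve])
        if np.ptp(curve) == 0 or np.abs(curve).max() == 0:
            continue
        targets.append(
            {"unit_id": row.unit_id, "label": row.label, "curve_24": curve}
        )
    table = regression.bank_fit_table(
        pd.DataFrame(targets), banks,
        ridge_lambda=config["regression"]["ridge_lambda"],
    )
    return table


def run_pipeline(
    config: Optional[dict] = None,
    out_dir: Optional[str] = None,
    seed: Optional[int] = None,
) -> dict:
    """Execute the full analysis chain on a synthetic session.

    Returns a result bundle (session, tables, summary dict); when
    ``out_dir`` is given all tables are written as CSV and the summary as
    JSON.  Identical config + seed gives identical summaries.
    """
    if config is None:
        config = default_config()
    elif isinstance(config, (str, Path)):
        with open(config) as f:
            config = yaml.safe_load(f)
    if seed is not None:
        config = {**config, "seed": seed}
    master = config.get("seed", 0)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("session", "sta", "regression"),
            np.random.SeedSequence(master).spawn(3),
        )
    }

    session = build_session(config, seed=stage_seeds["session"])
    metrics_table = metrics.unit_metrics_table(session)
    observed = lnmodel.observed_classification(session, strict=True)
    stas = compute_stas(session, config, stage_seeds["sta"])
    sta_table = sta_summary_table(stas, session)
    ln_table = lnmodel.predict_session(
        session,
        stas,
        observed=observed,
        ci_floor_quantile=config["ln"]["ci_floor_quantile"],
        spline_factor=config["ln"]["spline_factor"],
        exponent=config["ln"]["exponent"],
    )
    transitions = lnmodel.transition_summary(
        ln_table[ln_table.consistent_across_sf & ~ln_table.excluded]
    )
    regress_table = regression_stage(
        session, observed, config, stage_seeds["regression"]
    )

    class_counts = observed.label.value_counts().to_dict()
    summary = {
        "config_hash": _config_hash(config),
        "seed": master,
        "n_units": len(session.units),
        "class_counts": class_counts,
        "mean_dsi": float(metrics_table.dsi.mean()),
        "median_mi": float(metrics_table.mi.median()),
        "median_csi": float(metrics_table.csi.median()),
        "transitions": transitions.to_dict(orient="records"),
        "matched_bank_win_rate": _matched_win_rate(regress_table),
    }

    bundle = {
        "config": config,
        "session": session,
        "metrics": metrics_table,
        "observed": observed,
        "stas": stas,
        "sta_table": sta_table,
        "ln_table": ln_table,
        "transitions": transitions,
        "regression": regress_table,
        "summary": summary,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_table.to_csv(out / "unit_metrics.csv", index=False)
        observed.drop(
            columns=["grating_curve", "plaid_curve"]
        ).to_csv(out / "classification.csv", index=False)
        sta_table.to_csv(out / "sta_summary.csv", index=False)
        ln_table.to_csv(out / "ln_prediction.csv", index=False)
        transitions.to_csv(out / "transitions.csv", index=False)
        regress_table.to_csv(out / "regression.csv", index=False)
        session.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True)
    return bundle


def _matched_win_rate(regress_table: pd.DataFrame) -> Optional[float]:
    sub = regress_table[regress_table.label.isin(("component", "pattern"))]
    if sub.empty:
        return None
    return float((sub.best_bank == sub.label).mean())


def make_report(bundle: dict, out_dir: str) -> list:
    """Standard figure panels from a pipeline result bundle (PNG files)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    observed = bundle["observed"]
    colors = {"component": "tab:green", "pattern": "tab:orange",
              "unclassified": "0.6"}

    # Zp/Zc scatter with decision boundaries
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, grp in observed.groupby("label"):
        ax.scatter(grp.zc, grp.zp, c=colors.get(label, "k"), label=label,
                   s=25)
    t = SIGNIFICANCE_Z
    lim = max(
        6.0, float(np.nanmax(np.abs(observed[["zc", "zp"]].to_numpy()))) + 1
    )
    ax.plot([t, t], [-lim, 0], "k--", lw=0.8)
    ax.plot([t, lim], [0, lim - t], "k--", lw=0.8)
    ax.plot([-lim, 0], [t, t], "k--", lw=0.8)
    ax.plot([0, lim - t], [t, lim], "k--", lw=0.8)
    ax.set_xlabel("Zc")
    ax.set_ylabel("Zp")
    ax.legend(frameon=False)
    fig.savefig(out / "zp_zc_scatter.png", dpi=120)
    plt.close(fig)
    paths.append(out / "zp_zc_scatter.png")

    # class fractions
    fig, ax = plt.subplots(figsize=(4, 3))
    frac = observed.label.value_counts(normalize=True)
    ax.bar(frac.index, frac.values,
           color=[colors.get(k, "k") for k in frac.index])
    ax.set_ylabel("fraction of units")
    fig.savefig(out / "class_fractions.png", dpi=120)
    plt.close(fig)
    paths.append(out / "class_fractions.png")

    # CI / Gabor R2 by ground-truth class
    sta_table = bundle["sta_table"]
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax_i, col in zip(axes, ("ci_mean", "gabor_r2")):
        groups = [
            sta_table[sta_table.ground_truth_label == g][col].dropna()
            for g in ("component", "pattern")
        ]
        ax_i.boxplot(groups, tick_labels=["component", "pattern"])
        ax_i.set_ylabel(col)
    fig.tight_layout()
    fig.savefig(out / "sta_quality.png", dpi=120)
    plt.close(fig)
    paths.append(out / "sta_quality.png")

    # transition bars
    tr = bundle["transitions"].set_index("observed_label")
    fig, ax = plt.subplots(figsize=(5, 3))
    xs = np.arange(3)
    width = 0.35
    for i, cls in enumerate(("component", "pattern")):
        if cls in tr.index:
            vals = tr.loc[cls, ["to_same", "to_opposite", "to_unclassified"]]
            ax.bar(xs + i * width, vals.to_numpy(dtype=float), width,
                   color=colors[cls], label=cls)
    ax.set_xticks(xs + width / 2)
    ax.set_xticklabels(["to same", "to opposite", "to unclassified"])
    ax.set_ylabel("fraction of units")
    ax.legend(frameon=False)
    fig.savefig(out / "ln_transitions.png", dpi=120)
    plt.close(fig)
    paths.append(out / "ln_transitions.png")
    return [str(p) for p in paths]
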