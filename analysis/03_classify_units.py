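"""Tuning metrics and pattern/component classification of a session.

Loads results/session.h5 (or simulates one), computes per-unit response
metrics (responsiveness, DSI, MI, CSI, best SF/TF) and the Zp/Zc
partial-correlation classification, and reports how well the observed
labels recover the ground-truth classes.

Writes results/unit_metrics.csv and results/classification.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from patterncells import lnmodel, metrics, pipeline
from patterncells.units import Session

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0):
    path = OUT / "session.h5"
    if path.exists():
        session = Session.from_hdf5(path)
    else:
        session = pipeline.build_session(pipeline.desk_config(), seed=seed)
    table = metrics.unit_metrics_table(session)
    observed = lnmodel.observed_classification(session, strict=True)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "unit_metrics.csv", index=False)
    observed.drop(columns=["grating_curve", "plaid_curve"]).to_csv(
        OUT / "classification.csv", index=False
    )
    print("recovery of ground-truth classes by observed Zp/Zc labels:")
    print(pd.crosstab(observed.ground_truth_label, observed.label))
    merged = table.merge(
        session.ground_truth[["unit_id", "ground_truth_label"]], on="unit_id"
    )
    print("\nmedian modulation index by class (MI > 3 = simple-like):")
    print(merged.groupby("ground_truth_label").mi.median().round(2))
    print("\nmedian cross-suppression index by class:")
    print(merged.groupby("ground_truth_label").csi.median().round(2))
    return 0


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    sys.exit(main(seed))
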