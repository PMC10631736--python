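"""Linear tuning-curve models from class-specific regressor banks.

Each unit's concatenated grating+plaid tuning (24 direction bins) is fit
by ridge regression on three banks of synthetic reference units
(component / pattern / heterogeneous "unclassified"), with leave-
directions-out cross-validation.  The matched bank should win for
component and pattern cells, with high confidence, while unclassified
targets are fit poorly by everything.

Requires the pipeline outputs of 05 (or reruns them); writes
results/regression.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from patterncells import pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0):
    bundle = pipeline.run_pipeline(pipeline.desk_config(), out_dir=OUT,
                                   seed=seed)
    reg = bundle["regression"].merge(
        bundle["session"].ground_truth[["unit_id", "ground_truth_label"]],
        on="unit_id",
    )
    print("best-fitting bank by ground-truth class:")
    print(pd.crosstab(reg.ground_truth_label, reg.best_bank))
    sub = reg[reg.label.isin(("component", "pattern"))]
    print(
        f"\nmatched-bank win rate over classified units: "
        f"{(sub.best_bank == sub.label).mean():.0%} (n={len(sub)})"
    )
    print("median confidence by observed label:")
    print(reg.groupby("label").confidence.median().round(3))
    return 0


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    sys.exit(main(seed))
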