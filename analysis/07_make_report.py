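"""Figure panels summarizing a full pipeline run.

Renders the Zp/Zc scatter with decision boundaries, class-fraction bars,
STA quality (CI / Gabor R^2) by class, and the LN-prediction transition
bars into results/figures/.
"""

import sys
from pathlib import Path

from patterncells import pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0):
    bundle = pipeline.run_pipeline(pipeline.desk_config(), out_dir=OUT,
                                   seed=seed)
    paths = pipeline.make_report(bundle, OUT / "figures")
    for p in paths:
        print("wrote", p)
    return 0


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    sys.exit(main(seed))
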