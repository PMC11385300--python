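#!/usr/bin/env python
"""Sensitivity-to-findings ranking for the three output variables.

For each output node, every other variable is scored by how much observing
it would reduce the output's variance (band midpoints as real values),
entropy (mutual information, bits) and belief vector (variance of beliefs);
variables are listed in descending order of variance reduction.
"""

from pathlib import Path

import pandas as pd

from tillage_bbn.io import read_cases
from tillage_bbn.sensitivity import rank_findings_frame
from tillage_bbn.tillage import OUTPUT_VARS, fit_tillage_model
from tillage_bbn.validate import HOLDOUT_PLAN, split

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cases = read_cases(ROOT / "scratch" / "cases.csv")
    train = split(cases, HOLDOUT_PLAN)["train"]
    net, _ = fit_tillage_model(train, prior_weight=1.0)

    frames = []
    for target in OUTPUT_VARS:
        df = rank_findings_frame(net, target)
        df.insert(0, "target", target)
        frames.append(df)
        top = df.head(3)
        tops = ", ".join(f"{r.finding} (VR {r.variance_reduction:.3g})"
                         for r in top.itertuples())
        print(f"{target:>7}: most informative findings: {tops}")
    pd.concat(frames).to_csv(ROOT / "results" / "sensitivity.csv",
                             index=False, float_format="%.6g")
    print("wrote results/sensitivity.csv")


if __name__ == "__main__":
    main()
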