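#!/usr/bin/env python
"""Decade-block K-fold cross-validation of the tillage network.

Folds K1 (1975-1984) ... K4 (2005-2014) are each held out in turn with the
model refit (schemes + CPTs) on the remaining years; the final row trains
on K1-K4 and tests on K5 (2015-2022), mirroring the train/test design of
the original evaluation.
"""

from pathlib import Path

import pandas as pd

from tillage_bbn.io import read_cases
from tillage_bbn.tillage import OUTPUT_VARS, fit_tillage_model
from tillage_bbn.validate import kfold_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cases = read_cases(ROOT / "scratch" / "cases.csv")

    def factory(train):
        return fit_tillage_model(train, prior_weight=1.0)

    frames = []
    for target in OUTPUT_VARS:
        df = kfold_report(factory, cases, target)
        df.insert(0, "target", target)
        frames.append(df)
        line = ", ".join(f"{r.fold} {r.error_rate:.2f}%"
                         for r in df.itertuples())
        print(f"{target:>7}: {line}")
    pd.concat(frames).to_csv(ROOT / "results" / "kfold.csv", index=False,
                             float_format="%.2f")
    print("wrote results/kfold.csv")


if __name__ == "__main__":
    main()
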