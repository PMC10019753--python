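#!/usr/bin/env python
"""Cross-validated classifier comparison on the demonstration cohort.

Reads scratch/features.csv and runs the full grid: {LTM vs NM, STM vs NM}
x {state-wise tables for baseline/meditation/transmission, band-wise
tables for delta/theta/alpha/beta} x six classifiers, with 10-fold
subject-level cross-validation. Writes the 84-row accuracy grid to
results/ and prints accuracy pivots.
"""

import argparse
from pathlib import Path

import pandas as pd

from meditfc import run_full_comparison

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument(
        "--fold-unit", choices=["subject", "epoch"], default="subject",
        help="epoch-level folds reproduce a leakier protocol",
    )
    args = ap.parse_args()

    features_path = ROOT / "scratch" / "features.csv"
    if not features_path.exists():
        raise SystemExit("scratch/features.csv missing - run 02_connectivity_features.py first")
    features = pd.read_csv(features_path)

    grid = run_full_comparison(features, args.seed, fold_unit=args.fold_unit)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    grid.to_csv(results / "04_classifier_accuracy.csv", index=False)

    print(f"{len(grid)} (comparison, table, classifier) cells")
    for layout in ("statewise", "bandwise"):
        sub = grid[grid["layout"] == layout]
        print(f"\n{layout} mean accuracy:")
        print(
            sub.pivot_table(
                index="classifier", columns=["comparison", "fixed_factor"],
                values="mean_accuracy",
            ).round(3).to_string()
        )


if __name__ == "__main__":
    main()
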