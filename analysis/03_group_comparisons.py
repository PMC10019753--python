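#!/usr/bin/env python
"""Between-group statistics on the demonstration cohort's features.

Reads scratch/features.csv (rerun 02_connectivity_features.py if absent),
epoch-averages within subject, and runs Welch two-sample comparisons for
every (measure, band, state, group-pair) cell with significance stars.
Writes the 192-row grid to results/ and prints the significant cells.
"""

import argparse
from pathlib import Path

import pandas as pd

from meditfc import comparison_grid

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bh", action="store_true", help="Benjamini-Hochberg adjust")
    args = ap.parse_args()

    features_path = ROOT / "scratch" / "features.csv"
    if not features_path.exists():
        raise SystemExit("scratch/features.csv missing - run 02_connectivity_features.py first")
    features = pd.read_csv(features_path)

    grid = comparison_grid(features, bh_adjust=args.bh)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    grid.to_csv(results / "03_group_comparisons.csv", index=False)

    sig = grid[grid["star"] != "ns"]
    print(f"{len(grid)} comparisons, {len(sig)} significant")
    print("\nsignificant cells per pair and measure:")
    print(sig.groupby(["pair", "measure"]).size().unstack(fill_value=0).to_string())
    print("\nmost significant cells:")
    print(
        sig.nsmallest(10, "p_value")[
            ["measure", "band", "state", "pair", "mean_1", "mean_2", "p_value", "star"]
        ].to_string(index=False)
    )


if __name__ == "__main__":
    main()
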