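#!/usr/bin/env python
"""Recompute the published cross-cancer statistics from the fixture tables.

Runs every fixture-reproduction check (closed-form two-variable numbers,
b/k summaries, sex comparisons, correlations, regressions and lifetime
risks) and writes the pass/fail table to results/fixture_stats.csv.
"""

import argparse
from pathlib import Path

from stagesen.reproduce import compute_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/fixture_stats.csv"))
    args = ap.parse_args()

    report = compute_report()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out, index=False)
    ok = int(report["ok"].sum())
    print(f"{ok}/{len(report)} published statistics reproduced "
          f"(see {args.out})")
    if ok < len(report):
        print(report[~report["ok"]].to_string(index=False))


if __name__ == "__main__":
    main()
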