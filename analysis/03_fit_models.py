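#!/usr/bin/env python
"""Fit the multistage-senescence model to every simulated series.

Each cancer x sex series in results/rates.csv is fit by weighted nonlinear
least squares from its cancer-specific start age, and the fitted (u, k, b)
are compared with the simulation truth for the pooled series. Writes
results/fits.csv in the per-cancer parameter-table layout.
"""

import argparse
import importlib
import sys
from pathlib import Path

from stagesen.incidence_rates import read_series
from stagesen.model_fitting import FitConfig, fit_series, results_to_frame

sys.path.insert(0, str(Path(__file__).parent))
truth_mod = importlib.import_module("01_simulate_registry")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rates", type=Path, default=Path("results/rates.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/fits.csv"))
    args = ap.parse_args()

    results = []
    for s in read_series(args.rates):
        cfg = FitConfig.for_cancer(s.cancer_code)
        try:
            results.append(fit_series(s, cfg))
        except (ValueError, RuntimeError) as exc:
            print(f"skipping {s.cancer_code}/{s.sex}: {exc}", file=sys.stderr)
    frame = results_to_frame(results)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False)
    print(f"wrote {len(frame)} fits to {args.out}")

    print("pooled fits vs simulation truth (u, k, b):")
    truth = truth_mod.TRUTH
    for r in results:
        sex = "female" if r.cancer_code == "BRCA" else "pooled"
        if r.sex != sex or r.cancer_code not in truth:
            continue
        t = truth[r.cancer_code]
        print(f"  {r.cancer_code:6s} fitted ({r.params.u_mu:.4f}, "
              f"{r.params.k:5.2f}, {r.params.b:.5f})  "
              f"truth ({t.u_mu:.4f}, {t.k:5.2f}, {t.b:.5f})  "
              f"peak {r.peak_age:5.1f}")


if __name__ == "__main__":
    main()
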