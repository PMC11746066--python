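#!/usr/bin/env python
"""Structural-convention grid: which conventions come closest to the
published base-case totals.

The source publication does not fully document its spreadsheet conventions,
so the engine exposes three structural flags (first-line switch timing,
discount timing, AP/BP drug-cost rule).  This script evaluates all eight
combinations against the published per-strategy totals and reports the total
relative deviation of each; the shipped defaults are the arg-min row.  Note
that even the best grid point reproduces only the imatinib strategy within a
few percent — the nilotinib/dasatinib totals implied by the published inputs
fall well short of the published outputs (see docs/methods.md).
"""

import itertools
from pathlib import Path

import pandas as pd

import tkicea as t

OUT = Path(__file__).resolve().parents[1] / "results"

PUBLISHED = {
    "imatinib": (120_719.55, 5.93),
    "nilotinib": (169_861.41, 7.78),
    "dasatinib": (180_774.97, 7.60),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for sm, dtiming, apbp in itertools.product(
        ["per_cycle", "first_cycle_only"],
        ["mid_cycle", "end_cycle"],
        ["continue", "none"],
    ):
        spec = t.builtin_basecase()
        conv = spec.econ.conventions
        conv.switch_mode, conv.discount_timing, conv.apbp_drug_cost = sm, dtiming, apbp
        results = t.run_all(spec)
        row = {"switch_mode": sm, "discount_timing": dtiming,
               "apbp_drug_cost": apbp}
        dev = 0.0
        for name, (cost, qalys) in PUBLISHED.items():
            row[f"cost_{name}"] = results[name].total_cost
            row[f"qalys_{name}"] = results[name].total_qalys
            dev += abs(results[name].total_cost - cost) / cost
            dev += abs(results[name].total_qalys - qalys) / qalys
        row["total_rel_deviation"] = dev
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("total_rel_deviation").reset_index(drop=True)
    df.to_csv(OUT / "convention_grid.csv", index=False)
    best = df.iloc[0]
    print(df.round(3).to_string(index=False))
    print(f"\nBest grid point: switch_mode={best.switch_mode}, "
          f"discount_timing={best.discount_timing}, "
          f"apbp_drug_cost={best.apbp_drug_cost} "
          f"(total relative deviation {best.total_rel_deviation:.3f}) — "
          "these are the shipped defaults.")


if __name__ == "__main__":
    main()
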