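#!/usr/bin/env python
"""One-way deterministic sensitivity analysis: tornado tables and the two
special sweeps (imatinib switch split, discount rate).

Every ranged parameter is pushed to its published low and high bound and the
ICER of each second-generation strategy versus imatinib recomputed; tables
are sorted by ICER spread (tornado order).
"""

from pathlib import Path

import tkicea as t
from tkicea.dsa import tornado

OUT = Path(__file__).resolve().parents[1] / "results"
COMPARISONS = (("nilotinib", "imatinib"), ("dasatinib", "imatinib"))


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = t.builtin_basecase()
    for comparison in COMPARISONS:
        tag = f"{comparison[0]}_vs_{comparison[1]}"
        df = tornado(spec, comparison)
        df.to_csv(OUT / f"tornado_{tag}.csv", index=False)
        print(f"Most influential parameters, {tag}:")
        print(df.head(5).round(2).to_string(index=False))
        print()

    sweep = t.switch_split_sweep(spec)
    sweep.to_csv(OUT / "switch_split_sweep.csv", index=False)
    print("Imatinib-strategy switch-split sweep (proportion routed to nilotinib):")
    print(sweep.round(2).to_string(index=False))
    print()

    disc = t.discount_sweep(spec)
    disc.to_csv(OUT / "discount_sweep.csv", index=False)
    print("Discount-rate sweep 0-10%:")
    print(disc.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
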