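"""One-way deterministic sensitivity analysis.

Each ranged parameter is set to its low and high bound in turn (probabilities
and utilities capped at [0, 1]), the full cohort model is re-run, and the ICER
for a named comparison recorded.  The tornado table sorts parameters by the
spread between the two ICERs.  Two published special sweeps are included: the
imatinib-strategy switch-split sweep and the 0–10% discount-rate sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cea
from .markov import run_strategy
from .parameters import ModelSpec, _is_probability_like, fallback_range

__all__ = [
    "Comparison",
    "DsaRow",
    "discount_sweep",
    "icer_for",
    "one_way",
    "switch_split_sweep",
    "tornado",
]

# A comparison is (comparator, reference), e.g. ("nilotinib", "imatinib").
Comparison = tuple[str, str]


@dataclass(frozen=True)
class DsaRow:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def icer_for(spec: ModelSpec, comparison: Comparison) -> float:
    """ICER of comparator vs reference under ``spec`` (full model run)."""
    comparator, reference = comparison
    rc = run_strategy(spec, comparator)
    rr = run_strategy(spec, reference)
    return cea.icer(rc.total_cost - rr.total_cost, rc.total_qalys - rr.total_qalys)


def _capped(pid: str, value: float) -> float:
    if _is_probability_like(pid):
        return min(max(value, 0.0), 1.0)
    return max(value, 0.0)


def one_way(spec: ModelSpec, parameter: str, comparison: Comparison) -> DsaRow:
    """Recompute the comparison ICER at the parameter's low and high bound."""
    rng = spec.range_for(parameter)
    if rng is None:
        rng = fallback_range(parameter, spec.get(parameter))
    icers = []
    for bound in (rng.low, rng.high):
        work = spec.clone()
        work.set(parameter, _capped(parameter, bound))
        icers.append(icer_for(work, comparison))
    return DsaRow(parameter, rng.low, rng.high, icers[0], icers[1])


def tornado(spec: ModelSpec, comparison: Comparison) -> pd.DataFrame:
    """All ranged parameters swept; rows sorted by descending spread, ties
    broken lexicographically by parameter id."""
    rows = [one_way(spec, r.parameter, comparison) for r in spec.ranges]
    df = pd.DataFrame(
        [dict(parameter=r.parameter, low=r.low, high=r.high,
              icer_low=r.icer_low, icer_high=r.icer_high, spread=r.spread)
         for r in rows]
    )
    df = df.sort_values(["spread", "parameter"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df


def switch_split_sweep(
    spec: ModelSpec,
    nilotinib_props: np.ndarray | list[float] | None = None,
    strategy: str = "imatinib",
) -> pd.DataFrame:
    """Sweep the first-line-failure split of the imatinib strategy.

    ``nilotinib_props`` is the grid of proportions routed to nilotinib (the
    remainder goes to dasatinib); the published sweep runs the 50%/50% base
    out to 100% for each drug.
    """
    if nilotinib_props is None:
        nilotinib_props = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    strat = spec.strategy(strategy)
    dests = list(strat.switch.splits)
    if len(dests) != 2:
        raise ValueError("switch-split sweep needs a two-destination rule")
    rows = []
    for p in nilotinib_props:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"proportion {p} outside [0, 1]")
        work = spec.clone()
        rule = work.strategy(strategy).switch
        rule.splits["nilotinib"] = float(p)
        other = next(d for d in dests if d != "nilotinib")
        rule.splits[other] = float(1.0 - p)
        rows.append({
            "prop_nilotinib": float(p),
            "prop_" + other: float(1.0 - p),
            "icer_nilotinib_vs_imatinib": icer_for(work, ("nilotinib", "imatinib")),
            "icer_dasatinib_vs_imatinib": icer_for(work, ("dasatinib", "imatinib")),
        })
    return pd.DataFrame(rows)


def discount_sweep(
    spec: ModelSpec,
    rates: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """ICERs for both comparisons at discount rates over the published 0–10% span."""
    if rates is None:
        rates = np.round(np.arange(0.0, 0.1001, 0.01), 10)
    rows = []
    for r in rates:
        work = spec.clone()
        work.econ.discount_rate = float(r)
        rows.append({
            "discount_rate": float(r),
            "icer_nilotinib_vs_imatinib": icer_for(work, ("nilotinib", "imatinib")),
            "icer_dasatinib_vs_imatinib": icer_for(work, ("dasatinib", "imatinib")),
        })
    return pd.DataFrame(rows)
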