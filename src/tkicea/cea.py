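"""Incremental cost-effectiveness analysis.

ICER = Δcost / ΔQALY between two strategies; NMB = WTP × QALYs − cost.  The
willingness-to-pay threshold follows the WHO convention of a multiple of GDP
per capita (three by default), rounded to the nearest 10 US$.

Two table modes are provided.  ``paper`` compares every strategy to a fixed
reference (how the published Table 4 is laid out); ``frontier`` is the
textbook efficiency-frontier analysis with strong and extended dominance
pruning and sequential ICERs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .markov import StrategyResult

__all__ = [
    "IncrementalTable",
    "UndefinedICERError",
    "WtpThreshold",
    "build_incremental_table",
    "derive_wtp",
    "icer",
    "nmb",
]


class UndefinedICERError(ZeroDivisionError):
    """ICER requested for a zero QALY difference."""


def icer(delta_cost: float, delta_qalys: float) -> float:
    """Incremental cost per QALY gained.

    Note: a negative ratio (one difference negative) or a ratio from two
    negative differences is returned as-is; dominance interpretation is the
    caller's job (see :func:`build_incremental_table`).
    """
    if delta_qalys == 0:
        raise UndefinedICERError(
            "ICER undefined for zero QALY difference; report dominance instead")
    return delta_cost / delta_qalys


@dataclass(frozen=True)
class WtpThreshold:
    value: float
    multiplier: float
    gdp_per_capita: float


def derive_wtp(gdp_per_capita: float, multiplier: float = 3.0) -> WtpThreshold:
    """WTP = multiplier × GDP per capita, rounded to the nearest 10 US$."""
    if gdp_per_capita <= 0:
        raise ValueError("GDP per capita must be positive")
    raw = multiplier * gdp_per_capita
    value = round(raw / 10.0) * 10.0
    return WtpThreshold(value, multiplier, gdp_per_capita)


def nmb(result: StrategyResult | tuple[float, float],
        wtp: WtpThreshold | float) -> float:
    """Net monetary benefit at the given threshold."""
    if isinstance(result, StrategyResult):
        cost, qalys = result.total_cost, result.total_qalys
    else:
        cost, qalys = result
    thr = wtp.value if isinstance(wtp, WtpThreshold) else float(wtp)
    return thr * qalys - cost


@dataclass
class IncrementalTable:
    """Strategies sorted by ascending cost with incrementals and dominance flags.

    ``frame`` columns: strategy, total_cost, total_qalys, incremental_cost,
    incremental_qalys, icer, dominance.  Flags: ``none``, ``dominated`` (more
    costly, fewer QALYs), ``extendedly_dominated`` (frontier mode only) and
    ``dominant`` (cost-saving and more effective — no meaningful ratio).
    Dominated/dominant rows carry NaN ICERs.
    """

    frame: pd.DataFrame
    reference: str
    mode: str

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        for col in ("total_cost", "total_qalys", "incremental_cost",
                    "incremental_qalys", "icer"):
            out[f"{col}_unrounded"] = out[col]
            out[col] = out[col].round(2)
        out.to_csv(path, index=False)

    def row(self, strategy: str) -> pd.Series:
        return self.frame.set_index("strategy").loc[strategy]


def _totals(results) -> pd.DataFrame:
    if isinstance(results, Mapping):
        items = results.items()
    else:
        items = [(r.strategy, r) for r in results]
    return pd.DataFrame(
        [{"strategy": name, "total_cost": r.total_cost, "total_qalys": r.total_qalys}
         for name, r in items]
    )


def build_incremental_table(
    results: Mapping[str, StrategyResult] | list[StrategyResult],
    reference: str,
    mode: str = "paper",
) -> IncrementalTable:
    """Incremental table in ``paper`` (fixed-reference) or ``frontier`` mode."""
    df = _totals(results)
    if len(df) < 2:
        raise ValueError("need at least two strategies")
    if reference not in set(df["strategy"]):
        raise KeyError(f"unknown reference strategy {reference!r}")
    if mode not in ("paper", "frontier"):
        raise ValueError("mode must be 'paper' or 'frontier'")
    df = df.sort_values("total_cost", kind="stable").reset_index(drop=True)
    df["incremental_cost"] = np.nan
    df["incremental_qalys"] = np.nan
    df["icer"] = np.nan
    df["dominance"] = "none"

    if mode == "paper":
        ref = df[df["strategy"] == reference].iloc[0]
        for i in df.index:
            if df.loc[i, "strategy"] == reference:
                continue
            dc = df.loc[i, "total_cost"] - ref["total_cost"]
            dq = df.loc[i, "total_qalys"] - ref["total_qalys"]
            df.loc[i, "incremental_cost"] = dc
            df.loc[i, "incremental_qalys"] = dq
            if dc > 0 and dq < 0:
                df.loc[i, "dominance"] = "dominated"
            elif dc < 0 and dq > 0:
                df.loc[i, "dominance"] = "dominant"
            elif dq != 0:
                df.loc[i, "icer"] = dc / dq
        return IncrementalTable(df, reference, mode)

    # Frontier mode: strong dominance, then extended dominance with
    # non-decreasing sequential ICERs along the frontier.
    for i in df.index:
        cheaper = df.loc[: i - 1]
        if len(cheaper) and (cheaper["total_qalys"] >= df.loc[i, "total_qalys"]).any():
            df.loc[i, "dominance"] = "dominated"

    def _sequential(frontier: list[int]) -> list[float]:
        icers = []
        for a, b in zip(frontier[:-1], frontier[1:]):
            dc = df.loc[b, "total_cost"] - df.loc[a, "total_cost"]
            dq = df.loc[b, "total_qalys"] - df.loc[a, "total_qalys"]
            icers.append(dc / dq if dq != 0 else math.inf)
        return icers

    frontier = [i for i in df.index if df.loc[i, "dominance"] == "none"]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        icers = _sequential(frontier)
        for j in range(len(icers) - 1):
            if icers[j] > icers[j + 1]:
                df.loc[frontier[j + 1], "dominance"] = "extendedly_dominated"
                frontier.pop(j + 1)
                changed = True
                break
    icers = _sequential(frontier)
    for pos, i in enumerate(frontier):
        if pos == 0:
            continue
        prev = frontier[pos - 1]
        df.loc[i, "incremental_cost"] = df.loc[i, "total_cost"] - df.loc[prev, "total_cost"]
        df.loc[i, "incremental_qalys"] = (
            df.loc[i, "total_qalys"] - df.loc[prev, "total_qalys"])
        df.loc[i, "icer"] = icers[pos - 1]
    return IncrementalTable(df, reference, mode)
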