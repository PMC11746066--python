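"""Markov cohort engine for the TKI treatment-sequencing model.

The published model has five clinical states (first-line CP, second-line CP,
AP/BP, allogeneic SCT, death).  Internally each strategy's state space is
expanded so that per-drug costs and progression risks can be carried exactly:

* ``CP1`` — chronic phase on the strategy's first-line drug;
* ``CP2:<d>`` — chronic phase on second-line drug *d*, one state per switch
  destination;
* ``APBP:<d>`` — accelerated/blast phase tagged by the drug progressed from
  (the tag only matters for the AP/BP drug-cost convention);
* ``SCT_Y1`` / ``SCT_POST`` — first and subsequent post-transplant years;
* ``DEATH`` — absorbing.

Summing the expanded trace back to the five clinical states is exact; see
:func:`aggregate_occupancy`.

Competing risks within a cycle are ordered death-first: the annual death
probability is applied, and clinical events (treatment switch, progression,
SCT receipt) are applied to survivors, which keeps every row of the transition
matrix a proper probability distribution without rescaling.

Accumulation applies a half-cycle correction (state membership credited at the
average of the two cycle boundaries), discounts cycle *k* at the mid-cycle
exponent (1+r)^-(k-1/2) by default, and charges one-time costs (SCT procedure,
adverse-event bundle at treatment-line initiation) to entrant counts at the
entry cycle's discount factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .parameters import ModelSpec, validate

__all__ = [
    "StateSpace",
    "Trace",
    "StrategyResult",
    "ModelConsistencyError",
    "build_state_space",
    "build_transition_matrix",
    "run_trace",
    "accumulate",
    "run_strategy",
    "run_all",
    "aggregate_occupancy",
    "PAPER_STATES",
]

ROW_TOL = 1e-9

PAPER_STATES = ("FIRST_LINE", "SECOND_LINE", "APBP", "SCT", "DEATH")


class ModelConsistencyError(RuntimeError):
    """A computed transition row failed to be a probability distribution."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered expanded state space for one strategy."""

    strategy: str
    first_drug: str
    destinations: tuple[str, ...]
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def i_cp1(self) -> int:
        return 0

    def i_cp2(self, drug: str) -> int:
        return self.index(f"CP2:{drug}")

    def i_apbp(self, drug: str) -> int:
        return self.index(f"APBP:{drug}")

    @property
    def i_sct_y1(self) -> int:
        return self.index("SCT_Y1")

    @property
    def i_sct_post(self) -> int:
        return self.index("SCT_POST")

    @property
    def i_death(self) -> int:
        return self.index("DEATH")

    def paper_state(self, label: str) -> str:
        """Map an expanded state label to one of the five clinical states."""
        if label == "CP1":
            return "FIRST_LINE"
        if label.startswith("CP2:"):
            return "SECOND_LINE"
        if label.startswith("APBP:"):
            return "APBP"
        if label in ("SCT_Y1", "SCT_POST"):
            return "SCT"
        return "DEATH"


def build_state_space(spec: ModelSpec, strategy: str) -> StateSpace:
    strat = spec.strategy(strategy)  # KeyError for unknown strategy
    if not strat.switch.splits:
        raise ValueError(
            f"strategy {strategy!r} has an empty switch rule; the state space "
            "needs at least one second-line destination")
    dests = tuple(strat.switch.splits)
    labels = ("CP1",
              *(f"CP2:{d}" for d in dests),
              *(f"APBP:{d}" for d in dests),
              "SCT_Y1", "SCT_POST", "DEATH")
    return StateSpace(strategy, strat.first_line, dests, labels)


def build_transition_matrix(
    spec: ModelSpec, strategy: str, cycle: int = 1
) -> np.ndarray:
    """Per-cycle transition matrix over the expanded state space.

    ``cycle`` (1-based) only matters under the ``first_cycle_only`` switch
    convention, where the first-line failure hazard applies in cycle 1 only.
    """
    space = build_state_space(spec, strategy)
    strat = spec.strategy(strategy)
    conv = spec.econ.conventions

    first = spec.drugs[strat.first_line]
    n = space.n
    M = np.zeros((n, n))

    switching = conv.switch_mode == "per_cycle" or cycle == 1
    p_switch = (1.0 - first.ccyr) if switching else 0.0

    # CP1: death first, survivors switch per the rule or remain.
    i = space.i_cp1
    M[i, space.i_death] = 1.0 - first.os_cp
    M[i, i] = first.os_cp * (1.0 - p_switch)
    for d, prop in strat.switch.splits.items():
        M[i, space.i_cp2(d)] = first.os_cp * p_switch * prop

    # CP2[d]: death first, survivors progress to APBP[d] or remain.
    for d in space.destinations:
        drug = spec.drugs[d]
        i = space.i_cp2(d)
        M[i, space.i_death] = 1.0 - drug.os_cp
        M[i, space.i_apbp(d)] = drug.os_cp * drug.p_apbp
        M[i, i] = drug.os_cp * (1.0 - drug.p_apbp)

    # APBP[d]: SCT receipt first; non-recipients die or remain.
    t = spec.transplant
    for d in space.destinations:
        i = space.i_apbp(d)
        M[i, space.i_sct_y1] = t.p_receive
        M[i, space.i_death] = (1.0 - t.p_receive) * (1.0 - spec.apbp.os)
        M[i, i] = (1.0 - t.p_receive) * spec.apbp.os

    # SCT year 1 -> post-SCT or death.
    M[space.i_sct_y1, space.i_sct_post] = t.os_y1
    M[space.i_sct_y1, space.i_death] = 1.0 - t.os_y1

    # Post-SCT long-term survival convention.
    os_post = first.os_cp if conv.os_post_mode == "first_line" else t.os_y1
    M[space.i_sct_post, space.i_sct_post] = os_post
    M[space.i_sct_post, space.i_death] = 1.0 - os_post

    M[space.i_death, space.i_death] = 1.0

    bad = np.abs(M.sum(axis=1) - 1.0) > ROW_TOL
    if bad.any() or (M < -ROW_TOL).any() or (M > 1 + ROW_TOL).any():
        rows = [space.labels[j] for j in np.nonzero(bad)[0]]
        raise ModelConsistencyError(
            f"transition rows are not probability distributions: {rows}")
    return M


@dataclass
class Trace:
    """Cohort trace: occupancy at cycle boundaries and per-cycle entrants.

    ``occupancy`` has shape (horizon+1, n_states); row 0 is the initial
    distribution.  ``entrants`` has the same shape; row 0 is the initial
    distribution (the cohort 'enters' its starting states at t=0) and row k>0
    is the fraction newly flowing into each state during cycle k.
    """

    state_space: StateSpace | None
    occupancy: np.ndarray
    entrants: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1


MatrixLike = np.ndarray | Sequence[np.ndarray] | Callable[[int], np.ndarray]


def _matrix_at(matrix: MatrixLike, cycle: int) -> np.ndarray:
    if callable(matrix):
        return matrix(cycle)
    if isinstance(matrix, np.ndarray) and matrix.ndim == 2:
        return matrix
    return matrix[cycle - 1]


def run_trace(
    matrix: MatrixLike,
    horizon: int,
    initial: np.ndarray | None = None,
    state_space: StateSpace | None = None,
) -> Trace:
    """Propagate the cohort through ``horizon`` cycles.

    ``matrix`` may be a single matrix, a sequence of per-cycle matrices, or a
    callable ``cycle -> matrix`` (cycles are 1-based).  The cohort starts with
    occupancy 1 in the first state unless ``initial`` is given.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    M0 = _matrix_at(matrix, 1)
    n = M0.shape[0]
    occ = np.zeros((horizon + 1, n))
    ent = np.zeros((horizon + 1, n))
    occ[0] = initial if initial is not None else np.eye(n)[0]
    ent[0] = occ[0]
    for k in range(1, horizon + 1):
        M = _matrix_at(matrix, k)
        new = occ[k - 1] @ M
        ent[k] = new - occ[k - 1] * np.diag(M)
        occ[k] = new
        if abs(new.sum() - occ[0].sum()) > 1e-9:
            raise ModelConsistencyError(f"occupancy not conserved at cycle {k}")
    return Trace(state_space, occ, ent)


@dataclass
class StrategyResult:
    """Discounted per-patient totals and the per-cycle breakdown."""

    strategy: str
    total_cost: float
    total_qalys: float
    per_cycle: pd.DataFrame
    trace: Trace | None = None

    def components(self) -> dict[str, float]:
        cols = ["cost_drug", "cost_followup", "cost_sct", "cost_ae"]
        return {c: float(self.per_cycle[c].sum()) for c in cols}


def _state_vectors(spec: ModelSpec, space: StateSpace):
    """Annual cost components and utilities per expanded state."""
    conv = spec.econ.conventions
    n = space.n
    drug_cost = np.zeros(n)
    followup = np.zeros(n)
    sct_cost = np.zeros(n)
    util = np.zeros(n)

    u = spec.utilities
    drug_cost[space.i_cp1] = spec.drugs[space.first_drug].annual_cost
    followup[space.i_cp1] = spec.costs.followup()
    util[space.i_cp1] = u.u_cp1
    for d in space.destinations:
        i = space.i_cp2(d)
        drug_cost[i] = spec.drugs[d].annual_cost
        followup[i] = spec.costs.followup()
        util[i] = u.u_cp2
        j = space.i_apbp(d)
        if conv.apbp_drug_cost == "continue":
            drug_cost[j] = spec.drugs[d].annual_cost
        followup[j] = spec.costs.followup()
        util[j] = u.u_apbp
    sct_cost[space.i_sct_y1] = spec.transplant.cost_y1
    sct_cost[space.i_sct_post] = spec.transplant.cost_post
    util[space.i_sct_y1] = u.u_sct_y1
    util[space.i_sct_post] = u.u_sct_post
    util[space.i_death] = u.u_death
    return drug_cost, followup, sct_cost, util


def discount_factor(spec: ModelSpec, cycle: int) -> float:
    """Discount factor for cycle ``cycle`` (1-based) per the timing convention."""
    r = spec.econ.discount_rate
    dt = spec.econ.cycle_length_years
    if spec.econ.conventions.discount_timing == "mid_cycle":
        return float((1.0 + r) ** (-(cycle - 0.5) * dt))
    return float((1.0 + r) ** (-cycle * dt))


def accumulate(spec: ModelSpec, strategy: str, trace: Trace) -> StrategyResult:
    """Half-cycle-corrected, discounted cost and QALY accumulation."""
    space = trace.state_space or build_state_space(spec, strategy)
    if space.strategy != strategy:
        raise ValueError(
            f"trace was built for strategy {space.strategy!r}, not {strategy!r}")
    drug_cost, followup, sct_cost, util = _state_vectors(spec, space)
    dt = spec.econ.cycle_length_years
    ae_bundle = spec.costs.ae_bundle()
    cp2_idx = [space.i_cp2(d) for d in space.destinations]

    H = trace.horizon
    rows = []
    # Cycle 0: treatment-line initiation of the whole cohort (AE bundle),
    # charged at t=0 undiscounted.
    init_ae = float(trace.entrants[0, space.i_cp1]) * ae_bundle
    rows.append(dict(cycle=0, discount=1.0, cost_drug=0.0, cost_followup=0.0,
                     cost_sct=0.0, cost_ae=init_ae, qalys=0.0))
    for k in range(1, H + 1):
        eff = 0.5 * (trace.occupancy[k - 1] + trace.occupancy[k])
        df = discount_factor(spec, k)
        c_drug = float(eff @ drug_cost) * dt
        c_follow = float(eff @ followup) * dt
        c_sct = float(eff @ sct_cost) * dt
        c_sct += float(trace.entrants[k, space.i_sct_y1]) * spec.transplant.cost_initial
        c_ae = float(trace.entrants[k, cp2_idx].sum()) * ae_bundle
        q = float(eff @ util) * dt
        rows.append(dict(cycle=k, discount=df,
                         cost_drug=df * c_drug, cost_followup=df * c_follow,
                         cost_sct=df * c_sct, cost_ae=df * c_ae,
                         qalys=df * q))
    per_cycle = pd.DataFrame(rows)
    per_cycle["cost_total"] = per_cycle[
        ["cost_drug", "cost_followup", "cost_sct", "cost_ae"]].sum(axis=1)
    total_cost = float(per_cycle["cost_total"].sum())
    total_qalys = float(per_cycle["qalys"].sum())
    return StrategyResult(strategy, total_cost, total_qalys, per_cycle, trace)


def run_strategy(spec: ModelSpec, strategy: str) -> StrategyResult:
    """Build the state space and matrices, run the trace, accumulate."""
    space = build_state_space(spec, strategy)
    H = spec.econ.horizon_cycles
    if spec.econ.conventions.switch_mode == "per_cycle":
        matrix: MatrixLike = build_transition_matrix(spec, strategy, cycle=1)
    else:
        M1 = build_transition_matrix(spec, strategy, cycle=1)
        M2 = build_transition_matrix(spec, strategy, cycle=2)
        matrix = lambda k: M1 if k == 1 else M2  # noqa: E731
    trace = run_trace(matrix, H, state_space=space)
    return accumulate(spec, strategy, trace)


def run_all(spec: ModelSpec, check: bool = False) -> dict[str, StrategyResult]:
    """Run every strategy in the spec; optionally validate first."""
    if check:
        issues = validate(spec)
        if issues:
            raise ValueError("invalid model spec:\n  "
                             + "\n  ".join(str(i) for i in issues))
    return {s.name: run_strategy(spec, s.name) for s in spec.strategies}


def aggregate_occupancy(trace: Trace) -> pd.DataFrame:
    """Sum the expanded trace back to the five clinical states (exact)."""
    space = trace.state_space
    if space is None:
        raise ValueError("trace carries no state space")
    out = pd.DataFrame(0.0, index=range(trace.horizon + 1), columns=list(PAPER_STATES))
    for j, label in enumerate(space.labels):
        out[space.paper_state(label)] += trace.occupancy[:, j]
    out.index.name = "cycle"
    return out
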