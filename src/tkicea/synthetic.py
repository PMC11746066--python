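"""Random valid model specifications for property-based testing.

The generator emulates the statistical shape of the published parameter set:
a handful of drugs with per-cycle response, survival and progression
probabilities, one strategy per drug whose failures split across the other
drugs, transplant parameters, positive costs on a log-uniform scale, bounded
utilities, and a coherent sensitivity range bracketing every base value.
Probabilities are drawn from beta(2, 2) rescaled into configured bounds so
that both near-boundary and central regimes are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    AdverseEvent,
    ApBpParams,
    Conventions,
    CostSet,
    DrugProfile,
    EconSettings,
    ModelSpec,
    ParameterRange,
    Strategy,
    SwitchRule,
    TransplantParams,
    UtilitySet,
    _is_probability_like,
    validate,
)

__all__ = ["GeneratorConfig", "random_model", "perturb"]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_drugs: int = 3
    prob_low: float = 0.05
    prob_high: float = 0.95
    cost_scale: float = 10_000.0
    range_width: float = 0.3
    horizon_low: int = 5
    horizon_high: int = 30

    def __post_init__(self):
        if not (2 <= self.n_drugs <= 4):
            raise ValueError("n_drugs must be in 2..4")
        if not (0.0 <= self.prob_low < self.prob_high <= 1.0):
            raise ValueError("probability bounds must nest inside [0, 1]")
        if self.range_width < 0 or self.cost_scale <= 0:
            raise ValueError("range_width >= 0 and cost_scale > 0 required")
        if not (1 <= self.horizon_low <= self.horizon_high):
            raise ValueError("horizon bounds must satisfy 1 <= low <= high")


def _prob(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo + (hi - lo) * rng.beta(2.0, 2.0))


def _cost(rng: np.random.Generator, scale: float) -> float:
    # log-uniform over two decades centred on the configured scale
    return float(scale * 10 ** rng.uniform(-1.0, 1.0))


def random_model(config: GeneratorConfig) -> ModelSpec:
    """A random ModelSpec that passes validation; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.prob_low, config.prob_high
    names = [f"drug_{chr(ord('a') + i)}" for i in range(config.n_drugs)]

    drugs = {
        name: DrugProfile(
            name=name,
            annual_cost=_cost(rng, config.cost_scale),
            ccyr=_prob(rng, lo, hi),
            os_cp=_prob(rng, max(lo, 0.5), hi),
            p_apbp=_prob(rng, min(lo, 0.01), min(hi, 0.4)),
        )
        for name in names
    }

    strategies = []
    for name in names:
        others = [d for d in names if d != name]
        props = rng.dirichlet(np.ones(len(others)))
        # renormalize in float to meet the 1e-9 sum invariant exactly enough
        props = props / props.sum()
        splits = {d: float(p) for d, p in zip(others, props)}
        strategies.append(Strategy(name, name, SwitchRule(name, splits)))

    transplant = TransplantParams(
        p_receive=_prob(rng, 0.0, 0.4),
        os_y1=_prob(rng, 0.1, 0.9),
        cost_initial=_cost(rng, config.cost_scale),
        cost_y1=_cost(rng, config.cost_scale / 10),
        cost_post=_cost(rng, config.cost_scale / 10),
    )
    apbp = ApBpParams(os=_prob(rng, min(lo, 0.02), min(hi, 0.6)))
    costs = CostSet(
        consult=_cost(rng, config.cost_scale / 50),
        monitoring=_cost(rng, config.cost_scale / 10),
        adverse_events=[
            AdverseEvent(f"ae_{i}", _cost(rng, config.cost_scale / 20),
                         _prob(rng, 0.0, 0.3))
            for i in range(int(rng.integers(1, 4)))
        ],
    )
    utilities = UtilitySet(
        u_cp1=_prob(rng, 0.5, 0.99),
        u_cp2=_prob(rng, 0.3, 0.95),
        u_apbp=_prob(rng, 0.05, 0.6),
        u_sct_y1=_prob(rng, 0.2, 0.8),
        u_sct_post=_prob(rng, 0.4, 0.99),
    )
    econ = EconSettings(
        discount_rate=float(rng.uniform(0.0, 0.1)),
        horizon_cycles=int(rng.integers(config.horizon_low, config.horizon_high + 1)),
        gdp_per_capita=_cost(rng, config.cost_scale),
        conventions=Conventions(),
    )

    spec = ModelSpec(drugs, strategies, transplant, apbp, costs, utilities, econ, [])
    spec.ranges = _ranges_for(spec, rng, config.range_width)

    issues = validate(spec)
    if issues:  # pragma: no cover - generator contract
        raise AssertionError(f"generator produced invalid spec: {issues}")
    return spec


_RANGED = [
    "drugs.{d}.annual_cost", "drugs.{d}.ccyr", "drugs.{d}.os_cp", "drugs.{d}.p_apbp",
]


def _ranges_for(spec: ModelSpec, rng: np.random.Generator,
                width: float) -> list[ParameterRange]:
    pids = []
    for d in spec.drugs:
        pids += [t.format(d=d) for t in _RANGED]
    pids += ["transplant.p_receive", "transplant.os_y1", "transplant.cost_initial",
             "transplant.cost_y1", "transplant.cost_post", "apbp.os",
             "costs.consult", "costs.monitoring",
             "utilities.u_cp1", "utilities.u_cp2", "utilities.u_apbp",
             "utilities.u_sct_y1", "utilities.u_sct_post"]
    pids += [f"costs.ae.{a.name}.cost" for a in spec.costs.adverse_events]
    ranges = []
    for pid in pids:
        base = spec.get(pid)
        w = width * float(rng.uniform(0.0, 1.0))
        lo, hi = base * (1 - w), base * (1 + w)
        if _is_probability_like(pid):
            lo, hi = max(lo, 0.0), min(hi, 1.0)
            family = "beta" if hi > lo and 0 < base < 1 else "fixed"
        else:
            family = "gamma" if hi > lo else "fixed"
        ranges.append(ParameterRange(pid, lo, hi, family))
    return ranges


def perturb(spec: ModelSpec, parameter: str, delta: float) -> ModelSpec:
    """Clone with one parameter shifted by ``delta``; the original is untouched."""
    out = spec.clone()
    new = out.get(parameter) + delta
    if _is_probability_like(parameter) and not (0.0 <= new <= 1.0):
        raise ValueError(f"perturbation pushes {parameter} outside [0, 1]")
    if not _is_probability_like(parameter) and new < 0.0:
        raise ValueError(f"perturbation pushes {parameter} below 0")
    out.set(parameter, new)
    rng_entry = out.range_for(parameter)
    if rng_entry is not None:  # keep the range bracketing the new base
        rng_entry.low = min(rng_entry.low, new)
        rng_entry.high = max(rng_entry.high, new)
    return out
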