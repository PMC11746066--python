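"""Parameterization of the CML TKI treatment-sequencing decision model.

The decision problem compares three first-line tyrosine kinase inhibitor (TKI)
strategies for chronic-phase chronic myeloid leukemia — imatinib, nilotinib and
dasatinib — in a Markov cohort model with annual cycles.  Every quantity the
model needs (per-cycle transition probabilities, annual and per-event costs in
2024 US$, health-state utilities, economic settings and the sensitivity-analysis
ranges attached to each parameter) lives in a :class:`ModelSpec`.

A packaged base case (:func:`builtin_basecase`) carries the published South
African parameter set; :func:`load_config` overlays user overrides from a YAML
file on top of it.  Parameters are addressable by dotted path (for example
``drugs.nilotinib.annual_cost`` or ``utilities.u_apbp``), which is how the
sensitivity-analysis modules sweep and redraw them.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "AdverseEvent",
    "ApBpParams",
    "ConfigError",
    "Conventions",
    "CostSet",
    "DrugProfile",
    "EconSettings",
    "Issue",
    "ModelSpec",
    "ParameterRange",
    "Strategy",
    "SwitchRule",
    "TransplantParams",
    "UtilitySet",
    "builtin_basecase",
    "fallback_range",
    "load_config",
    "save_config",
    "spec_from_dict",
    "spec_to_dict",
    "validate",
]

SPLIT_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or maps to no known key."""


@dataclass
class DrugProfile:
    """One TKI: its annual acquisition cost and the per-cycle clinical probabilities.

    ``ccyr`` is the probability of complete cytogenetic response per annual
    cycle; its complement is the treatment-failure (switch) hazard while the
    drug is used first line.  ``os_cp`` is the annual overall-survival
    probability while on the drug in chronic phase, and ``p_apbp`` the annual
    probability of progression to the merged accelerated/blast phase while the
    drug is used second line.
    """

    name: str
    annual_cost: float
    ccyr: float
    os_cp: float
    p_apbp: float


@dataclass
class SwitchRule:
    """Where first-line failures go: destination drug -> proportion (sums to 1)."""

    from_drug: str
    splits: dict[str, float]


@dataclass
class Strategy:
    name: str
    first_line: str
    switch: SwitchRule


@dataclass
class TransplantParams:
    """Allogeneic stem-cell transplantation from AP/BP.

    ``p_receive`` is the annual probability of undergoing SCT while in AP/BP;
    ``os_y1`` the first-year post-SCT survival (its complement is the printed
    remainder "death post-SCT").  ``cost_initial`` is a one-time procedure cost
    charged on entry, ``cost_y1``/``cost_post`` annual follow-up costs in the
    first and subsequent post-SCT years.
    """

    p_receive: float
    os_y1: float
    cost_initial: float
    cost_y1: float
    cost_post: float


@dataclass
class ApBpParams:
    """Merged accelerated/blast phase: annual survival probability."""

    os: float


@dataclass
class AdverseEvent:
    """A grade-3/4 adverse event costed once per treatment-line initiation."""

    name: str
    cost: float
    incidence: float


@dataclass
class CostSet:
    consult: float
    monitoring: float
    adverse_events: list[AdverseEvent]

    def ae_bundle(self) -> float:
        """Expected one-time AE cost per treatment-line initiation."""
        return sum(a.cost * a.incidence for a in self.adverse_events)

    def followup(self) -> float:
        """Recurring annual consultation + monitoring cost for CP/AP-BP states."""
        return self.consult + self.monitoring


@dataclass
class UtilitySet:
    u_cp1: float
    u_cp2: float
    u_apbp: float
    u_sct_y1: float
    u_sct_post: float
    u_death: float = 0.0


@dataclass
class Conventions:
    """Structural convention flags where the published model is ambiguous.

    switch_mode
        ``per_cycle`` applies the (1 - CCyR) first-line failure hazard every
        cycle spent first line; ``first_cycle_only`` applies it in cycle 1 only.
    discount_timing
        ``mid_cycle`` discounts cycle k at (1+r)^-(k-1/2), matching the
        half-cycle correction; ``end_cycle`` uses (1+r)^-k.
    apbp_drug_cost
        ``continue``: AP/BP keeps accruing the progressed-from drug's annual
        cost plus follow-up; ``none``: follow-up only.
    os_post_mode
        Long-term post-SCT annual survival: ``first_line`` proxies it with the
        strategy's first-line drug survival; ``constant`` reuses the printed
        first-year post-SCT survival every year.
    range_interpretation
        ``ci95`` reads sensitivity ranges as 95% intervals when deriving PSA
        distribution spreads; ``uniform`` samples the range uniformly.

    The shipped defaults are the grid point (switch_mode x discount_timing x
    apbp_drug_cost) that minimizes total relative deviation from the published
    base-case totals; see docs/methods.md and analysis/02_convention_grid.py.
    """

    switch_mode: str = "per_cycle"
    discount_timing: str = "mid_cycle"
    apbp_drug_cost: str = "continue"
    os_post_mode: str = "first_line"
    range_interpretation: str = "ci95"

    _ALLOWED = {
        "switch_mode": ("per_cycle", "first_cycle_only"),
        "discount_timing": ("mid_cycle", "end_cycle"),
        "apbp_drug_cost": ("continue", "none"),
        "os_post_mode": ("first_line", "constant"),
        "range_interpretation": ("ci95", "uniform"),
    }


@dataclass
class EconSettings:
    """Economic settings: 5% annual discounting of costs and effects, a 20-year
    horizon of 12-month cycles, and a WTP threshold of 3x GDP per capita
    (rounded to the nearest 10 US$) unless overridden."""

    discount_rate: float = 0.05
    horizon_cycles: int = 20
    cycle_length_years: float = 1.0
    gdp_per_capita: float = 6253.20
    wtp: float | None = None
    wtp_multiplier: float = 3.0
    cohort_size: int = 1000
    conventions: Conventions = field(default_factory=Conventions)


@dataclass
class ParameterRange:
    """Sensitivity range and PSA distribution family for one dotted parameter."""

    parameter: str
    low: float
    high: float
    family: str  # 'beta' | 'gamma' | 'fixed'


@dataclass(frozen=True)
class Issue:
    """A single validation failure: which parameter, which rule it violates."""

    parameter: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.parameter}: {self.rule}"


@dataclass
class ModelSpec:
    """Complete parameterization of the decision problem."""

    drugs: dict[str, DrugProfile]
    strategies: list[Strategy]
    transplant: TransplantParams
    apbp: ApBpParams
    costs: CostSet
    utilities: UtilitySet
    econ: EconSettings
    ranges: list[ParameterRange]

    # -- access helpers ----------------------------------------------------
    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(
            f"unknown strategy {name!r}; have {[s.name for s in self.strategies]}"
        )

    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]

    def clone(self) -> "ModelSpec":
        return copy.deepcopy(self)

    def wtp(self) -> float:
        """Effective WTP threshold: explicit override, else derived from GDP."""
        if self.econ.wtp is not None:
            return float(self.econ.wtp)
        from .cea import derive_wtp  # local import to avoid a cycle

        return derive_wtp(self.econ.gdp_per_capita, self.econ.wtp_multiplier).value

    def range_for(self, parameter: str) -> ParameterRange | None:
        for r in self.ranges:
            if r.parameter == parameter:
                return r
        return None

    # -- dotted-path parameter access --------------------------------------
    def get(self, parameter: str) -> float:
        obj, attr = _resolve(self, parameter)
        return getattr(obj, attr)

    def set(self, parameter: str, value: float) -> None:
        obj, attr = _resolve(self, parameter)
        setattr(obj, attr, value)


def _resolve(spec: ModelSpec, pid: str) -> tuple[Any, str]:
    """Map a dotted parameter id to (owning object, attribute name)."""
    parts = pid.split(".")
    try:
        head = parts[0]
        if head == "drugs":
            return spec.drugs[parts[1]], parts[2]
        if head == "transplant":
            return spec.transplant, parts[1]
        if head == "apbp":
            return spec.apbp, parts[1]
        if head == "utilities":
            return spec.utilities, parts[1]
        if head == "econ":
            return spec.econ, parts[1]
        if head == "costs":
            if parts[1] == "ae":
                for ae in spec.costs.adverse_events:
                    if ae.name == parts[2]:
                        return ae, parts[3]
                raise KeyError(parts[2])
            return spec.costs, parts[1]
        if head == "strategies":
            strat = spec.strategy(parts[1])
            if parts[2] == "switch":
                return _SplitHandle(strat.switch, parts[3]), "value"
            return strat, parts[2]
    except (IndexError, KeyError) as exc:
        raise KeyError(f"unknown parameter id {pid!r}") from exc
    raise KeyError(f"unknown parameter id {pid!r}")


class _SplitHandle:
    """Attribute-style view onto one entry of a switch-rule split dict."""

    def __init__(self, rule: SwitchRule, dest: str):
        if dest not in rule.splits:
            raise KeyError(dest)
        self._rule, self._dest = rule, dest

    @property
    def value(self) -> float:
        return self._rule.splits[self._dest]

    @value.setter
    def value(self, v: float) -> None:
        self._rule.splits[self._dest] = v


# ---------------------------------------------------------------------------
# Base case
# ---------------------------------------------------------------------------

def _is_probability_like(pid: str) -> bool:
    leaf = pid.rsplit(".", 1)[-1]
    return leaf.startswith("u_") or leaf in {
        "ccyr",
        "os_cp",
        "p_apbp",
        "p_receive",
        "os_y1",
        "os",
        "incidence",
        "discount_rate",
    }


def fallback_range(parameter: str, base: float, width: float = 0.5) -> ParameterRange:
    """+/-50% default range for a parameter without published bounds.

    Probabilities and utilities are capped at 1 on the high side and use a beta
    family; costs use gamma.
    """
    low = base * (1.0 - width)
    high = base * (1.0 + width)
    if _is_probability_like(parameter):
        return ParameterRange(parameter, max(low, 0.0), min(high, 1.0), "beta")
    return ParameterRange(parameter, max(low, 0.0), high, "gamma")


def builtin_basecase(apbp_range_literal: bool = False) -> ModelSpec:
    """The packaged South African base case.

    ``apbp_range_literal`` selects the literal printed sensitivity range
    (0.42-0.54) for the imatinib progression probability instead of the default
    corrected reading (0.042-0.054).
    """
    drugs = {
        "imatinib": DrugProfile("imatinib", 4634.40, 0.67, 0.977, 0.048),
        "nilotinib": DrugProfile("nilotinib", 24517.94, 0.76, 0.933, 0.019),
        "dasatinib": DrugProfile("dasatinib", 10790.80, 0.80, 0.931, 0.043),
    }
    strategies = [
        Strategy("imatinib", "imatinib",
                 SwitchRule("imatinib", {"nilotinib": 0.50, "dasatinib": 0.50})),
        Strategy("nilotinib", "nilotinib",
                 SwitchRule("nilotinib", {"imatinib": 0.15, "dasatinib": 0.85})),
        Strategy("dasatinib", "dasatinib",
                 SwitchRule("dasatinib", {"imatinib": 0.15, "nilotinib": 0.85})),
    ]
    transplant = TransplantParams(
        p_receive=0.038, os_y1=0.429,
        cost_initial=14722.43, cost_y1=543.55, cost_post=427.80,
    )
    apbp = ApBpParams(os=0.052)
    costs = CostSet(
        consult=94.91,
        monitoring=806.25,
        adverse_events=[
            AdverseEvent("non_haematological", 23.53, 0.05),
            AdverseEvent("neutropenia", 358.50, 0.05),
            AdverseEvent("thrombocytopenia", 1164.28, 0.05),
            AdverseEvent("anaemia", 799.39, 0.05),
        ],
    )
    utilities = UtilitySet(0.89, 0.75, 0.22, 0.60, 0.85, 0.0)
    econ = EconSettings()

    apbp_ima = (0.42, 0.54) if apbp_range_literal else (0.042, 0.054)
    R = ParameterRange
    ranges = [
        R("drugs.imatinib.ccyr", 0.60, 0.81, "beta"),
        R("drugs.nilotinib.ccyr", 0.63, 0.85, "beta"),
        R("drugs.dasatinib.ccyr", 0.68, 0.92, "beta"),
        R("drugs.imatinib.p_apbp", *apbp_ima, "beta"),
        R("drugs.nilotinib.p_apbp", 0.017, 0.021, "beta"),
        R("drugs.dasatinib.p_apbp", 0.037, 0.049, "beta"),
        R("drugs.imatinib.os_cp", 0.83, 1.0, "beta"),
        R("drugs.nilotinib.os_cp", 0.79, 1.0, "beta"),
        R("drugs.dasatinib.os_cp", 0.81, 1.0, "beta"),
        R("apbp.os", 0.046, 0.060, "beta"),
        R("transplant.p_receive", 0.0, 1.0, "beta"),
        R("transplant.os_y1", 0.354, 0.504, "beta"),
        R("drugs.imatinib.annual_cost", 2317.20, 6951.60, "gamma"),
        R("drugs.nilotinib.annual_cost", 12258.97, 36776.91, "gamma"),
        R("drugs.dasatinib.annual_cost", 5395.40, 16186.20, "gamma"),
        R("costs.consult", 47.46, 142.37, "gamma"),
        R("costs.monitoring", 403.12, 1209.38, "gamma"),
        R("transplant.cost_y1", 271.78, 815.32, "gamma"),
        R("transplant.cost_post", 213.90, 641.70, "gamma"),
        R("transplant.cost_initial", 7361.21, 22083.64, "gamma"),
        R("costs.ae.non_haematological.cost", 11.75, 35.29, "gamma"),
        R("costs.ae.neutropenia.cost", 179.25, 537.75, "gamma"),
        R("costs.ae.thrombocytopenia.cost", 582.14, 1746.42, "gamma"),
        R("costs.ae.anaemia.cost", 399.70, 1199.08, "gamma"),
        R("utilities.u_cp1", 0.78, 0.94, "beta"),
        R("utilities.u_cp2", 0.57, 0.85, "beta"),
        R("utilities.u_apbp", 0.07, 0.34, "beta"),
        R("utilities.u_sct_y1", 0.51, 0.69, "beta"),
        R("utilities.u_sct_post", 0.723, 0.978, "beta"),
    ]
    return ModelSpec(drugs, strategies, transplant, apbp, costs, utilities, econ, ranges)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_prob(issues: list[Issue], pid: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        issues.append(Issue(pid, "probability out of range [0, 1]"))


def _check_cost(issues: list[Issue], pid: str, value: float) -> None:
    if value < 0.0:
        issues.append(Issue(pid, "cost < 0"))


def validate(spec: ModelSpec, check_ranges: bool = True) -> list[Issue]:
    """Return every invariant violation in ``spec`` (empty list = valid).

    ``check_ranges=False`` skips the requirement that each base value lie
    inside its sensitivity range — Monte-Carlo draws may legitimately leave
    the printed range when it is read as a 95% interval.
    """
    issues: list[Issue] = []

    for name, d in spec.drugs.items():
        base = f"drugs.{name}"
        _check_prob(issues, f"{base}.ccyr", d.ccyr)
        _check_prob(issues, f"{base}.os_cp", d.os_cp)
        _check_prob(issues, f"{base}.p_apbp", d.p_apbp)
        _check_cost(issues, f"{base}.annual_cost", d.annual_cost)

    seen_first_line: set[str] = set()
    for s in spec.strategies:
        base = f"strategies.{s.name}"
        if s.first_line not in spec.drugs:
            issues.append(Issue(f"{base}.first_line", "references unknown drug"))
        if s.first_line in seen_first_line:
            issues.append(Issue(f"{base}.first_line",
                                "more than one switch rule for this first-line drug"))
        seen_first_line.add(s.first_line)
        rule = s.switch
        if not rule.splits:
            issues.append(Issue(f"{base}.switch", "switch rule has no destinations"))
        total = sum(rule.splits.values())
        if rule.splits and abs(total - 1.0) > SPLIT_TOL:
            issues.append(Issue(f"{base}.switch", f"splits sum != 1 (got {total!r})"))
        for dest, p in rule.splits.items():
            if dest == s.first_line:
                issues.append(Issue(f"{base}.switch.{dest}",
                                    "switch destination equals first-line drug"))
            if dest not in spec.drugs:
                issues.append(Issue(f"{base}.switch.{dest}", "references unknown drug"))
            _check_prob(issues, f"{base}.switch.{dest}", p)

    t = spec.transplant
    _check_prob(issues, "transplant.p_receive", t.p_receive)
    _check_prob(issues, "transplant.os_y1", t.os_y1)
    for attr in ("cost_initial", "cost_y1", "cost_post"):
        _check_cost(issues, f"transplant.{attr}", getattr(t, attr))

    _check_prob(issues, "apbp.os", spec.apbp.os)

    _check_cost(issues, "costs.consult", spec.costs.consult)
    _check_cost(issues, "costs.monitoring", spec.costs.monitoring)
    for ae in spec.costs.adverse_events:
        _check_cost(issues, f"costs.ae.{ae.name}.cost", ae.cost)
        _check_prob(issues, f"costs.ae.{ae.name}.incidence", ae.incidence)

    u = spec.utilities
    for attr in ("u_cp1", "u_cp2", "u_apbp", "u_sct_y1", "u_sct_post", "u_death"):
        _check_prob(issues, f"utilities.{attr}", getattr(u, attr))
    if u.u_death != 0.0:
        issues.append(Issue("utilities.u_death", "death utility must equal 0"))

    e = spec.econ
    if not (0.0 <= e.discount_rate <= 1.0):
        issues.append(Issue("econ.discount_rate", "discount rate out of range [0, 1]"))
    if e.horizon_cycles < 1:
        issues.append(Issue("econ.horizon_cycles", "horizon must be >= 1 cycle"))
    if e.wtp is not None and e.wtp < 0:
        issues.append(Issue("econ.wtp", "WTP threshold < 0"))
    for flag, allowed in Conventions._ALLOWED.items():
        if getattr(e.conventions, flag) not in allowed:
            issues.append(Issue(f"econ.conventions.{flag}",
                                f"must be one of {allowed}"))

    for r in spec.ranges:
        if not check_ranges:
            break
        if r.low > r.high:
            issues.append(Issue(r.parameter, "range low > high"))
        if r.family not in ("beta", "gamma", "fixed"):
            issues.append(Issue(r.parameter, "unknown distribution family"))
        try:
            base = spec.get(r.parameter)
        except KeyError:
            issues.append(Issue(r.parameter, "range refers to unknown parameter"))
            continue
        if not (r.low - SPLIT_TOL <= base <= r.high + SPLIT_TOL):
            issues.append(Issue(r.parameter, "base value outside sensitivity range"))
        prob_like = _is_probability_like(r.parameter)
        if r.family == "beta" and not prob_like:
            issues.append(Issue(r.parameter, "beta family on a non-probability parameter"))
        if r.family == "gamma" and prob_like:
            issues.append(Issue(r.parameter, "gamma family on a probability parameter"))

    return issues


# ---------------------------------------------------------------------------
# Config serialization (YAML)
# ---------------------------------------------------------------------------

def spec_to_dict(spec: ModelSpec) -> dict:
    """Plain-dict form of a spec, mirroring the config schema."""
    return {
        "drugs": {
            name: {"annual_cost": d.annual_cost, "ccyr": d.ccyr,
                   "os_cp": d.os_cp, "p_apbp": d.p_apbp}
            for name, d in spec.drugs.items()
        },
        "strategies": [
            {"name": s.name, "first_line": s.first_line,
             "switch": dict(s.switch.splits)}
            for s in spec.strategies
        ],
        "transplant": dataclasses.asdict(spec.transplant),
        "apbp": dataclasses.asdict(spec.apbp),
        "costs": {
            "consult": spec.costs.consult,
            "monitoring": spec.costs.monitoring,
            "adverse_events": [dataclasses.asdict(a) for a in spec.costs.adverse_events],
        },
        "utilities": dataclasses.asdict(spec.utilities),
        "econ": {
            "discount_rate": spec.econ.discount_rate,
            "horizon_cycles": spec.econ.horizon_cycles,
            "cycle_length_years": spec.econ.cycle_length_years,
            "gdp_per_capita": spec.econ.gdp_per_capita,
            "wtp": spec.econ.wtp,
            "wtp_multiplier": spec.econ.wtp_multiplier,
            "cohort_size": spec.econ.cohort_size,
            "conventions": {
                f: getattr(spec.econ.conventions, f) for f in Conventions._ALLOWED
            },
        },
        "ranges": [dataclasses.asdict(r) for r in spec.ranges],
    }


_TOP_KEYS = ("drugs", "strategies", "transplant", "apbp", "costs",
             "utilities", "econ", "ranges")


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(
                f"unknown config key {here!r}; valid keys here: {sorted(base)}")
        if isinstance(base[key], dict) and isinstance(val, Mapping):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


_DRUG_FIELDS = {"annual_cost", "ccyr", "os_cp", "p_apbp"}


def spec_from_dict(data: Mapping) -> ModelSpec:
    """Build a ModelSpec from a config mapping; omitted fields default to the
    packaged base case.

    The ``drugs`` section merges per drug (a partial mapping overrides fields
    of a base-case drug; a complete profile adds a new drug).  ``strategies``
    and ``ranges`` replace their sections wholly when present, and a config
    that redefines ``strategies`` together with ``drugs`` defines the drug set
    exactly (base-case drugs are not inherited) — this is what makes saved
    configs of arbitrary models round-trip.
    """
    base = spec_to_dict(builtin_basecase())
    unknown = set(data) - set(_TOP_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown config section(s) {sorted(unknown)}; valid: {list(_TOP_KEYS)}")

    merged = dict(base)

    drugs_cfg = data.get("drugs")
    merged_drugs = {k: dict(v) for k, v in base["drugs"].items()}
    if drugs_cfg is not None:
        if not isinstance(drugs_cfg, Mapping):
            raise ConfigError("drugs: must be a mapping of drug name -> fields")
        for name, vals in drugs_cfg.items():
            if name in merged_drugs:
                bad = set(vals) - _DRUG_FIELDS
                if bad:
                    raise ConfigError(
                        f"drugs.{name}: unknown key(s) {sorted(bad)}; "
                        f"valid: {sorted(_DRUG_FIELDS)}")
                merged_drugs[name].update(vals)
            else:
                if set(vals) != _DRUG_FIELDS:
                    raise ConfigError(
                        f"drugs.{name}: a new drug must define exactly "
                        f"{sorted(_DRUG_FIELDS)}")
                merged_drugs[name] = dict(vals)
        if "strategies" in data:
            merged_drugs = {k: v for k, v in merged_drugs.items() if k in drugs_cfg}
    merged["drugs"] = merged_drugs

    for key in ("strategies", "ranges"):
        if key in data:
            merged[key] = data[key]
    for key in ("transplant", "apbp", "costs", "utilities", "econ"):
        if key in data:
            merged[key] = _merge(base[key], data[key], key)

    d = merged
    drugs = {
        name: DrugProfile(name=name, **vals) for name, vals in d["drugs"].items()
    }
    strategies = [
        Strategy(s["name"], s["first_line"],
                 SwitchRule(s["first_line"], dict(s["switch"])))
        for s in d["strategies"]
    ]
    costs = CostSet(
        consult=d["costs"]["consult"],
        monitoring=d["costs"]["monitoring"],
        adverse_events=[AdverseEvent(**a) for a in d["costs"]["adverse_events"]],
    )
    econ_d = dict(d["econ"])
    conv = Conventions(**econ_d.pop("conventions"))
    econ = EconSettings(conventions=conv, **econ_d)
    spec = ModelSpec(
        drugs=drugs,
        strategies=strategies,
        transplant=TransplantParams(**d["transplant"]),
        apbp=ApBpParams(**d["apbp"]),
        costs=costs,
        utilities=UtilitySet(**d["utilities"]),
        econ=econ,
        ranges=[ParameterRange(**r) for r in d["ranges"]],
    )
    issues = validate(spec)
    if issues:
        raise ConfigError(
            "configuration produced an invalid model:\n  "
            + "\n  ".join(str(i) for i in issues))
    return spec


def load_config(path) -> ModelSpec:
    """Read a YAML config file; omitted fields default to the base case."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return spec_from_dict(data)


def save_config(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
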