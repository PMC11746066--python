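"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: every ranged parameter is
given a distribution fitted by method of moments to its base value and
sensitivity range — beta for probabilities and utilities, gamma for costs —
treating the printed range as a 95% interval (sd = width / (2 × 1.96)).  Each
iteration redraws all parameters independently, re-runs the full cohort model
for every strategy on the shared draw, and records (cost, QALY) pairs.

Decision uncertainty is summarized by the cost-effectiveness acceptability
curve (probability each strategy has the maximum net monetary benefit across a
WTP grid), the pairwise acceptability fraction (points on the cost-effective
side of the WTP line on the incremental CE plane), and a 95% confidence
ellipse for the incremental cloud (chi-square with 2 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .markov import run_strategy
from .parameters import ModelSpec, validate

__all__ = [
    "CeacCurve",
    "ConfidenceEllipse",
    "FittedDistribution",
    "PsaIterationError",
    "PsaSample",
    "Z95",
    "ceac",
    "confidence_ellipse",
    "default_wtp_grid",
    "fit_beta",
    "fit_distributions",
    "fit_gamma",
    "pairwise_acceptability",
    "run_psa",
]

Z95 = 1.959964  # two-sided 95% normal quantile
CHI2_95_2DF = float(stats.chi2.ppf(0.95, df=2))


class PsaIterationError(RuntimeError):
    """A drawn parameter set remained invalid after truncation."""


@dataclass(frozen=True)
class FittedDistribution:
    """A per-parameter sampling distribution.

    ``family`` is ``beta`` (args = (alpha, beta)), ``gamma``
    (args = (shape, scale)), ``uniform`` (args = (low, high)) or ``fixed``
    (args = (value,)).  ``clamped`` flags a minimal-information beta fallback
    whose mean no longer matches the base value.
    """

    parameter: str
    family: str
    args: tuple[float, ...]
    clamped: bool = False

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.args
            return shape * scale
        if self.family == "uniform":
            lo, hi = self.args
            return 0.5 * (lo + hi)
        return self.args[0]

    def sd(self) -> float:
        if self.family == "beta":
            a, b = self.args
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))
        if self.family == "gamma":
            shape, scale = self.args
            return float(np.sqrt(shape) * scale)
        if self.family == "uniform":
            lo, hi = self.args
            return (hi - lo) / np.sqrt(12.0)
        return 0.0

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(*self.args, size=size)
        if self.family == "gamma":
            shape, scale = self.args
            return rng.gamma(shape, scale, size=size)
        if self.family == "uniform":
            lo, hi = self.args
            return rng.uniform(lo, hi, size=size)
        return np.full(size, self.args[0])


def _range_sd(low: float, high: float) -> float:
    return (high - low) / (2.0 * Z95)


def fit_beta(mean: float, low: float, high: float) -> FittedDistribution:
    """Method-of-moments beta fit; the range is read as a 95% interval.

    If the implied variance is infeasible (sd² >= mean(1-mean)) the fit falls
    back to a flagged minimal-information beta with shapes clamped at 0.5.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("beta fit needs mean strictly inside (0, 1)")
    if low >= high:
        raise ValueError("need low < high")
    sd = _range_sd(low, high)
    var = sd * sd
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:
        a = max(mean * nu, 0.5)
        b = max((1.0 - mean) * nu, 0.5)
        return FittedDistribution("", "beta", (a, b), clamped=True)
    return FittedDistribution("", "beta", (mean * nu, (1.0 - mean) * nu))


def fit_gamma(mean: float, low: float, high: float) -> FittedDistribution:
    """Method-of-moments gamma fit; the range is read as a 95% interval."""
    if mean <= 0:
        raise ValueError("gamma fit needs a positive mean")
    if low >= high:
        raise ValueError("need low < high")
    sd = _range_sd(low, high)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return FittedDistribution("", "gamma", (shape, scale))


def fit_distributions(spec: ModelSpec) -> list[FittedDistribution]:
    """One fitted distribution per ranged parameter, in spec order."""
    uniform = spec.econ.conventions.range_interpretation == "uniform"
    fits = []
    for r in spec.ranges:
        base = spec.get(r.parameter)
        if r.family == "fixed" or r.low == r.high:
            fit = FittedDistribution(r.parameter, "fixed", (base,))
        elif uniform:
            fit = FittedDistribution(r.parameter, "uniform", (r.low, r.high))
        elif r.family == "beta":
            f = fit_beta(base, r.low, r.high)
            fit = FittedDistribution(r.parameter, "beta", f.args, f.clamped)
        else:
            f = fit_gamma(base, r.low, r.high)
            fit = FittedDistribution(r.parameter, "gamma", f.args)
        fits.append(fit)
    return fits


@dataclass
class PsaSample:
    """Per-iteration (cost, QALY) pairs for every strategy plus the draw audit."""

    strategies: list[str]
    costs: np.ndarray  # (n_iterations, n_strategies)
    qalys: np.ndarray
    draws: pd.DataFrame  # (n_iterations, n_parameters)
    seed: int
    fits: list[FittedDistribution] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]

    def column(self, strategy: str) -> int:
        return self.strategies.index(strategy)

    def deltas(self, reference: str, comparator: str) -> tuple[np.ndarray, np.ndarray]:
        """(ΔQALY, Δcost) of comparator vs reference per iteration."""
        i, j = self.column(comparator), self.column(reference)
        return self.qalys[:, i] - self.qalys[:, j], self.costs[:, i] - self.costs[:, j]


def run_psa(spec: ModelSpec, n_iterations: int, seed: int) -> PsaSample:
    """Seeded Monte Carlo over all ranged parameters (switch splits stay fixed)."""
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    issues = validate(spec)
    if issues:
        raise ValueError("invalid model spec:\n  " + "\n  ".join(map(str, issues)))
    rng = np.random.default_rng(seed)
    fits = fit_distributions(spec)
    draw_mat = {f.parameter: f.rvs(rng, n_iterations) for f in fits}
    names = spec.strategy_names()
    costs = np.empty((n_iterations, len(names)))
    qalys = np.empty((n_iterations, len(names)))
    for i in range(n_iterations):
        work = spec.clone()
        for f in fits:
            work.set(f.parameter, float(draw_mat[f.parameter][i]))
        bad = validate(work, check_ranges=False)
        if bad:
            # Truncate probability-like draws into [0, 1] and retry once.
            for f in fits:
                v = work.get(f.parameter)
                if f.family in ("beta", "uniform"):
                    work.set(f.parameter, min(max(v, 0.0), 1.0))
            bad = validate(work, check_ranges=False)
            if bad:
                audit = {f.parameter: float(draw_mat[f.parameter][i]) for f in fits}
                raise PsaIterationError(
                    f"iteration {i} invalid after truncation: "
                    f"{[str(b) for b in bad]}; draws={audit}")
        for j, name in enumerate(names):
            res = run_strategy(work, name)
            costs[i, j] = res.total_cost
            qalys[i, j] = res.total_qalys
    draws = pd.DataFrame(draw_mat)
    draws.index.name = "iteration"
    return PsaSample(names, costs, qalys, draws, seed, fits)


def default_wtp_grid(
    wtp: float = 18760.0, high: float = 60000.0, step: float = 500.0
) -> np.ndarray:
    """0..high in ``step`` increments, with the base threshold as an exact point."""
    grid = np.arange(0.0, high + 0.5 * step, step)
    return np.unique(np.concatenate([grid, [wtp]]))


@dataclass
class CeacCurve:
    """Probability each strategy has the maximum NMB, per WTP grid point."""

    frame: pd.DataFrame  # columns: wtp, then one per strategy
    strategies: list[str]

    def at(self, wtp: float, strategy: str) -> float:
        row = self.frame[np.isclose(self.frame["wtp"], wtp)]
        if row.empty:
            raise KeyError(f"WTP {wtp} not on the grid")
        return float(row.iloc[0][strategy])


def ceac(sample: PsaSample, wtp_grid: np.ndarray | list[float]) -> CeacCurve:
    """CEAC via the max-NMB rule; ties go to the earlier strategy in order."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    rows = []
    for w in wtp_grid:
        nmb = w * sample.qalys - sample.costs
        best = np.argmax(nmb, axis=1)  # first index wins ties
        probs = np.bincount(best, minlength=len(sample.strategies)) / sample.n_iterations
        rows.append([w, *probs])
    frame = pd.DataFrame(rows, columns=["wtp", *sample.strategies])
    return CeacCurve(frame, list(sample.strategies))


def pairwise_acceptability(
    sample: PsaSample, reference: str, comparator: str, wtp: float
) -> float:
    """Fraction of iterations on the cost-effective side of the WTP line,
    i.e. with ΔC − wtp×ΔE < 0 for comparator vs reference."""
    de, dc = sample.deltas(reference, comparator)
    return float(np.mean(dc - wtp * de < 0))


@dataclass
class ConfidenceEllipse:
    """95% confidence ellipse of the incremental (ΔE, ΔC) cloud."""

    center: tuple[float, float]
    cov: np.ndarray
    chi2_quantile: float
    degenerate: bool

    @property
    def axes(self) -> tuple[float, float]:
        """Semi-axis lengths (major, minor)."""
        vals = np.sort(np.linalg.eigvalsh(self.cov))[::-1]
        vals = np.clip(vals, 0.0, None)
        return tuple(np.sqrt(vals * self.chi2_quantile))

    @property
    def angle(self) -> float:
        """Orientation of the major axis, radians from the ΔE axis."""
        vals, vecs = np.linalg.eigh(self.cov)
        major = vecs[:, np.argmax(vals)]
        return float(np.arctan2(major[1], major[0]))

    def mahalanobis2(self, de: np.ndarray, dc: np.ndarray) -> np.ndarray:
        inv = np.linalg.pinv(self.cov)
        x = np.stack([de - self.center[0], dc - self.center[1]], axis=-1)
        return np.einsum("...i,ij,...j->...", x, inv, x)

    def contains(self, de, dc) -> np.ndarray:
        return self.mahalanobis2(np.asarray(de), np.asarray(dc)) <= self.chi2_quantile

    def boundary(self, num: int = 200) -> np.ndarray:
        """(num, 2) points on the ellipse boundary (for plotting)."""
        t = np.linspace(0, 2 * np.pi, num)
        vals, vecs = np.linalg.eigh(self.cov)
        vals = np.clip(vals, 0.0, None)
        circle = np.stack([np.cos(t), np.sin(t)])
        pts = vecs @ (np.sqrt(vals[:, None] * self.chi2_quantile) * circle)
        return (pts.T + np.asarray(self.center))


def confidence_ellipse(
    sample: PsaSample, reference: str, comparator: str
) -> ConfidenceEllipse:
    de, dc = sample.deltas(reference, comparator)
    if len(de) < 3:
        raise ValueError("need at least 3 iterations for an ellipse")
    center = (float(np.mean(de)), float(np.mean(dc)))
    cov = np.cov(np.stack([de, dc]))
    degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-12 * max(1.0, cov.max())) < 2)
    return ConfidenceEllipse(center, cov, CHI2_95_2DF, degenerate)
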