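# Methods

## The decision problem

`tkicea` implements a Markov cohort model comparing three first-line tyrosine
kinase inhibitor (TKI) strategies — imatinib, nilotinib and dasatinib — for
newly diagnosed chronic-phase chronic myeloid leukemia (CML-CP) from a South
African public-payer perspective.  The model runs 20 annual cycles, discounts
costs and QALYs at 5% per year, applies a half-cycle correction, and reports
discounted per-patient totals, ICERs against a willingness-to-pay (WTP)
threshold of three times GDP per capita ($6,253.20 × 3 rounded to the nearest
$10 = $18,760/QALY), one-way deterministic sensitivity analysis, and a
probabilistic sensitivity analysis with CEACs.

## State space and transitions

The clinical model has five mutually exclusive states: first-line CP,
second-line CP, merged accelerated/blast phase (AP/BP), allogeneic stem-cell
transplantation (SCT), and death.  Internally the engine expands second-line
CP and AP/BP by drug (`CP2:<d>`, `APBP:<d>`) so per-drug costs and progression
risks are carried exactly, and splits SCT into a first-year tunnel (`SCT_Y1`)
and a long-term state (`SCT_POST`).  Summing the expanded trace back to the
five clinical states is exact (`aggregate_occupancy`), and a test verifies the
expanded trace equals a hand-built five-state trace when all drugs are given
identical parameters.

Within a cycle, competing risks are ordered **death first**: the annual death
probability (1 − overall survival) is applied, and clinical events — treatment
switch with probability (1 − CCyR) split per the switch rule, progression to
AP/BP with the second-line drug's annual progression probability, SCT receipt —
apply to survivors.  This keeps every transition row a proper distribution
without rescaling.  All-cause mortality is carried entirely by the state- and
drug-specific survival probabilities; no separate background life table is
used.

## Accumulation conventions

* **Half-cycle correction**: cycle *k* credits the average of the occupancy at
  its two boundaries, `(occ(k−1) + occ(k)) / 2`.
* **Discounting**: mid-cycle by default, `(1+r)^−(k−1/2)`, consistent with the
  half-cycle correction; end-of-cycle available by flag.  `r = 0` reproduces
  the undiscounted sums exactly under either timing (tested).
* **Recurring costs**: drug acquisition plus consultation and monitoring in CP
  states; first-year / subsequent-year follow-up costs in the SCT states.
* **One-time costs**: the SCT procedure cost is charged to entrants into
  `SCT_Y1` at the entry cycle's discount factor; an adverse-event bundle
  (Σ per-event cost × incidence over the listed grade-3/4 events) is charged
  per treatment-line initiation — the whole cohort at t = 0 (undiscounted) and
  entrants into any second-line state thereafter.  AE incidences are not
  published; the default is 0.05 per event per line initiation, configurable,
  and the bundle is a ~0.1% share of totals.

## Structural conventions (and how the defaults were chosen)

The source publication's spreadsheet conventions are not fully documented, so
the engine exposes explicit flags:

| flag | options (default first) | meaning |
|---|---|---|
| `switch_mode` | `per_cycle`, `first_cycle_only` | (1−CCyR) failure hazard every cycle in first line, or in cycle 1 only |
| `discount_timing` | `mid_cycle`, `end_cycle` | exponent (k−½) vs k |
| `apbp_drug_cost` | `continue`, `none` | AP/BP keeps accruing the progressed-from drug's cost, or follow-up only |
| `os_post_mode` | `first_line`, `constant` | long-term post-SCT survival proxied by the first-line drug's CP survival, or the first-year value reused annually |
| `range_interpretation` | `ci95`, `uniform` | sensitivity ranges read as 95% intervals for PSA spreads, or sampled uniformly |

`analysis/02_convention_grid.py` evaluates the 2×2×2 grid of the first three
flags against the published per-strategy totals; the shipped defaults
(`per_cycle`, `mid_cycle`, `continue`) are the grid's arg-min by total relative
deviation.

**Known limitation — base-case reproduction.** Under the best grid point the
imatinib strategy reproduces the published totals closely ($117,739.57 and
6.028 QALYs vs $120,719.55 and 5.93), but the nilotinib and dasatinib
strategies come out 23–34% below the published totals ($111,841.67 / 5.490 vs
$169,861.41 / 7.78; $131,870.13 / 5.861 vs $180,774.97 / 7.60).  The published
totals imply roughly 9.5 discounted life-years for the second-generation
strategies, which is unattainable with the published annual survival
probabilities (0.933 / 0.931) under any structure we examined (switch timing,
progression from first line, strategy-level survival, survival
re-annualization).  We therefore ship the published inputs verbatim with the
grid-best conventions and report the model's own outputs; downstream results
(ICER quadrants, CEAC ordering) differ from the publication accordingly.  In
this implementation nilotinib is cost-saving and QALY-losing relative to
imatinib, and dasatinib is dominated.

Other conventions worth noting: the imatinib AP/BP sensitivity range is
shipped as 0.042–0.054 (the printed 0.42–0.54 does not bracket the printed
base 0.048 and is inconsistent with the neighbouring rows; the literal reading
is selectable); results are per patient (the 1,000-patient cohort is
presentational); currency is fixed 2024 US$.

## Sensitivity analysis

**One-way DSA.**  Each ranged parameter is set to its low and high bound
(probabilities and utilities capped at [0, 1]), the model re-run, and the
comparison ICER recorded; the tornado table sorts by ICER spread with
lexicographic tie-breaks, which makes output byte-for-byte reproducible.
Parameters without published bounds get ±50% of base, capped at 1 for
probabilities.  Two special sweeps: the imatinib switch split from 100%
nilotinib to 100% dasatinib, and discount rates 0–10%.  Because the published
tornado bar values are not machine-readable, DSA checks are property-based
(ordering, caps, reproducibility), not numeric reproduction.

**PSA.**  Beta distributions for probabilities and utilities, gamma for
costs, fitted by method of moments with sd = range width / (2 × 1.959964);
the fitted mean equals the base value to 1e-9 except for the flagged
minimal-information fallback (shapes clamped at 0.5) used when the implied
variance is infeasible — in the base case only the SCT-receipt probability
with its printed 0–1 range.  Switch splits have no published ranges and stay
fixed.  Parameters are drawn independently (no correlation structure is
published).  1,000 iterations by default, fully reproducible by seed.  The
CEAC uses the max-NMB rule with ties broken by fixed strategy order; the
pairwise acceptability fraction tests ΔC − WTP×ΔE < 0 per iteration — these
are different estimands and can legitimately disagree.  The 95% confidence
ellipse uses the sample mean and covariance of (ΔE, ΔC) with the 2-df
chi-square quantile 5.9915; coverage is verified by simulation.

## Verification oracle

An individual-level microsimulation (`tkicea.microsim`) samples each
individual's path from the same transition rows and accrues value with the
same conventions; the half-cycle correction appears as half a cycle of the
departing plus half of the arriving state per transition, whose expectation
equals the trace-level correction term by term (so the cohort totals are the
exact expectation of the simulated totals).  Tests assert agreement within
3 Monte-Carlo standard errors at n = 100,000 on the base case and 25 random
models, and SE ∝ 1/√n scaling.  With 156 simultaneous 3-SE checks an
occasional ~3σ excursion is statistically expected; seeds are fixed and not
selected.

## Synthetic models

`tkicea.synthetic.random_model` generates structurally valid random
specifications (2–4 drugs, dirichlet switch splits, beta(2,2)-shaped
probabilities inside configured bounds, log-uniform costs, coherent ranges,
horizons 5–30 cycles) for property-based testing.  These exercise the code
paths and invariants of the engine; they do not emulate trial-level survival
data, parameter correlation, patient heterogeneity or age-dependent
mortality, so passing property tests demonstrates internal consistency, not
clinical realism.

## Problem sizes used in the shipped analyses

Base case: 20 cycles, 3 strategies (milliseconds).  DSA: 29 ranged parameters
× 2 bounds × 2 comparisons.  PSA: 1,000 iterations (the published simulation
size).  Oracle checks: n = 100,000 individuals per strategy.  Property suite:
1,000 generator seeds with heavier sub-checks on fixed strides of those seeds.
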