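# tkicea

A Markov cohort cost-effectiveness model of first-line tyrosine kinase
inhibitor (TKI) strategies — imatinib, nilotinib, dasatinib — for chronic-phase
chronic myeloid leukemia in South Africa, for health-economics analysts who
want the published analysis as tested, configurable code rather than a
spreadsheet.

The model tracks a cohort over 20 annual cycles through five clinical states
(first-line CP, second-line CP after treatment failure, accelerated/blast
phase, allogeneic stem-cell transplantation, death), accumulating discounted
costs *C* and quality-adjusted life years *E* per strategy with a half-cycle
correction and 5% annual discounting.  Strategies are compared by the
incremental cost-effectiveness ratio **ICER = ΔC/ΔE** and net monetary benefit
**NMB = λ·E − C** against a willingness-to-pay threshold λ = 3 × GDP per
capita = $18,760/QALY.  Parameter uncertainty is handled by one-way
deterministic sweeps (tornado diagrams) and a probabilistic sensitivity
analysis (method-of-moments beta/gamma distributions, 1,000 Monte-Carlo
iterations, CE-plane clouds with 95% confidence ellipses, cost-effectiveness
acceptability curves).  An independent individual-level microsimulation of the
identical model serves as a verification oracle for the cohort engine.

## Worked example

```python
import tkicea as t

spec = t.builtin_basecase()          # published inputs, 2024 US$
results = t.run_all(spec)
table = t.build_incremental_table(results, reference="imatinib")
print(table.frame.round(2).to_string(index=False))
```

prints

```
 strategy  total_cost  total_qalys  incremental_cost  incremental_qalys     icer dominance
nilotinib   111841.67         5.49          -5897.90              -0.54 10967.61      none
 imatinib   117739.57         6.03               NaN                NaN      NaN      none
dasatinib   131870.13         5.86          14130.56              -0.17      NaN dominated
```

Read: an imatinib-first patient accrues a discounted $117,739.57 and
6.03 QALYs over 20 years.  Under this model's structural conventions the
nilotinib-first strategy saves $5,897.90 but loses 0.54 QALYs per patient
(an ICER of $10,967.61 saved per QALY forgone, the south-west quadrant of the
CE plane), while dasatinib-first costs more and yields less than imatinib and
is dominated.  At the $18,760/QALY threshold imatinib has the highest net
monetary benefit, in line with the published conclusion that imatinib remains
the cost-effective first-line choice.  Note that while the imatinib totals
reproduce the published ones within ~2%, the published nilotinib/dasatinib
totals are substantially higher than any parameterization of this structure
yields from the published inputs — see `docs/methods.md` for the analysis of
this discrepancy.

Every parameter can be overridden from a YAML config (`t.load_config`), and
the same pipeline is scriptable from the shell:

```sh
tkicea run --out out/                 # base-case table + traces
tkicea dsa --out out/                 # tornado tables + sweeps
tkicea psa --out out/ -n 1000 --seed 1 --plot
tkicea validate --config my.yaml
```

The numbered drivers under `analysis/` rerun the full study narrative
(base case, structural-convention grid, one-way DSA, PSA) and write their
tables under `results/`.

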