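# casefind

Decision-analytic cost-effectiveness modelling of **case-finding strategies
for antenatal depression**, from the perspective of the English NHS.

Around 1 in 10 pregnant women experience antenatal depression, but routine
care identifies only about half of cases. *Case finding* — systematically
administering a short screening instrument (the Whooley questions, EPDS, or
PHQ-9) and referring screen-positives for further assessment and treatment —
can raise detection, at the price of instrument time, assessment costs and
false positives. This package implements a decision-tree model that compares
three policies over a 20-week horizon (from screening at ~20 weeks gestation
to birth):

* **no case finding** — women are identified only if they visit a GP;
* **universal case finding** — every woman is screened with a two-stage
  Whooley → PHQ-9 strategy;
* **targeted case finding** — only women with at least one depression risk
  factor (age < 20, history of anxiety, history of depression, recent
  threatening life event; 55.8% of women) are screened, the rest receive
  standard care.

## The model

Women flow through a tree with chance nodes for risk stratum, true
depression status and severity, screening outcome (TP/FN/FP/TN), treatment
allocation (facilitated self-help for mild cases; intensive psychological
therapy, sertraline or both for moderate–severe cases), treatment response
and spontaneous recovery. Each pathway carries a cost (instrument
administration, midwife assessment of screen-positives, treatment, GP
consultations, partial treatment of false positives) and a piecewise-linear
EQ-5D utility trajectory u(t) on the horizon; health benefit is

QALYs = (1/52) ∫₀²⁰ u(t) dt,

with no discounting (horizon < 1 year). Screening performance enters as
sensitivity/specificity against the gold-standard clinical interview;
standard care identifies a depressed woman with sensitivity 50.1%, while a
non-depressed woman can only become a false positive if she visits a GP.
Strategies are compared by incremental cost-effectiveness ratios (ICERs)
with strict and extended dominance, and decision uncertainty is quantified
by a probabilistic sensitivity analysis (beta distributions on probabilities
and utilities, fixed unit costs) summarised as cost-effectiveness
acceptability curves (CEACs).

Because the underlying individual-level cohort data are not publicly
deposited, the package includes a **synthetic cohort generator** that
reproduces the published marginal structure (risk-factor prevalences and
their 55.8% union, stratified depression prevalence 17.1%/1.7%, instrument
operating characteristics, stratum utilities, GP-visit rates), so the whole
pipeline — cohort → derived parameters → tree → PSA — runs end to end and is
testable.

## Worked example

```python
from casefind import STRATEGIES, default_params, evaluate, incremental_analysis

params = default_params()
results = [evaluate(s, params) for s in STRATEGIES()]
for r in results:
    print(f"{r.strategy:<16s} cost £{r.cost:6.2f}   QALYs {r.qalys:.4f}")
print(incremental_analysis(results).round(4))
```

prints

```
No case finding  cost £ 56.46   QALYs 0.3373
Universal        cost £ 47.67   QALYs 0.3377
Targeted         cost £ 57.30   QALYs 0.3377

                    cost   qalys     status        icer comparator
strategy
Universal        47.6699  0.3377  reference         NaN       None
No case finding  56.4645  0.3373  dominated         NaN       None
Targeted         57.2990  0.3377   frontier  281277.558  Universal
```

Universal case finding costs ~£9 less per woman than no case finding *and*
yields more QALYs — it **dominates** standard care, chiefly because
screening replaces GP-led identification and produces far fewer false
positives. Targeted case finding finds the most true positives but also the
most false positives; its extra health relative to universal screening costs
~£280,000 per QALY, far above the £20,000–£30,000/QALY range decision-makers
typically accept. Scaled to the ~600,000 women giving birth in England and
Wales each year, universal screening yields 43,631 true positives versus
30,962 under standard care, with 16,154 fewer false positives.

The `examples/` directory walks each capability: cohort generation,
parameter derivation with Wilson intervals and the 70%-sensitivity /
60%-specificity inclusion filter, deterministic evaluation with a
branch-level audit table, PSA with CEAC plotting, and the pre-specified
one-way sensitivity scenarios.

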