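"""Evaluate the decision tree: per-person costs and QALYs of the three
policies, the incremental analysis, and the 600,000-woman projection.

The base-case result: universal case finding costs less *and* yields more
QALYs than no case finding (it dominates), while the extra health from
targeting only high-risk women costs far more per QALY than decision-makers
are typically willing to pay.
"""

from casefind import (STRATEGIES, Strategy, default_params, evaluate,
                      incremental_analysis, project_population)

params = default_params()
results = [evaluate(s, params) for s in STRATEGIES()]

print("per-person expected values over the 20-week horizon:")
for r in results:
    print(f"  {r.strategy:<16s} cost £{r.cost:6.2f}   QALYs {r.qalys:.4f}")

print("\nincremental analysis (ordered by cost):")
print(incremental_analysis(results).round(4).to_string())

proj = project_population(Strategy("universal"), params, cohort_size=600_000)
b = proj.blocks["whole"]
print(f"\nuniversal case finding across 600,000 births/year:")
print(f"  true positives  {b.tp:>8,}   false negatives {b.fn:>8,}")
print(f"  false positives {b.fp:>8,}   true negatives  {b.tn:>8,}")
print(f"  total cost £{proj.total_costs/1e6:.1f}M, total QALYs {proj.total_qalys:,.0f}")

# audit trail: every branch of the tree with its probability, cost and QALYs
branches = results[1].branches
print(f"\nbranch audit table: {len(branches)} pathways; the five most likely:")
print(branches.nlargest(5, "probability")[["arm", "path", "probability", "cost", "qalys"]]
      .round(4).to_string(index=False))
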