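"""Derive model parameters from a cohort: operating characteristics of the
screening-strategy menu, the inclusion filter, and stratum utilities.

Strategies must reach 70% sensitivity (identifying cases is the point of the
programme) and 60% specificity (limiting wasted treatment of false
positives) to be considered.
"""

from casefind import (GeneratorConfig, STANDARD_STRATEGIES, estimate_performance,
                      estimate_utilities, filter_strategies, generate_cohort,
                      params_from_cohort)

cohort = generate_cohort(GeneratorConfig(n_women=50_000, seed=1))

perfs = [estimate_performance(cohort, s, "high_risk") for s in STANDARD_STRATEGIES]
print("high-risk subgroup operating characteristics:")
for p in perfs:
    s, sp = p.sensitivity, p.specificity
    print(f"  {p.strategy_id:<18s} sens {s.value:5.1%} ({s.ci95[0]:.1%}-{s.ci95[1]:.1%})"
          f"  spec {sp.value:5.1%}")

included, excluded = filter_strategies(perfs)
print("\nincluded:", ", ".join(p.strategy_id for p in included))
for sid, reasons in excluded.items():
    print(f"excluded: {sid} ({'; '.join(reasons)})")

util = estimate_utilities(cohort)
print("\nEQ-5D utilities (non-depressed mean; depressed states by 12%/26% decrement):")
print(util[["u_nondepressed", "u_mild", "u_modsev"]].round(3))

params = params_from_cohort(cohort)
print(f"\nassembled parameter set: high-risk proportion "
      f"{params.p_highrisk.value:.1%}, two-stage whole-sample sens/spec "
      f"{params.sens_cf_whole.value:.1%}/{params.spec_cf_whole.value:.1%}")
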