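"""Parameter derivation: stratification, Wilson intervals, operating
characteristics, inclusion filtering and utility tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casefind import (EstimationError, InstrumentPerformance, StrategyDefinition,
                      DerivedEstimate, estimate_performance, estimate_proportion,
                      estimate_utilities, filter_strategies, params_from_cohort,
                      strategy_positive, stratify)
from casefind.derive import MIN_SENSITIVITY, MIN_SPECIFICITY

CHAIN = StrategyDefinition("Whooley->PHQ-9", [("whooley", None), ("phq9", 10)])


def _records(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "age_under20": [False] * n, "hist_anxiety": [False] * n,
        "hist_depression": [False] * n, "life_event": [False] * n,
        "high_risk": [False] * n, "depressed": [False] * n,
        "severity": ["none"] * n, "epds_score": [0] * n, "phq9_score": [0] * n,
        "whooley_positive": [False] * n, "eq5d_utility": [0.9] * n,
        "gp_visit": [False] * n,
    }
    base.update(cols)
    df = pd.DataFrame(base)
    df["high_risk"] = df[["age_under20", "hist_anxiety", "hist_depression", "life_event"]].any(axis=1)
    return df


def test_stratify_rules():
    rec = _records(life_event=[True, False], hist_anxiety=[False, False])
    strata = stratify(rec)
    assert list(strata["high_risk"].index) == [0]   # one life event suffices
    assert list(strata["low_risk"].index) == [1]
    assert len(strata["whole"]) == 2
    empty = stratify(rec.iloc[0:0])
    assert all(len(v) == 0 for v in empty.values())


def test_estimate_proportion_matches_printed_high_risk_interval():
    rec = _records(life_event=[True] * 218 + [False] * 173)
    est = estimate_proportion(rec, "high_risk")
    assert est.value == pytest.approx(218 / 391)
    # published: 55.8% (95% CI 50.7 to 60.7%)
    assert est.ci95[0] == pytest.approx(0.507, abs=0.005)
    assert est.ci95[1] == pytest.approx(0.607, abs=0.005)


def test_estimate_proportion_boundaries():
    rec = _records(depressed=[False] * 10)
    est = estimate_proportion(rec, "depressed")
    assert est.value == 0.0 and est.ci95[0] == 0.0
    est = estimate_proportion(_records(depressed=[True] * 8), "depressed")
    assert est.value == 1.0 and est.ci95[1] == 1.0
    with pytest.raises(EstimationError):
        estimate_proportion(rec.iloc[0:0], "depressed")


@given(k=st.integers(0, 50), n=st.integers(1, 50))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_wilson_interval_brackets_estimate(k, n):
    k = min(k, n)
    rec = _records(depressed=[True] * k + [False] * (n - k))
    est = estimate_proportion(rec, "depressed")
    assert 0.0 <= est.ci95[0] <= est.value <= est.ci95[1] <= 1.0


def test_perfect_instrument():
    rec = _records(depressed=[True, True, False, False],
                   severity=["mild_moderate"] * 2 + ["none"] * 2,
                   whooley_positive=[True, True, False, False],
                   phq9_score=[15, 15, 0, 0])
    perf = estimate_performance(rec, CHAIN)
    assert perf.sensitivity.value == 1.0
    assert perf.specificity.value == 1.0


def test_two_stage_with_never_positive_second_stage():
    rec = _records(depressed=[True, True, False, False],
                   severity=["mild_moderate"] * 2 + ["none"] * 2,
                   whooley_positive=[True, True, True, False],
                   phq9_score=[0, 0, 0, 0])
    perf = estimate_performance(rec, CHAIN)
    assert perf.sensitivity.value == 0.0
    assert perf.specificity.value == 1.0


def test_performance_requires_both_classes():
    with pytest.raises(EstimationError):
        estimate_performance(_records(depressed=[True, True],
                                      severity=["mild_moderate"] * 2), CHAIN)


def test_chaining_never_beats_marginal_sensitivity(big_cohort):
    chain = estimate_performance(big_cohort, CHAIN, "high_risk")
    whooley = estimate_performance(
        big_cohort, StrategyDefinition("Whooley", [("whooley", None)]), "high_risk")
    phq9 = estimate_performance(
        big_cohort, StrategyDefinition("PHQ-9>=10", [("phq9", 10)]), "high_risk")
    assert chain.sensitivity.value <= whooley.sensitivity.value
    assert chain.sensitivity.value <= phq9.sensitivity.value
    assert chain.specificity.value >= whooley.specificity.value


def _perf(sens, spec, sid="s"):
    est = lambda v: DerivedEstimate(sid, v, 0.01, (max(v - 0.05, 0), min(v + 0.05, 1)), 100)
    return InstrumentPerformance(sid, "high_risk", est(sens), est(spec), 50, 50)


def test_filter_strategies_boundaries():
    included, exclusions = filter_strategies([
        _perf(0.706, 0.895, "two-stage"),
        _perf(0.69, 0.99, "low-sens"),
        _perf(0.70, 0.60, "on-boundary"),
        _perf(0.90, 0.59, "low-spec"),
    ])
    ids = [p.strategy_id for p in included]
    assert ids == ["two-stage", "on-boundary"]  # thresholds are inclusive
    assert "sensitivity" in exclusions["low-sens"][0]
    assert "specificity" in exclusions["low-spec"][0]


def test_utility_decrement_arithmetic():
    rec = _records(life_event=[True] * 4 + [False] * 4,
                   eq5d_utility=[0.869] * 4 + [0.910] * 4)
    util = estimate_utilities(rec, decrement_mild=0.12, decrement_modsev=0.26)
    assert util.loc["high_risk", "u_mild"] == pytest.approx(0.765, abs=5e-4)
    assert util.loc["high_risk", "u_modsev"] == pytest.approx(0.643, abs=5e-4)
    assert util.loc["low_risk", "u_mild"] == pytest.approx(0.801, abs=5e-4)
    assert util.loc["low_risk", "u_modsev"] == pytest.approx(0.673, abs=5e-4)
    no_dec = estimate_utilities(rec, 0.0, 0.0)
    assert no_dec.loc["high_risk", "u_mild"] == no_dec.loc["high_risk", "u_nondepressed"]


def test_utilities_require_nondepressed_records():
    rec = _records(depressed=[True, True], severity=["mild_moderate"] * 2)
    with pytest.raises(EstimationError):
        estimate_utilities(rec)


def test_params_from_cohort_recovers_generating_values(big_cohort):
    """Estimates from a large synthetic cohort converge to the values the
    generator was configured with (within 2 Monte-Carlo SEs)."""
    derived = params_from_cohort(big_cohort)
    n = len(big_cohort)

    def within(est, target, n_eff):
        mc_se = math.sqrt(max(target * (1 - target), 1e-12) / n_eff)
        assert est == pytest.approx(target, abs=2 * mc_se), f"{est} vs {target}"

    n_high = int(big_cohort.high_risk.sum())
    n_dep = int(big_cohort.depressed.sum())
    n_dep_high = int((big_cohort.high_risk & big_cohort.depressed).sum())
    within(derived.p_highrisk.value, 0.558, n)
    within(derived.prev_high.value, 0.171, n_high)
    within(derived.prev_low.value, 0.017154, n - n_high)
    within(derived.p_modsev.value, 0.30, n_dep)
    within(derived.sens_cf_whole.value, 0.706, n_dep)
    within(derived.spec_cf_whole.value, 0.895, n - n_dep)
    within(derived.sens_cf_high.value, 0.742, n_dep_high)
    within(derived.spec_cf_high.value, 0.850, n_high - n_dep_high)
    within(derived.p_gp_visit_high.value, 0.780, n_high)
    within(derived.p_gp_visit_low.value, 0.642, n - n_high)
    # utility means: MC SE from the generator's individual-level noise
    for field, target, n_eff in [("u_nondep_high", 0.869, 46000),
                                 ("u_nondep_low", 0.910, 43000)]:
        se = 0.03 / math.sqrt(n_eff)
        assert getattr(derived, field).value == pytest.approx(target, abs=2 * se)
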