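"""Decision tree: trajectories, QALY integration, branch probabilities and
expected-value evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casefind import (ConfigError, Strategy, STRATEGIES, branch_probabilities,
                      build_trajectory, default_params, evaluate, expected_cost,
                      qaly)


# --- QALY integration --------------------------------------------------------

def test_qaly_constant_utility():
    assert qaly([(0, 0.910), (20, 0.910)]) == pytest.approx(0.910 * 20 / 52)
    assert qaly([(0, 0.0), (20, 0.0)]) == 0.0


def test_qaly_ramp_then_flat():
    # linear 0.643 -> 0.869 over weeks 0-8, then flat to week 20
    traj = [(0, 0.643), (8, 0.869), (20, 0.869)]
    expected = (8 * (0.643 + 0.869) / 2 + 12 * 0.869) / 52
    assert qaly(traj) == pytest.approx(expected)
    assert expected == pytest.approx(0.31685, abs=5e-6)


def test_qaly_rejects_bad_trajectories():
    with pytest.raises(ConfigError):
        qaly([(0, 0.9), (10, 0.9)])            # does not cover horizon
    with pytest.raises(ConfigError):
        qaly([(0, 0.9), (5, 1.2), (20, 0.9)])  # utility out of range
    with pytest.raises(ConfigError):
        qaly([(0, 0.9), (10, 0.9), (5, 0.9), (20, 0.9)])


@given(u0=st.floats(0, 1), u1=st.floats(0, 1), t=st.floats(0.5, 19.5))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_qaly_bounds(u0, u1, t):
    q = qaly([(0, u0), (t, u1), (20, u1)])
    assert 0.0 <= q <= 20 / 52 + 1e-12


# --- trajectories -------------------------------------------------------------

def test_tn_trajectory_flat_nondepressed(params):
    traj = build_trajectory("tn", params, 0.910)
    assert traj == [(0.0, 0.910), (20.0, 0.910)]


def test_fn_unidentified_mild_declines_to_modsev(params):
    traj = build_trajectory("fn_unidentified", params, 0.910, "mild_moderate")
    (w0, u0), (w1, u1) = traj
    assert (w0, w1) == (0.0, 20.0)
    assert u0 == pytest.approx(0.801, abs=5e-4)   # mild utility on a 0.910 base
    assert u1 == pytest.approx(0.673, abs=5e-4)   # moderate/severe utility


def test_tp_and_spontaneous_shapes_differ_only_in_ramp(params):
    tp = build_trajectory("tp_responder", params, 0.910, "mild_moderate")
    fn = build_trajectory("fn_spontaneous", params, 0.910, "mild_moderate")
    assert tp[0] == fn[0] and tp[-1] == fn[-1]
    assert tp[1][0] == params.treatment_weeks
    assert fn[1][0] == params.spont_recovery_weeks


def test_fn_identified_ramp_starts_midhorizon(params):
    traj = build_trajectory("fn_identified_responder", params, 0.910, "moderate_severe")
    weeks = [w for w, _ in traj]
    assert weeks == [0.0, 10.0, 18.0, 20.0]


def test_depressed_paths_require_severity(params):
    with pytest.raises(ConfigError):
        build_trajectory("tp_responder", params, 0.91)
    with pytest.raises(ConfigError):
        build_trajectory("no_such_path", params, 0.91)


# --- branch probabilities -----------------------------------------------------

def test_case_finding_branch_probabilities():
    probs = branch_probabilities(0.103, 0.706, 0.895, "case_finding")
    assert probs["tp"] == pytest.approx(0.072718)
    assert probs["fp"] == pytest.approx(0.094185)
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)


def test_standard_care_visit_multiplies_fp_only():
    probs = branch_probabilities(0.103, 0.501, 0.813, "standard_care", p_visit=0.722)
    assert probs["tp"] == pytest.approx(0.103 * 0.501)
    assert probs["fp"] == pytest.approx(0.897 * 0.722 * 0.187, abs=1e-6)
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)


def test_zero_prevalence_has_no_depressed_branches():
    probs = branch_probabilities(0.0, 0.7, 0.9, "case_finding")
    assert probs["tp"] == probs["fn"] == 0.0


# --- evaluation ----------------------------------------------------------------

def test_branch_probabilities_sum_to_one_within_each_arm(params):
    for strat in STRATEGIES():
        res = evaluate(strat, params)
        for _, arm in res.branches.groupby("arm"):
            assert arm.probability.sum() == pytest.approx(1.0, abs=1e-9)


def test_qalys_within_horizon_bounds(params):
    for strat in STRATEGIES():
        res = evaluate(strat, params)
        assert 0.0 <= res.qalys <= 20 / 52


def test_equal_constant_utilities_make_strategies_equivalent_in_qalys(params):
    p = params.copy()
    for f in ("u_nondep_whole", "u_nondep_high", "u_nondep_low"):
        getattr(p, f).value = 0.8
    p.decrement_mild = 0.0
    p.decrement_modsev = 0.0
    qalys = [evaluate(s, p, branch_table=False).qalys for s in STRATEGIES()]
    assert max(qalys) - min(qalys) < 1e-12
    assert qalys[0] == pytest.approx(0.8 * 20 / 52)


def test_universal_dominates_no_case_finding(params):
    none, universal, targeted = [evaluate(s, params, branch_table=False) for s in STRATEGIES()]
    assert universal.cost < none.cost
    assert universal.qalys > none.qalys
    assert none.cost <= targeted.cost
    assert universal.qalys <= targeted.qalys


def test_more_effective_treatment_never_reduces_qalys(params):
    p = params.copy()
    base = evaluate(Strategy("universal"), p, branch_table=False).qalys
    p.p_recover_fsh.value = min(1.0, p.p_recover_fsh.value + 0.2)
    p.p_recover_pharma.value = min(1.0, p.p_recover_pharma.value + 0.2)
    better = evaluate(Strategy("universal"), p, branch_table=False).qalys
    assert better >= base


def test_higher_unit_cost_never_reduces_expected_cost(params):
    p = params.copy()
    base = evaluate(Strategy("targeted"), p, branch_table=False).cost
    p.assessment_cost += 10
    p.sertraline_cost += 5
    up = evaluate(Strategy("targeted"), p, branch_table=False).cost
    assert up > base


def test_universal_cost_with_only_nondepressed_pathways(params):
    """With zero prevalence, the universal cost is screening plus the
    false-positive pathway: (1-spec) x (assessment + partial treatment)."""
    p = params.copy()
    p.prev_high.value = 0.0
    p.prev_low.value = 0.0
    res = evaluate(Strategy("universal"), p, branch_table=False)
    screen = p.whooley_cost() + p.phq9_cost()
    expected = screen + (1 - p.spec_cf_whole.value) * (p.assessment_cost + p.fp_cost())
    assert res.cost == pytest.approx(expected)


def test_no_case_finding_costs_nothing_without_gp_visits(params):
    p = params.copy()
    for f in ("prev_whole", "prev_high", "prev_low", "p_gp_visit_whole",
              "p_gp_visit_high", "p_gp_visit_low"):
        getattr(p, f).value = 0.0
    res = evaluate(Strategy("no_case_finding"), p, branch_table=False)
    assert res.cost == pytest.approx(0.0)


def test_whole_population_evaluation_close_to_hand_audit(params):
    """Per-person cost of the no-case-finding arm on whole-sample parameters,
    against an independent branch-by-branch hand calculation."""
    cost = expected_cost(Strategy("no_case_finding"), params, "whole")
    prev, sens, spec, visit = 0.103, 0.501, 0.813, 0.722
    tp, fn = prev * sens, prev * (1 - sens)
    fp = (1 - prev) * visit * (1 - spec)
    mix = (0.128 * 909.69 + 0.523 * 300.26 + 0.349 * 935.34)
    treat = 0.7 * 273.44 + 0.3 * mix
    hand = (visit * 39.23 + tp * treat + fp * 54.69
            + fn * 0.65 * (39.23 + 0.10 * treat))
    assert cost == pytest.approx(hand, rel=1e-9)


def test_strategy_kind_validated():
    with pytest.raises(ConfigError):
        Strategy("screen_everyone_twice")
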