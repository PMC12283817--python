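"""PSA, CEAC, incremental analysis and population projection."""

import numpy as np
import pytest

from casefind import (ConfigError, Strategy, STRATEGIES, beta_from_moments,
                      ceac_table, draw_params, incremental_analysis,
                      project_population, run_psa, evaluate)


# --- beta method of moments ---------------------------------------------------

def test_beta_uniform_case():
    a, b = beta_from_moments(0.5, np.sqrt(1 / 12))
    assert a == pytest.approx(1.0) and b == pytest.approx(1.0)


def test_beta_from_printed_se():
    a, b = beta_from_moments(0.65, 0.065)
    assert a == pytest.approx(34.35, abs=0.01)
    assert b == pytest.approx(18.50, abs=0.01)


def test_beta_draw_mean_matches_moments():
    rng = np.random.default_rng(0)
    a, b = beta_from_moments(0.3, 0.05)
    draws = rng.beta(a, b, size=200_000)
    assert draws.mean() == pytest.approx(0.3, abs=3 * 0.05 / np.sqrt(200_000))
    assert draws.std() == pytest.approx(0.05, abs=0.001)


def test_beta_rejects_impossible_moments():
    with pytest.raises(ConfigError):
        beta_from_moments(0.5, 0.6)
    with pytest.raises(ConfigError):
        beta_from_moments(0.0, 0.1)


# --- PSA -----------------------------------------------------------------------

def test_psa_seed_determinism(params):
    a = run_psa(params, n_iter=20, seed=5)
    b = run_psa(params, n_iter=20, seed=5)
    assert np.array_equal(a.costs, b.costs) and np.array_equal(a.qalys, b.qalys)


def test_draw_params_keeps_structure_valid(params):
    rng = np.random.default_rng(1)
    for _ in range(50):
        d = draw_params(params, rng)
        d.validate()
        mix = d.mix_ipt.value + d.mix_pharma.value + d.mix_both.value
        assert mix == pytest.approx(1.0, abs=1e-12)
        ph = d.p_highrisk.value
        assert d.prev_whole.value == pytest.approx(
            ph * d.prev_high.value + (1 - ph) * d.prev_low.value)


def test_degenerate_psa_reproduces_deterministic(params):
    """With every SE zeroed the single PSA iteration equals the deterministic run."""
    p = params.copy()
    from casefind.psa import PSA_FIELDS
    for name in PSA_FIELDS:
        u = getattr(p, name)
        u.se, u.ci95 = None, None
    res = run_psa(p, n_iter=1, seed=0)
    for j, strat in enumerate(STRATEGIES()):
        det = evaluate(strat, p, branch_table=False)
        assert res.costs[0, j] == pytest.approx(det.cost)
        assert res.qalys[0, j] == pytest.approx(det.qalys)


def test_ceac_probability_vector_and_zero_threshold():
    costs = np.array([[10.0, 20.0], [30.0, 5.0], [10.0, 10.0]])
    qalys = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
    ceac = ceac_table(costs, qalys, ["A", "B"], [0.0, 100.0])
    assert np.allclose(ceac.sum(axis=1), 1.0)
    # lambda = 0: the cheaper strategy wins; the exact tie is split equally
    assert ceac.loc[0.0, "A"] == pytest.approx((1 + 0 + 0.5) / 3)
    assert ceac.loc[100.0, "B"] == pytest.approx(1.0)  # B gains 1 QALY for <=100


def test_psa_summary_brackets_means(params):
    res = run_psa(params, n_iter=100, seed=2)
    s = res.summary()
    assert ((s.cost_lo <= s.cost_mean) & (s.cost_mean <= s.cost_hi)).all()
    assert ((s.qalys_lo <= s.qalys_mean) & (s.qalys_mean <= s.qalys_hi)).all()


# --- incremental analysis -------------------------------------------------------

def test_strict_dominance():
    df = incremental_analysis([("A", 100.0, 1.0), ("B", 50.0, 2.0)])
    assert df.loc["A", "status"] == "dominated"
    assert df.loc["B", "status"] == "reference"


def test_icer_arithmetic():
    df = incremental_analysis([("A", 50.0, 1.00), ("B", 150.0, 1.01)])
    assert df.loc["B", "icer"] == pytest.approx(10_000.0)
    assert df.loc["B", "comparator"] == "A"


def test_extended_dominance():
    # B's ICER vs A (200/QALY) exceeds C's ICER vs B (50/QALY): B is
    # extendedly dominated and C is compared directly with A
    df = incremental_analysis([("A", 0.0, 1.0), ("B", 200.0, 2.0), ("C", 250.0, 3.0)])
    assert df.loc["B", "status"] == "extendedly_dominated"
    assert df.loc["C", "icer"] == pytest.approx(125.0)


def test_dominance_invariant_to_input_order(params):
    res = [evaluate(s, params, branch_table=False) for s in STRATEGIES()]
    a = incremental_analysis(res)
    b = incremental_analysis(res[::-1])
    assert a.sort_index().status.equals(b.sort_index().status)


def test_frontier_icers_strictly_increase():
    df = incremental_analysis(
        [("A", 0.0, 1.0), ("B", 100.0, 2.0), ("C", 300.0, 3.0), ("D", 900.0, 4.0)])
    icers = df[df.status == "frontier"].icer.to_numpy()
    assert np.all(np.diff(icers) > 0)


# --- population projection -------------------------------------------------------

def test_projection_zero_cohort(params):
    proj = project_population(Strategy("universal"), params, cohort_size=0)
    b = proj.blocks["whole"]
    assert (b.n, b.tp, b.tn, b.fn, b.fp) == (0, 0, 0, 0, 0)
    assert proj.total_costs == 0.0


def test_projection_blocks_sum_to_cohort(params):
    for strat in STRATEGIES():
        proj = project_population(strat, params)
        for b in proj.blocks.values():
            assert b.tp + b.tn + b.fn + b.fp == b.n
        assert sum(b.n for b in proj.blocks.values()) == 600_000


def test_projection_universal_counts(params):
    b = project_population(Strategy("universal"), params).blocks["whole"]
    assert b.n_depressed == 61_800
    assert b.tp == 43_631
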