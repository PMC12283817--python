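"""Independent microsimulation oracle for the decision tree.

Walks individual women through the identification and treatment pathways by
Monte-Carlo sampling, accruing per-woman costs and weekly utilities on an
integer-week grid (exact for the model's piecewise-linear trajectories,
whose knots fall on integer weeks).  Written against the pathway rules
directly — not via the package's branch enumeration — so agreement with the
analytic evaluation is a genuine cross-check.
"""

import numpy as np

from casefind import ModelParams, Strategy


def microsimulate(strategy: Strategy, params: ModelParams, n: int, seed: int):
    """Simulate ``n`` women; returns (mean_cost, se_cost, mean_qalys, se_qalys)."""
    rng = np.random.default_rng(seed)
    p = params

    high = rng.random(n) < p.p_highrisk.value
    prev = np.where(high, p.prev_high.value, p.prev_low.value)
    u_n = np.where(high, p.u_nondep_high.value, p.u_nondep_low.value)
    p_visit = np.where(high, p.p_gp_visit_high.value, p.p_gp_visit_low.value)

    if strategy.kind == "universal":
        screened = np.ones(n, dtype=bool)
        sens = np.full(n, p.sens_cf_whole.value)
        spec = np.full(n, p.spec_cf_whole.value)
    elif strategy.kind == "targeted":
        screened = high
        sens = np.where(high, p.sens_cf_high.value, p.sens_std.value)
        spec = np.where(high, p.spec_cf_high.value, p.spec_std.value)
    else:
        screened = np.zeros(n, dtype=bool)
        sens = np.full(n, p.sens_std.value)
        spec = np.full(n, p.spec_std.value)

    dep = rng.random(n) < prev
    modsev = dep & (rng.random(n) < p.p_modsev.value)
    mild = dep & ~modsev
    u_dep = np.where(modsev, u_n * (1 - p.decrement_modsev), u_n * (1 - p.decrement_mild))

    tp = dep & (rng.random(n) < sens)
    fn = dep & ~tp
    visit = rng.random(n) < p_visit
    miss = rng.random(n) < (1 - spec)
    fp = ~dep & np.where(screened, miss, visit & miss)

    # treatment allocation for depressed women (applies if ever identified)
    opts = p.treatment_modsev()
    weights = np.array([w for _, w, _, _ in opts])
    choice = rng.choice(len(opts), size=n, p=weights)
    treat_cost = np.where(mild, p.fsh_cost(), np.array([c for _, _, c, _ in opts])[choice])
    p_rec = np.where(mild, p.p_recover_fsh.value, np.array([r for _, _, _, r in opts])[choice])
    responder = rng.random(n) < p_rec

    spont = fn & (rng.random(n) < (1 - p.p_no_spont.value))
    persistent = fn & ~spont
    identified = persistent & (rng.random(n) < p.p_fn_identified)

    screen_cost = p.whooley_cost() + p.first_stage_positive_rate * p.phq9_cost()
    gp_ident = p.identification_consult_cost()
    cost = np.zeros(n)
    cost[screened] += screen_cost
    cost[~screened & visit] += gp_ident
    cost[screened & (tp | fp)] += p.assessment_cost
    cost[fp] += p.fp_cost()
    cost[tp] += treat_cost[tp]
    cost[persistent] += gp_ident       # mid-horizon GP visit of all persistent FNs
    cost[identified] += treat_cost[identified]

    # weekly utility grid (exact: all trajectory knots sit on integer weeks)
    weeks = np.arange(int(p.horizon_weeks) + 1, dtype=float)
    U = np.tile(u_n[:, None], (1, weeks.size)).astype(float)
    U[fp] = (u_n[fp] * (1 - p.fp_utility_decrement))[:, None]

    def ramp(start_week, length):
        """fraction of the depressed->non-depressed improvement completed."""
        return np.clip((weeks - start_week) / length, 0.0, 1.0)

    def set_traj(mask, frac_row):
        U[mask] = u_dep[mask, None] + (u_n[mask] - u_dep[mask])[:, None] * frac_row[None, :]

    set_traj(tp & responder, ramp(0.0, p.treatment_weeks))
    set_traj(tp & ~responder, np.zeros_like(weeks))
    set_traj(spont, ramp(0.0, p.spont_recovery_weeks))
    set_traj(identified & responder, ramp(p.fn_identify_week, p.treatment_weeks))
    set_traj(identified & ~responder, np.zeros_like(weeks))
    unid = persistent & ~identified
    decline = unid & mild
    U[decline] = (u_dep[decline, None]
                  + (u_n[decline] * (1 - p.decrement_modsev) - u_dep[decline])[:, None]
                  * (weeks / p.horizon_weeks)[None, :])
    U[unid & modsev] = u_dep[unid & modsev, None] * np.ones_like(weeks)[None, :]

    qalys = np.trapezoid(U, weeks, axis=1) / p.weeks_per_year
    return (cost.mean(), cost.std(ddof=1) / np.sqrt(n),
            qalys.mean(), qalys.std(ddof=1) / np.sqrt(n))
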