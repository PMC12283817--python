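"""The three-stage decision tree and its deterministic evaluation.

Strategies
----------
* ``no_case_finding`` — women can only be identified as depressed if they
  visit a GP (standard care).
* ``universal`` — every woman is screened with the instrument chain.
* ``targeted`` — only women with at least one depression risk factor are
  screened; low-risk women receive standard care.

All three strategies are evaluated on the same two-stratum population
(high/low risk, mixed with the high-risk proportion), each stratum carrying
its own depression prevalence, GP-visit rate and utility level, so costs
and QALYs are directly comparable across strategies.  Whole-sample
strategies apply the whole-sample operating characteristics within both
strata; the targeted strategy applies the high-risk-subgroup operating
characteristics in the high-risk stratum and standard care in the low-risk
stratum, whose prevalence is the share of depression left after removing
the high-risk stratum's (preserving overall prevalence).

Pathways
--------
Screened women: true/false positives receive a midwife further assessment;
true positives start treatment at week 0 (mild -> facilitated self-help;
moderate/severe -> the observed mix of intensive psychological therapy,
sertraline, or both), and responders improve linearly to the non-depressed
utility over the 8-week course.  False negatives either spontaneously
recover (linear improvement over 7 weeks), or continue depressed and visit
a GP mid-horizon, where 10% are identified and treated (improvement over
weeks 10-18 for responders); unidentified mild cases decline linearly to
the moderate/severe utility by the end of the horizon.  Standard-care arms
replace screening with GP identification: an assessment consultation for
every woman who visits a GP, treatment for identified true positives, and
the partial-treatment cost for false positives.

QALYs are the trapezoidal integral of each piecewise-linear utility
trajectory over the 20-week horizon, divided by 52 (no discounting: the
horizon is under a year).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .params import ModelParams

__all__ = [
    "Strategy",
    "STRATEGIES",
    "CEResult",
    "qaly",
    "build_trajectory",
    "branch_probabilities",
    "expected_cost",
    "evaluate",
]


@dataclass
class Strategy:
    """A case-finding policy to evaluate."""

    kind: str  # "no_case_finding" | "universal" | "targeted"
    label: str = ""
    #: fraction of screened women who are also administered (and costed for)
    #: the second-stage instrument; None -> take from params
    first_stage_positive_rate: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("no_case_finding", "universal", "targeted"):
            raise ConfigError(f"unknown strategy kind {self.kind!r}")
        if not self.label:
            self.label = {"no_case_finding": "No case finding",
                          "universal": "Universal",
                          "targeted": "Targeted"}[self.kind]


def STRATEGIES() -> List[Strategy]:
    """The three policies compared in the base case."""
    return [Strategy("no_case_finding"), Strategy("universal"), Strategy("targeted")]


# ---------------------------------------------------------------------------
# QALY machinery

def qaly(trajectory: Sequence[Tuple[float, float]], horizon_weeks: float = 20.0,
         weeks_per_year: float = 52.0) -> float:
    """QALYs accrued by a piecewise-linear utility trajectory.

    ``trajectory`` is a list of (week, utility) knots with non-decreasing
    weeks covering [0, horizon]; the trapezoidal integral of utility over
    weeks is exact for piecewise-linear trajectories.
    """
    weeks = np.array([w for w, _ in trajectory], dtype=float)
    utils = np.array([u for _, u in trajectory], dtype=float)
    if np.any(np.diff(weeks) < 0):
        raise ConfigError("trajectory weeks must be non-decreasing")
    if weeks[0] > 0 or weeks[-1] < horizon_weeks - 1e-9:
        raise ConfigError("trajectory must cover the full horizon")
    if np.any((utils < 0) | (utils > 1)):
        raise ConfigError("trajectory utilities must be in [0, 1]")
    return float(np.trapezoid(utils, weeks)) / weeks_per_year


def build_trajectory(path: str, params: ModelParams, u_nondep: float,
                     severity: str = "none") -> List[Tuple[float, float]]:
    """Utility trajectory knots for a named pathway.

    ``path`` is one of: ``tn``, ``fp``, ``tp_responder``, ``tp_nonresponder``,
    ``fn_spontaneous``, ``fn_identified_responder``, ``fn_identified_nonresponder``,
    ``fn_unidentified``.  ``u_nondep`` is the stratum's non-depressed utility;
    depressive-state utilities apply the configured proportional decrements.
    """
    H = params.horizon_weeks
    u_mild = u_nondep * (1 - params.decrement_mild)
    u_ms = u_nondep * (1 - params.decrement_modsev)
    u_dep = {"mild_moderate": u_mild, "moderate_severe": u_ms}.get(severity)
    if path in ("tp_responder", "tp_nonresponder", "fn_spontaneous", "fn_identified_responder",
                "fn_identified_nonresponder", "fn_unidentified") and u_dep is None:
        raise ConfigError(f"path {path!r} requires a depressed severity, got {severity!r}")

    if path == "tn":
        return [(0.0, u_nondep), (H, u_nondep)]
    if path == "fp":
        u = u_nondep * (1 - params.fp_utility_decrement)
        return [(0.0, u), (H, u)]
    if path == "tp_responder":
        t = params.treatment_weeks
        return [(0.0, u_dep), (t, u_nondep), (H, u_nondep)]
    if path == "tp_nonresponder":
        return [(0.0, u_dep), (H, u_dep)]
    if path == "fn_spontaneous":
        t = params.spont_recovery_weeks
        return [(0.0, u_dep), (t, u_nondep), (H, u_nondep)]
    if path == "fn_identified_responder":
        t0 = params.fn_identify_week
        t1 = t0 + params.treatment_weeks
        return [(0.0, u_dep), (t0, u_dep), (t1, u_nondep), (H, u_nondep)]
    if path == "fn_identified_nonresponder":
        return [(0.0, u_dep), (H, u_dep)]
    if path == "fn_unidentified":
        if severity == "mild_moderate":
            # untreated mild depression worsens to moderate/severe over the horizon
            return [(0.0, u_mild), (H, u_ms)]
        return [(0.0, u_ms), (H, u_ms)]
    raise ConfigError(f"unknown trajectory path {path!r}")


# ---------------------------------------------------------------------------
# chance-node probabilities

def branch_probabilities(prev: float, sens: float, spec: float,
                         mode: str = "case_finding", p_visit: float = 0.0) -> dict:
    """TP/FN/FP/TN probabilities for one stratum.

    With case finding every woman is screened.  Under standard care a
    depressed woman is identified with the standard-care sensitivity, while a
    non-depressed woman can only be misidentified if she visits a GP, so the
    visit probability multiplies the false-positive pathway only.
    """
    if mode == "case_finding":
        probs = {
            "tp": prev * sens,
            "fn": prev * (1 - sens),
            "fp": (1 - prev) * (1 - spec),
        }
    elif mode == "standard_care":
        probs = {
            "tp": prev * sens,
            "fn": prev * (1 - sens),
            "fp": (1 - prev) * p_visit * (1 - spec),
        }
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    probs["tn"] = 1.0 - sum(probs.values())
    for k, v in probs.items():
        if not -1e-12 <= v <= 1.0 + 1e-12:
            raise ConfigError(f"branch probability {k} = {v} outside [0, 1]")
    return probs


# ---------------------------------------------------------------------------
# branch enumeration

@dataclass
class _Arm:
    """One stratum under one identification mode."""

    stratum: str
    weight: float
    prev: float
    u_nondep: float
    mode: str               # "case_finding" | "standard_care"
    sens: float
    spec: float
    p_visit: float = 0.0    # standard care only
    screening_cost: float = 0.0
    common_cost: float = 0.0  # incurred by every woman in the arm


@dataclass
class Branch:
    """One fully expanded pathway through the tree (per arm)."""

    arm: str
    label: str
    probability: float
    cost: float
    trajectory: list
    qalys: float = 0.0


def _treatments(params: ModelParams, severity: str):
    """(label, weight, cost, p_recover) options for a severity level."""
    if severity == "mild_moderate":
        return [("fsh", 1.0, params.fsh_cost(), params.p_recover_fsh.value)]
    return params.treatment_modsev()


def _arm_branches(arm: _Arm, params: ModelParams) -> List[Branch]:
    probs = branch_probabilities(arm.prev, arm.sens, arm.spec, arm.mode, arm.p_visit)
    gp_ident = params.identification_consult_cost()
    assess = params.assessment_cost if arm.mode == "case_finding" else 0.0
    u_n = arm.u_nondep
    branches = [
        Branch(arm.stratum, "tn", probs["tn"], 0.0, build_trajectory("tn", params, u_n)),
        Branch(arm.stratum, "fp", probs["fp"], assess + params.fp_cost(),
               build_trajectory("fp", params, u_n)),
    ]
    p_ms = params.p_modsev.value
    for severity, p_sev in (("mild_moderate", 1 - p_ms), ("moderate_severe", p_ms)):
        options = _treatments(params, severity)
        # true positives: assessed and treated at week 0
        for label, w, cost, p_rec in options:
            base_p = probs["tp"] * p_sev * w
            branches.append(Branch(
                arm.stratum, f"tp/{severity}/{label}/responder", base_p * p_rec,
                assess + cost, build_trajectory("tp_responder", params, u_n, severity)))
            branches.append(Branch(
                arm.stratum, f"tp/{severity}/{label}/nonresponder", base_p * (1 - p_rec),
                assess + cost, build_trajectory("tp_nonresponder", params, u_n, severity)))
        # false negatives
        p_fn_sev = probs["fn"] * p_sev
        p_ns = params.p_no_spont.value
        branches.append(Branch(
            arm.stratum, f"fn/{severity}/spontaneous", p_fn_sev * (1 - p_ns), 0.0,
            build_trajectory("fn_spontaneous", params, u_n, severity)))
        # all non-recovered false negatives visit a GP mid-horizon (one
        # consultation); a fraction are identified and treated
        p_id = params.p_fn_identified
        for label, w, cost, p_rec in options:
            base_p = p_fn_sev * p_ns * p_id * w
            branches.append(Branch(
                arm.stratum, f"fn/{severity}/identified/{label}/responder", base_p * p_rec,
                gp_ident + cost,
                build_trajectory("fn_identified_responder", params, u_n, severity)))
            branches.append(Branch(
                arm.stratum, f"fn/{severity}/identified/{label}/nonresponder", base_p * (1 - p_rec),
                gp_ident + cost,
                build_trajectory("fn_identified_nonresponder", params, u_n, severity)))
        branches.append(Branch(
            arm.stratum, f"fn/{severity}/unidentified", p_fn_sev * p_ns * (1 - p_id),
            gp_ident, build_trajectory("fn_unidentified", params, u_n, severity)))
    for b in branches:
        b.qalys = qaly(b.trajectory, params.horizon_weeks, params.weeks_per_year)
    return branches


def _strategy_arms(strategy: Strategy, params: ModelParams,
                   population: str = "stratified") -> List[_Arm]:
    fspr = (strategy.first_stage_positive_rate
            if strategy.first_stage_positive_rate is not None
            else params.first_stage_positive_rate)
    screen = params.whooley_cost() + fspr * params.phq9_cost()
    p_high = params.p_highrisk.value

    def cf_arm(stratum, weight, prev, u, sens, spec):
        return _Arm(stratum, weight, prev, u, "case_finding", sens, spec,
                    screening_cost=screen, common_cost=screen)

    def std_arm(stratum, weight, prev, u, p_visit):
        return _Arm(stratum, weight, prev, u, "standard_care",
                    params.sens_std.value, params.spec_std.value, p_visit=p_visit,
                    common_cost=p_visit * params.identification_consult_cost())

    if population == "whole":
        if strategy.kind == "universal":
            return [cf_arm("whole", 1.0, params.prev_whole.value, params.u_nondep_whole.value,
                           params.sens_cf_whole.value, params.spec_cf_whole.value)]
        if strategy.kind == "no_case_finding":
            return [std_arm("whole", 1.0, params.prev_whole.value, params.u_nondep_whole.value,
                            params.p_gp_visit_whole.value)]
        # targeted is inherently stratified
    elif population != "stratified":
        raise ConfigError(f"unknown population {population!r}")

    high = dict(stratum="high_risk", weight=p_high, prev=params.prev_high.value,
                u=params.u_nondep_high.value)
    low = dict(stratum="low_risk", weight=1 - p_high, prev=params.prev_low.value,
               u=params.u_nondep_low.value)
    if strategy.kind == "no_case_finding":
        return [std_arm(high["stratum"], high["weight"], high["prev"], high["u"],
                        params.p_gp_visit_high.value),
                std_arm(low["stratum"], low["weight"], low["prev"], low["u"],
                        params.p_gp_visit_low.value)]
    if strategy.kind == "universal":
        s, sp = params.sens_cf_whole.value, params.spec_cf_whole.value
        return [cf_arm(high["stratum"], high["weight"], high["prev"], high["u"], s, sp),
                cf_arm(low["stratum"], low["weight"], low["prev"], low["u"], s, sp)]
    return [cf_arm(high["stratum"], high["weight"], high["prev"], high["u"],
                   params.sens_cf_high.value, params.spec_cf_high.value),
            std_arm(low["stratum"], low["weight"], low["prev"], low["u"],
                    params.p_gp_visit_low.value)]


@dataclass
class CEResult:
    """Per-person expected cost (GBP) and QALYs of one strategy."""

    strategy: str
    cost: float
    qalys: float
    branches: Optional[pd.DataFrame] = field(default=None, repr=False)


def evaluate(strategy: Strategy, params: ModelParams, population: str = "stratified",
             branch_table: bool = True) -> CEResult:
    """Expected cost and QALYs per person for one strategy.

    With ``population="stratified"`` (default) every strategy is evaluated on
    the high/low-risk population mixture; ``"whole"`` collapses the
    no-case-finding and universal strategies onto whole-sample parameters.
    Set ``branch_table=False`` to skip assembling the audit table (used in
    tight PSA loops).
    """
    arms = _strategy_arms(strategy, params, population)
    total_cost = 0.0
    total_qalys = 0.0
    rows = []
    for arm in arms:
        branches = _arm_branches(arm, params)
        p_sum = sum(b.probability for b in branches)
        if abs(p_sum - 1.0) > 1e-9:
            raise ConfigError(f"branch probabilities in arm {arm.stratum} sum to {p_sum}")
        arm_cost = arm.common_cost + sum(b.probability * b.cost for b in branches)
        arm_qalys = sum(b.probability * b.qalys for b in branches)
        total_cost += arm.weight * arm_cost
        total_qalys += arm.weight * arm_qalys
        if branch_table:
            for b in branches:
                rows.append({
                    "arm": b.arm, "arm_weight": arm.weight, "path": b.label,
                    "probability": b.probability, "cost": b.cost, "qalys": b.qalys,
                    "common_cost": arm.common_cost,
                })
    table = pd.DataFrame(rows) if branch_table else None
    return CEResult(strategy.label, total_cost, total_qalys, table)


def expected_cost(strategy: Strategy, params: ModelParams, stratum: str = "whole") -> float:
    """Per-person expected cost of one arm of a strategy.

    ``stratum`` selects the arm (``whole`` uses whole-sample parameters for
    whole-population strategies; ``high_risk``/``low_risk`` select the
    corresponding arm of the stratified evaluation).
    """
    population = "whole" if stratum == "whole" else "stratified"
    arms = _strategy_arms(strategy, params, population)
    for arm in arms:
        if arm.stratum == stratum:
            branches = _arm_branches(arm, params)
            return arm.common_cost + sum(b.probability * b.cost for b in branches)
    raise ConfigError(f"strategy {strategy.kind!r} has no arm for stratum {stratum!r}")
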