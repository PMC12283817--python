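"""Probabilistic sensitivity analysis, incremental CEA and population projection.

The PSA redraws every probability and utility parameter from a beta
distribution matched to its point estimate and standard error (method of
moments; an SE is recovered from a printed 95% CI as width/3.92), holds unit
costs fixed, and re-evaluates all strategies on the same draw (common random
parameters across strategies within an iteration).  Decision uncertainty is
summarised as percentile intervals and cost-effectiveness acceptability
curves: at willingness-to-pay threshold lambda, the probability a strategy
maximises net monetary benefit lambda*QALYs - cost, with ties split equally.

The incremental analysis orders strategies by cost, flags strict and
extended dominance, and reports ICERs along the efficient frontier
(computed on unrounded values).  The population projection scales the
screening-outcome probabilities to an annual birth cohort (600,000 women,
England and Wales) using the published whole-sample parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .model import STRATEGIES, Strategy, branch_probabilities, evaluate
from .params import ModelParams, Uncertain

__all__ = [
    "beta_from_moments",
    "draw_params",
    "PSAResult",
    "run_psa",
    "ceac_table",
    "incremental_analysis",
    "PopulationProjection",
    "project_population",
    "plot_ceac",
]

DEFAULT_THRESHOLDS = (0.0, 20000.0, 30000.0)

#: parameters redrawn in the PSA (probabilities and utilities; costs fixed)
PSA_FIELDS = [
    "p_highrisk", "prev_high", "prev_low", "p_modsev",
    "sens_std", "spec_std", "sens_cf_whole", "spec_cf_whole",
    "sens_cf_high", "spec_cf_high",
    "p_gp_visit_whole", "p_gp_visit_high", "p_gp_visit_low",
    "mix_ipt", "mix_pharma", "mix_both",
    "p_no_spont", "p_recover_fsh", "p_recover_ipt", "p_recover_pharma",
    "p_recover_combined",
    "u_nondep_whole", "u_nondep_high", "u_nondep_low",
]


def beta_from_moments(mean: float, se: float) -> tuple:
    """Beta shape parameters (alpha, beta) matching a mean and SE.

    Method of moments: nu = mean(1-mean)/se^2 - 1; alpha = mean*nu;
    beta = (1-mean)*nu.  Requires 0 < mean < 1 and se^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta mean {mean} must be strictly inside (0, 1)")
    if se <= 0:
        raise ConfigError(f"beta se {se} must be positive")
    if se * se >= mean * (1 - mean):
        raise ConfigError(f"se {se} too large for mean {mean} (variance bound exceeded)")
    nu = mean * (1 - mean) / (se * se) - 1.0
    return mean * nu, (1 - mean) * nu


def _draw(u: Uncertain, rng: np.random.Generator) -> float:
    if u.dist == "fixed":
        return u.value
    se = u.std_error
    if not se:  # no uncertainty descriptor -> degenerate
        return u.value
    a, b = beta_from_moments(u.value, se)
    return float(rng.beta(a, b))


def draw_params(params: ModelParams, rng: np.random.Generator) -> ModelParams:
    """One PSA draw: a new parameter set with every uncertain probability and
    utility redrawn; the treatment mix is renormalised to sum to one and the
    whole-sample prevalence is kept consistent with the stratified draws."""
    drawn = params.copy()
    for name in PSA_FIELDS:
        u = getattr(drawn, name)
        setattr(drawn, name, Uncertain(_draw(u, rng), se=u.se, ci95=u.ci95, dist=u.dist))
    total = drawn.mix_ipt.value + drawn.mix_pharma.value + drawn.mix_both.value
    for name in ("mix_ipt", "mix_pharma", "mix_both"):
        u = getattr(drawn, name)
        setattr(drawn, name, Uncertain(u.value / total, se=u.se, ci95=u.ci95))
    ph = drawn.p_highrisk.value
    drawn.prev_whole = Uncertain(
        ph * drawn.prev_high.value + (1 - ph) * drawn.prev_low.value,
        se=params.prev_whole.se, ci95=params.prev_whole.ci95)
    return drawn


@dataclass
class PSAResult:
    """Iteration-level PSA output plus summaries."""

    strategies: List[str]
    costs: np.ndarray    # (n_iter, n_strategies)
    qalys: np.ndarray
    thresholds: Sequence[float]
    seed: Optional[int] = None

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]

    def summary(self) -> pd.DataFrame:
        """Mean and percentile 95% interval of cost and QALYs per strategy."""
        rows = []
        for j, s in enumerate(self.strategies):
            c, q = self.costs[:, j], self.qalys[:, j]
            rows.append({
                "strategy": s,
                "cost_mean": c.mean(), "cost_lo": np.percentile(c, 2.5),
                "cost_hi": np.percentile(c, 97.5),
                "qalys_mean": q.mean(), "qalys_lo": np.percentile(q, 2.5),
                "qalys_hi": np.percentile(q, 97.5),
            })
        return pd.DataFrame(rows).set_index("strategy")

    def ceac(self) -> pd.DataFrame:
        return ceac_table(self.costs, self.qalys, self.strategies, self.thresholds)

    def iterations(self) -> pd.DataFrame:
        """Long-format iteration-level costs and QALYs."""
        frames = []
        for j, s in enumerate(self.strategies):
            frames.append(pd.DataFrame({
                "iteration": np.arange(self.n_iter), "strategy": s,
                "cost": self.costs[:, j], "qalys": self.qalys[:, j]}))
        return pd.concat(frames, ignore_index=True)


def ceac_table(costs: np.ndarray, qalys: np.ndarray, strategies: Sequence[str],
               thresholds: Sequence[float]) -> pd.DataFrame:
    """Probability each strategy is cost-effective at each threshold.

    A strategy 'wins' an iteration when its net monetary benefit is maximal;
    exact ties share the win equally, so the probabilities across strategies
    sum to one at every threshold.
    """
    rows = []
    for lam in thresholds:
        nmb = lam * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-12)
        share = winners / winners.sum(axis=1, keepdims=True)
        rows.append({"threshold": lam, **{s: share[:, j].mean() for j, s in enumerate(strategies)}})
    return pd.DataFrame(rows).set_index("threshold")


def run_psa(params: ModelParams, strategies: Optional[Sequence[Strategy]] = None,
            n_iter: int = 10000, seed: int = 0,
            thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
            population: str = "stratified") -> PSAResult:
    """Monte-Carlo PSA: ``n_iter`` joint redraws of all uncertain parameters.

    All strategies are evaluated on the same draw in each iteration.
    Deterministic under a fixed seed.
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    strategies = list(strategies) if strategies is not None else STRATEGIES()
    params.validate()
    rng = np.random.default_rng(seed)
    costs = np.empty((n_iter, len(strategies)))
    qalys = np.empty((n_iter, len(strategies)))
    for i in range(n_iter):
        drawn = draw_params(params, rng)
        for j, strat in enumerate(strategies):
            res = evaluate(strat, drawn, population=population, branch_table=False)
            costs[i, j] = res.cost
            qalys[i, j] = res.qalys
    return PSAResult([s.label for s in strategies], costs, qalys, tuple(thresholds), seed)


# ---------------------------------------------------------------------------
# incremental analysis

def incremental_analysis(ce_results) -> pd.DataFrame:
    """Incremental cost-effectiveness analysis with dominance.

    ``ce_results`` is a sequence of :class:`~casefind.model.CEResult` (or
    (label, cost, qalys) tuples).  Strategies are ordered by ascending cost
    (ties broken by label); strictly dominated strategies (>= cost and
    <= QALYs versus some other, at least one strict) and extendedly
    dominated strategies (ICER vs the previous frontier point exceeding that
    of a later point) are flagged; ICERs along the efficient frontier are
    strictly increasing.
    """
    items = []
    for r in ce_results:
        if hasattr(r, "cost"):
            items.append((r.strategy, float(r.cost), float(r.qalys)))
        else:
            label, c, q = r
            items.append((label, float(c), float(q)))
    if len(items) < 2:
        raise ConfigError("incremental analysis needs at least two strategies")
    items.sort(key=lambda t: (t[1], t[0]))

    status = {}
    for label, c, q in items:
        for lab2, c2, q2 in items:
            if lab2 != label and c2 <= c and q2 >= q and (c2 < c or q2 > q):
                status[label] = "dominated"
                break

    frontier = [it for it in items if status.get(it[0]) != "dominated"]
    # iterative extended dominance: drop frontier points whose incremental
    # ICER exceeds the next one's until ICERs are strictly increasing
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            l0, c0, q0 = frontier[i - 1]
            l1, c1, q1 = frontier[i]
            l2, c2, q2 = frontier[i + 1]
            icer1 = (c1 - c0) / (q1 - q0) if q1 != q0 else math.inf
            icer2 = (c2 - c1) / (q2 - q1) if q2 != q1 else math.inf
            if icer1 >= icer2:
                status[l1] = "extendedly_dominated"
                frontier.pop(i)
                changed = True
                break

    rows = []
    prev = None
    for label, c, q in items:
        st = status.get(label)
        if st is None:
            if prev is None:
                rows.append({"strategy": label, "cost": c, "qalys": q,
                             "status": "reference", "icer": np.nan, "comparator": None})
            else:
                icer = (c - prev[1]) / (q - prev[2]) if q != prev[2] else math.inf
                rows.append({"strategy": label, "cost": c, "qalys": q,
                             "status": "frontier", "icer": icer, "comparator": prev[0]})
            prev = (label, c, q)
        else:
            rows.append({"strategy": label, "cost": c, "qalys": q,
                         "status": st, "icer": np.nan, "comparator": None})
    return pd.DataFrame(rows).set_index("strategy")


# ---------------------------------------------------------------------------
# population projection

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class StratumCounts:
    """Screening-outcome counts for one population block."""

    n: int
    n_depressed: int
    tp: int
    tn: int
    fn: int
    fp: int


@dataclass
class PopulationProjection:
    """Outcomes of one strategy scaled to a fixed annual birth cohort."""

    strategy: str
    cohort_size: int
    blocks: dict = field(default_factory=dict)  # name -> StratumCounts
    total_costs: float = 0.0
    total_qalys: float = 0.0

    def table(self) -> pd.DataFrame:
        rows = []
        for name, b in self.blocks.items():
            rows.append({"block": name, "n": b.n, "n_depressed": b.n_depressed,
                         "tp": b.tp, "tn": b.tn, "fn": b.fn, "fp": b.fp})
        return pd.DataFrame(rows).set_index("block")


def _counts(n: float, prev_count: float, probs: dict) -> StratumCounts:
    """Round outcome counts half-up, with TN as the remainder so blocks sum."""
    tp = _round_half_up(n * probs["tp"])
    fn = _round_half_up(n * probs["fn"])
    fp = _round_half_up(n * probs["fp"])
    return StratumCounts(
        n=_round_half_up(n), n_depressed=_round_half_up(prev_count),
        tp=tp, fn=fn, fp=fp, tn=_round_half_up(n) - tp - fn - fp)


def project_population(strategy: Strategy, params: ModelParams,
                       cohort_size: int = 600000) -> PopulationProjection:
    """Screening-outcome counts and totals for a hypothetical birth cohort.

    Whole-population strategies use the published whole-sample prevalence,
    operating characteristics and GP-visit rate; the targeted strategy is
    reported as separate high-risk and low-risk blocks, the low-risk block
    carrying the depression left over after the high-risk block (preserving
    overall prevalence).  Counts are rounded half-up; total costs and QALYs
    are the per-person stratified means scaled to the cohort.
    """
    if cohort_size < 0:
        raise ConfigError("cohort_size must be >= 0")
    proj = PopulationProjection(strategy.label, cohort_size)
    N = float(cohort_size)
    if strategy.kind == "no_case_finding":
        probs = branch_probabilities(params.prev_whole.value, params.sens_std.value,
                                     params.spec_std.value, "standard_care",
                                     params.p_gp_visit_whole.value)
        proj.blocks["whole"] = _counts(N, N * params.prev_whole.value, probs)
    elif strategy.kind == "universal":
        probs = branch_probabilities(params.prev_whole.value, params.sens_cf_whole.value,
                                     params.spec_cf_whole.value, "case_finding")
        proj.blocks["whole"] = _counts(N, N * params.prev_whole.value, probs)
    else:
        n_high = N * params.p_highrisk.value
        n_low = N - n_high
        dep_high = n_high * params.prev_high.value
        dep_low = N * params.prev_whole.value - dep_high
        prev_low = dep_low / n_low if n_low else 0.0
        p_hi = branch_probabilities(params.prev_high.value, params.sens_cf_high.value,
                                    params.spec_cf_high.value, "case_finding")
        p_lo = branch_probabilities(prev_low, params.sens_std.value, params.spec_std.value,
                                    "standard_care", params.p_gp_visit_low.value)
        proj.blocks["high_risk"] = _counts(n_high, dep_high, p_hi)
        proj.blocks["low_risk"] = _counts(n_low, dep_low, p_lo)
    res = evaluate(strategy, params, population="stratified", branch_table=False)
    proj.total_costs = res.cost * cohort_size
    proj.total_qalys = res.qalys * cohort_size
    return proj


def plot_ceac(ceac: pd.DataFrame, ax=None):
    """Plot cost-effectiveness acceptability curves (one line per strategy)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in ceac.columns:
        ax.plot(ceac.index, ceac[col], marker="o", label=col)
    ax.set_xlabel("Willingness to pay (GBP/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
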