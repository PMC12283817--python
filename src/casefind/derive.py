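"""Derive model parameters from an individual-level cohort.

Given a cohort table (observed or synthetic), this module reproduces the
secondary-analysis steps that feed the decision model: stratification into
high/low depression-risk groups, prevalence and proportion estimates with
Wilson 95% confidence intervals, screening-strategy operating
characteristics (including two-stage chains), strategy inclusion filtering,
and stratum utility values with proportional decrements for depressive
states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._errors import EstimationError
from .params import ModelParams, Uncertain

__all__ = [
    "DerivedEstimate",
    "StrategyDefinition",
    "InstrumentPerformance",
    "STANDARD_STRATEGIES",
    "stratify",
    "estimate_proportion",
    "strategy_positive",
    "estimate_performance",
    "filter_strategies",
    "estimate_utilities",
    "params_from_cohort",
]

#: minimum acceptable operating characteristics for a case-finding strategy
MIN_SENSITIVITY = 0.70
MIN_SPECIFICITY = 0.60


@dataclass
class DerivedEstimate:
    """A proportion (or utility mean) with its SE and Wilson 95% CI."""

    name: str
    value: float
    se: float
    ci95: tuple
    n: int


@dataclass
class StrategyDefinition:
    """A case-finding instrument chain.

    ``stages`` is an ordered sequence of (instrument, threshold) pairs; the
    second stage is applied only to first-stage positives and a final
    positive requires every stage positive.  Thresholds are score cut-offs
    (``epds_score >= t``, ``phq9_score >= t``); the Whooley questions are
    binary so their threshold is ignored.
    """

    strategy_id: str
    stages: Sequence

    def __post_init__(self):
        if not self.stages:
            raise EstimationError(f"strategy {self.strategy_id!r} has no stages")


#: the instrument menu considered for inclusion
STANDARD_STRATEGIES = [
    StrategyDefinition("EPDS>=10", [("epds", 10)]),
    StrategyDefinition("EPDS>=13", [("epds", 13)]),
    StrategyDefinition("Whooley", [("whooley", None)]),
    StrategyDefinition("PHQ-9>=10", [("phq9", 10)]),
    StrategyDefinition("Whooley->EPDS>=10", [("whooley", None), ("epds", 10)]),
    StrategyDefinition("Whooley->EPDS>=13", [("whooley", None), ("epds", 13)]),
    StrategyDefinition("Whooley->PHQ-9", [("whooley", None), ("phq9", 10)]),
]


@dataclass
class InstrumentPerformance:
    """Sensitivity and specificity of a strategy in one stratum."""

    strategy_id: str
    stratum: str
    sensitivity: DerivedEstimate
    specificity: DerivedEstimate
    n_cases: int
    n_noncases: int


def stratify(records: pd.DataFrame) -> dict:
    """Partition a cohort into ``whole``, ``high_risk`` and ``low_risk`` views.

    A woman is high risk iff at least one of the four risk-factor indicators
    is set; the two risk strata are exhaustive and exclusive and their union
    is the whole sample.
    """
    high = records["high_risk"].astype(bool)
    return {
        "whole": records,
        "high_risk": records[high],
        "low_risk": records[~high],
    }


def estimate_proportion(records: pd.DataFrame, predicate, name: str = "proportion") -> DerivedEstimate:
    """k/n with the Wilson score 95% interval and binomial SE."""
    n = len(records)
    if n == 0:
        raise EstimationError(f"{name}: cannot estimate a proportion from zero records")
    flags = np.asarray(predicate(records) if callable(predicate) else records[predicate], dtype=bool)
    k = int(flags.sum())
    p = k / n
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    # guard float error at the boundaries so the interval brackets the estimate
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return DerivedEstimate(name, p, math.sqrt(p * (1 - p) / n), (lo, hi), n)


def strategy_positive(records: pd.DataFrame, strategy: StrategyDefinition) -> np.ndarray:
    """Boolean screen-positive indicator: every stage in the chain positive."""
    pos = np.ones(len(records), dtype=bool)
    for instrument, threshold in strategy.stages:
        if instrument == "whooley":
            stage = records["whooley_positive"].to_numpy(dtype=bool)
        elif instrument == "epds":
            stage = records["epds_score"].to_numpy() >= threshold
        elif instrument == "phq9":
            stage = records["phq9_score"].to_numpy() >= threshold
        else:
            raise EstimationError(f"unknown instrument {instrument!r}")
        pos &= stage
    return pos


def estimate_performance(records: pd.DataFrame, strategy: StrategyDefinition,
                         stratum: str = "whole") -> InstrumentPerformance:
    """Sensitivity/specificity of a strategy against gold-standard status."""
    group = stratify(records)[stratum]
    dep = group["depressed"].astype(bool)
    n_cases, n_noncases = int(dep.sum()), int((~dep).sum())
    if n_cases == 0 or n_noncases == 0:
        raise EstimationError(
            f"stratum {stratum!r} needs both depressed and non-depressed records "
            f"(has {n_cases} / {n_noncases})"
        )
    pos = strategy_positive(group, strategy)
    sens = estimate_proportion(group[dep.to_numpy()], lambda g: strategy_positive(g, strategy),
                               name=f"{strategy.strategy_id} sensitivity")
    spec = estimate_proportion(group[~dep.to_numpy()], lambda g: ~strategy_positive(g, strategy),
                               name=f"{strategy.strategy_id} specificity")
    return InstrumentPerformance(strategy.strategy_id, stratum, sens, spec, n_cases, n_noncases)


def filter_strategies(performances: Sequence[InstrumentPerformance]):
    """Split strategies into included and excluded by the acceptability rules.

    A strategy is included iff sensitivity >= 70% (detecting cases is the
    point of the programme; 50% is no better than chance) and specificity
    >= 60% (limiting resources spent on false positives).  Returns
    ``(included, exclusions)`` where exclusions map strategy id to the list
    of failed criteria.
    """
    included, exclusions = [], {}
    for perf in performances:
        reasons = []
        if perf.sensitivity.value < MIN_SENSITIVITY:
            reasons.append(f"sensitivity {perf.sensitivity.value:.3f} < {MIN_SENSITIVITY:.2f}")
        if perf.specificity.value < MIN_SPECIFICITY:
            reasons.append(f"specificity {perf.specificity.value:.3f} < {MIN_SPECIFICITY:.2f}")
        if reasons:
            exclusions[perf.strategy_id] = reasons
        else:
            included.append(perf)
    return included, exclusions


def estimate_utilities(records: pd.DataFrame, decrement_mild: float = 0.12,
                       decrement_modsev: float = 0.26) -> pd.DataFrame:
    """Utility table by stratum and health state.

    The non-depressed mean EQ-5D utility (with SE) is estimated per stratum;
    depressed-state utilities are formed by applying the proportional
    decrements to the stratum's non-depressed mean, mirroring how the model
    parameterises depression disutility.
    """
    rows = []
    for stratum, group in stratify(records).items():
        nondep = group.loc[~group["depressed"].astype(bool), "eq5d_utility"]
        if len(nondep) == 0:
            raise EstimationError(f"stratum {stratum!r} has no non-depressed records")
        mean = float(nondep.mean())
        se = float(nondep.std(ddof=1) / math.sqrt(len(nondep))) if len(nondep) > 1 else float("nan")
        rows.append({
            "stratum": stratum,
            "n_nondepressed": len(nondep),
            "u_nondepressed": mean,
            "se_nondepressed": se,
            "u_mild": mean * (1 - decrement_mild),
            "u_modsev": mean * (1 - decrement_modsev),
        })
    return pd.DataFrame(rows).set_index("stratum")


def params_from_cohort(records: pd.DataFrame,
                       strategy: Optional[StrategyDefinition] = None,
                       base: Optional[ModelParams] = None) -> ModelParams:
    """Assemble a :class:`ModelParams` whose cohort-derived block comes from data.

    Prevalences, the high-risk proportion, GP-visit rates, non-depressed
    utilities, the moderate/severe severity share and the chosen strategy's
    operating characteristics are re-estimated from ``records``; every
    literature-sourced parameter (treatment mix and effects, unit costs,
    standard-care identification) is taken from ``base`` (the default
    parameter set if not given).
    """
    params = (base.copy() if base is not None else ModelParams())
    strategy = strategy or StrategyDefinition("Whooley->PHQ-9", [("whooley", None), ("phq9", 10)])
    strata = stratify(records)

    def as_unc(est: DerivedEstimate) -> Uncertain:
        return Uncertain(est.value, se=est.se, ci95=est.ci95)

    params.p_highrisk = as_unc(estimate_proportion(records, "high_risk", "p_highrisk"))
    params.prev_whole = as_unc(estimate_proportion(strata["whole"], "depressed", "prev_whole"))
    params.prev_high = as_unc(estimate_proportion(strata["high_risk"], "depressed", "prev_high"))
    params.prev_low = as_unc(estimate_proportion(strata["low_risk"], "depressed", "prev_low"))
    dep = records[records["depressed"].astype(bool)]
    if len(dep):
        params.p_modsev = as_unc(estimate_proportion(
            dep, lambda g: g["severity"] == "moderate_severe", "p_modsev"))
    params.p_gp_visit_whole = as_unc(estimate_proportion(strata["whole"], "gp_visit", "gp_visit"))
    params.p_gp_visit_high = as_unc(estimate_proportion(strata["high_risk"], "gp_visit", "gp_visit"))
    params.p_gp_visit_low = as_unc(estimate_proportion(strata["low_risk"], "gp_visit", "gp_visit"))

    perf_whole = estimate_performance(records, strategy, "whole")
    perf_high = estimate_performance(records, strategy, "high_risk")
    params.sens_cf_whole = as_unc(perf_whole.sensitivity)
    params.spec_cf_whole = as_unc(perf_whole.specificity)
    params.sens_cf_high = as_unc(perf_high.sensitivity)
    params.spec_cf_high = as_unc(perf_high.specificity)

    util = estimate_utilities(records, params.decrement_mild, params.decrement_modsev)
    params.u_nondep_whole = Uncertain(util.loc["whole", "u_nondepressed"],
                                      se=util.loc["whole", "se_nondepressed"])
    params.u_nondep_high = Uncertain(util.loc["high_risk", "u_nondepressed"],
                                     se=util.loc["high_risk", "se_nondepressed"])
    params.u_nondep_low = Uncertain(util.loc["low_risk", "u_nondepressed"],
                                    se=util.loc["low_risk", "se_nondepressed"])
    params.validate()
    return params
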