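"""Declarative one-way sensitivity-analysis engine.

A scenario is a named set of parameter overrides applied to a copy of the
base parameter set (the base is never mutated, so scenarios compose and
revert trivially).  :func:`builtin_scenarios` ships the pre-specified
scenario set: a utility decrement for false positives (2%, 10%), zero or
threefold instrument administration time, alternative false-positive
treatment fractions (10%, 30%), alternative probabilities of a missed case
being identified in primary care (5%, 25%), and a longer GP consultation to
assess depression (13.83 min, 1.5x the average appointment).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import pandas as pd
import yaml

from ._errors import ScenarioError
from .model import STRATEGIES, Strategy, evaluate
from .params import ModelParams, Uncertain
from .psa import incremental_analysis

__all__ = [
    "ScenarioConfig",
    "apply_scenario",
    "run_scenarios",
    "builtin_scenarios",
    "load_scenarios",
]


@dataclass
class ScenarioConfig:
    """A named set of (parameter path, value) overrides.

    Paths address :class:`~casefind.params.ModelParams` fields; an uncertain
    parameter's point estimate is addressed either directly (``"sens_std"``)
    or explicitly (``"sens_std.value"``).
    """

    name: str
    overrides: dict = dc_field(default_factory=dict)
    description: str = ""


def _valid_paths(params: ModelParams) -> list:
    return sorted(vars(params).keys())


def apply_scenario(params: ModelParams, scenario: ScenarioConfig) -> ModelParams:
    """Return a new parameter set with the scenario's overrides applied.

    The base set is untouched.  Unknown paths raise :class:`ScenarioError`
    listing the valid parameter fields; the result is re-validated so an
    override can never leave a probability outside [0, 1] silently.
    """
    out = params.copy()
    for path, value in scenario.overrides.items():
        parts = path.split(".")
        name = parts[0]
        if not hasattr(out, name):
            raise ScenarioError(
                f"scenario {scenario.name!r}: unknown parameter {path!r}; "
                f"valid fields: {', '.join(_valid_paths(out))}"
            )
        current = getattr(out, name)
        if isinstance(current, Uncertain):
            if len(parts) > 2 or (len(parts) == 2 and parts[1] != "value"):
                raise ScenarioError(
                    f"scenario {scenario.name!r}: {path!r} — only the point "
                    f"estimate ('{name}' or '{name}.value') can be overridden")
            setattr(out, name, Uncertain(float(value), se=current.se,
                                         ci95=current.ci95, dist=current.dist))
        else:
            if len(parts) > 1:
                raise ScenarioError(f"scenario {scenario.name!r}: {path!r} is not a nested parameter")
            setattr(out, name, type(current)(value) if current is not None else value)
    out.validate()
    return out


def run_scenarios(base_params: ModelParams, scenarios: Sequence[ScenarioConfig],
                  strategies: Optional[Sequence[Strategy]] = None) -> pd.DataFrame:
    """Deterministic evaluation plus incremental analysis for each scenario.

    Returns one row per (scenario, strategy) with per-person cost, QALYs and
    the strategy's incremental status (reference / frontier ICER / dominated).
    """
    strategies = list(strategies) if strategies is not None else STRATEGIES()
    rows = []
    for scen in scenarios:
        p = apply_scenario(base_params, scen)
        results = [evaluate(s, p, branch_table=False) for s in strategies]
        inc = incremental_analysis(results)
        for res in results:
            rows.append({
                "scenario": scen.name,
                "strategy": res.strategy,
                "cost": res.cost,
                "qalys": res.qalys,
                "status": inc.loc[res.strategy, "status"],
                "icer": inc.loc[res.strategy, "icer"],
                "comparator": inc.loc[res.strategy, "comparator"],
            })
    return pd.DataFrame(rows)


def builtin_scenarios() -> list:
    """The pre-specified one-way sensitivity analyses (plus the base case)."""
    return [
        ScenarioConfig("base_case", {}, "Base-case assumptions"),
        ScenarioConfig("fp_decrement_2pct", {"fp_utility_decrement": 0.02},
                       "2% utility decrement for false-positive outcomes"),
        ScenarioConfig("fp_decrement_10pct", {"fp_utility_decrement": 0.10},
                       "10% utility decrement for false-positive outcomes"),
        ScenarioConfig("admin_time_online", {"whooley_admin_min": 0.0, "epds_admin_min": 0.0},
                       "Instruments completed online before the visit: no "
                       "administration time, scoring time retained"),
        ScenarioConfig("admin_time_3x", {"instrument_time_multiplier": 3.0},
                       "Threefold instrument administration and scoring time "
                       "(a more conversational approach)"),
        ScenarioConfig("fp_treatment_10pct", {"fp_treatment_fraction": 0.10},
                       "False positives incur 10% of the full FSH cost"),
        ScenarioConfig("fp_treatment_30pct", {"fp_treatment_fraction": 0.30},
                       "False positives incur 30% of the full FSH cost"),
        ScenarioConfig("fn_identified_5pct", {"p_fn_identified": 0.05},
                       "5% of persistent missed cases identified in primary care"),
        ScenarioConfig("fn_identified_25pct", {"p_fn_identified": 0.25},
                       "25% of persistent missed cases identified in primary care"),
        ScenarioConfig("gp_consult_longer", {"gp_assessment_minutes": 13.83},
                       "GP assessment consultations 1.5x the average length"),
    ]


def load_scenarios(path) -> list:
    """Load scenarios from a YAML file: a list of {name, overrides, description}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ScenarioError(f"scenario file {path} must contain a list of scenarios")
    return [ScenarioConfig(d["name"], d.get("overrides", {}) or {}, d.get("description", ""))
            for d in raw]
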