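"""Model parameter set and unit-cost / treatment-effect arithmetic.

The economic model compares three policies for identifying antenatal
depression at ~20 weeks gestation — no case finding, universal case finding,
and case finding targeted at women with at least one depression risk factor —
over a 20-week horizon from the English NHS perspective (GBP, 2021 prices).

:class:`ModelParams` holds every quantity the decision tree needs:
epidemiology (risk-factor and depression prevalence by stratum, severity
split), screening-instrument and standard-care operating characteristics,
treatment mix and response probabilities, unit costs built up from staff
minutes and per-minute rates, and EQ-5D utility values with proportional
decrements for depressive states.  Probabilities and utilities carry
uncertainty descriptors (SE or 95% CI) for probabilistic sensitivity
analysis; unit costs are treated as fixed.

Derived probabilities (baseline risk x relative risk) are carried unrounded;
two-decimal values are for reporting only.  Money is rounded half-up to the
penny at reporting boundaries.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import yaml

from ._errors import ConfigError

__all__ = [
    "Uncertain",
    "CostComponents",
    "ModelParams",
    "instrument_cost",
    "treatment_cost",
    "false_positive_cost",
    "derive_recovery",
    "round_money",
    "default_params",
    "save_params",
    "load_params",
]

#: price of one average-length (9.22 min) GP consultation, GBP
GP_CONSULT_COST = 39.23
#: minutes of an average GP consultation underlying that price
GP_CONSULT_MINUTES = 9.22


def round_money(x: float) -> float:
    """Round a monetary amount half-up to the penny."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class Uncertain:
    """A scalar parameter with an uncertainty descriptor.

    ``se`` takes precedence; otherwise the SE is recovered from a 95% CI as
    (upper - lower) / 3.92.  ``dist`` is ``"beta"`` for quantities on [0, 1]
    and ``"fixed"`` for parameters excluded from probabilistic analysis.
    """

    value: float
    se: Optional[float] = None
    ci95: Optional[tuple] = None
    dist: str = "beta"

    @property
    def std_error(self) -> Optional[float]:
        if self.se is not None:
            return self.se
        if self.ci95 is not None:
            lo, hi = self.ci95
            return (hi - lo) / 3.92
        return None

    def to_dict(self) -> dict:
        d = {"value": self.value, "dist": self.dist}
        if self.se is not None:
            d["se"] = self.se
        if self.ci95 is not None:
            d["ci95"] = list(self.ci95)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Uncertain":
        ci = tuple(d["ci95"]) if d.get("ci95") is not None else None
        return cls(value=d["value"], se=d.get("se"), ci95=ci, dist=d.get("dist", "beta"))


@dataclass
class CostComponents:
    """Primitive components of a treatment/monitoring cost."""

    staff_minutes: float = 0.0
    rate_per_minute: float = 0.0
    materials: float = 0.0
    gp_consultations: int = 0
    drug_cost: float = 0.0

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigError(f"CostComponents.{f.name} must be non-negative")


def instrument_cost(admin_minutes: float, scoring_minutes: float, rate_per_minute: float) -> float:
    """Cost of administering and scoring one screening instrument, to the penny.

    E.g. the two Whooley questions: (0.71 + 1) min of midwife time at
    GBP 0.92/min -> GBP 1.57.
    """
    if admin_minutes < 0 or scoring_minutes < 0 or rate_per_minute < 0:
        raise ConfigError("instrument_cost arguments must be non-negative")
    return round_money((admin_minutes + scoring_minutes) * rate_per_minute)


def treatment_cost(components: CostComponents) -> float:
    """Total cost of a treatment pathway from its primitive components."""
    components.validate()
    total = (
        components.staff_minutes * components.rate_per_minute
        + components.materials
        + components.gp_consultations * GP_CONSULT_COST
        + components.drug_cost
    )
    return round_money(total)


def false_positive_cost(full_fsh_cost: float, fraction: float) -> float:
    """Partial treatment cost incurred by a false-positive case.

    Women incorrectly identified as depressed are assumed to start (but not
    complete) facilitated self-help; ``fraction`` of the full FSH cost is
    incurred (0.20 in the base case).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("false_positive_cost fraction must be in [0, 1]")
    return round_money(full_fsh_cost * fraction)


def derive_recovery(baseline: float, relative_risk: float, direction: str = "recovery") -> float:
    """Probability of *no* recovery from a baseline probability and a relative risk.

    ``direction="recovery"``: baseline and RR describe recovery, so the
    no-recovery probability is 1 - baseline * RR.  ``direction="no_recovery"``:
    baseline and RR describe failure to recover, returned directly as
    baseline * RR.  The product must be a valid probability.
    """
    if direction not in ("recovery", "no_recovery"):
        raise ConfigError(f"unknown direction {direction!r}")
    p = baseline * relative_risk
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"baseline x RR = {p:.4f} is outside [0, 1]")
    return 1.0 - p if direction == "recovery" else p


# Wilson-style SEs for the modelled two-stage strategy, at the source cohort's
# approximate stratum sizes (whole sample: ~40 depressed / ~351 non-depressed;
# high-risk subgroup: ~37 / ~181).
def _binom_se(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)


@dataclass
class ModelParams:
    """Complete parameter set of the decision model.

    Field groups: epidemiology, case identification, treatment effects,
    unit costs (fixed), utilities, and the time structure of the 20-week
    horizon.  ``prev_low`` defaults to the value implied by the whole-sample
    and high-risk prevalences (preserving overall prevalence when the cohort
    is split), not the independently rounded low-risk estimate.
    """

    # --- epidemiology -----------------------------------------------------
    p_highrisk: Uncertain = field(default_factory=lambda: Uncertain(0.558, ci95=(0.507, 0.607)))
    prev_whole: Uncertain = field(default_factory=lambda: Uncertain(0.103, ci95=(0.074, 0.137)))
    prev_high: Uncertain = field(default_factory=lambda: Uncertain(0.171, ci95=(0.122, 0.227)))
    # derived: (0.103 - 0.558*0.171) / 0.442; CI from the printed low-risk row
    prev_low: Uncertain = field(
        default_factory=lambda: Uncertain((0.103 - 0.558 * 0.171) / (1 - 0.558), ci95=(0.004, 0.050))
    )
    p_modsev: Uncertain = field(default_factory=lambda: Uncertain(0.30, se=0.030))

    # --- case identification ---------------------------------------------
    sens_std: Uncertain = field(default_factory=lambda: Uncertain(0.501, ci95=(0.413, 0.590)))
    spec_std: Uncertain = field(default_factory=lambda: Uncertain(0.813, ci95=(0.745, 0.873)))
    sens_cf_whole: Uncertain = field(default_factory=lambda: Uncertain(0.706, se=_binom_se(0.706, 40)))
    spec_cf_whole: Uncertain = field(default_factory=lambda: Uncertain(0.895, se=_binom_se(0.895, 351)))
    sens_cf_high: Uncertain = field(default_factory=lambda: Uncertain(0.742, se=_binom_se(0.742, 37)))
    spec_cf_high: Uncertain = field(default_factory=lambda: Uncertain(0.850, se=_binom_se(0.850, 181)))
    p_gp_visit_whole: Uncertain = field(default_factory=lambda: Uncertain(0.722, ci95=(0.675, 0.765)))
    p_gp_visit_high: Uncertain = field(default_factory=lambda: Uncertain(0.780, ci95=(0.721, 0.830)))
    p_gp_visit_low: Uncertain = field(default_factory=lambda: Uncertain(0.642, ci95=(0.565, 0.712)))
    #: probability that a false negative who does not spontaneously recover is
    #: identified as depressed at the mid-horizon GP visit (expert opinion)
    p_fn_identified: float = 0.10

    # --- treatment: mix for moderate/severe depression --------------------
    mix_ipt: Uncertain = field(default_factory=lambda: Uncertain(0.128, ci95=(0.092, 0.171)))
    mix_pharma: Uncertain = field(default_factory=lambda: Uncertain(0.523, ci95=(0.465, 0.581)))
    mix_both: Uncertain = field(default_factory=lambda: Uncertain(0.349, ci95=(0.295, 0.406)))

    # --- treatment effects (recovery probabilities, unrounded) ------------
    p_no_spont: Uncertain = field(default_factory=lambda: Uncertain(0.65, se=0.065))
    p_recover_fsh: Uncertain = field(
        default_factory=lambda: Uncertain(1 - derive_recovery(0.38, 1.59), ci95=(0.51, 0.72))
    )
    p_recover_ipt: Uncertain = field(
        default_factory=lambda: Uncertain(1 - derive_recovery(0.64, 0.69, "no_recovery"), ci95=(0.45, 0.64))
    )
    p_recover_pharma: Uncertain = field(
        default_factory=lambda: Uncertain(1 - derive_recovery(0.43, 1.27), ci95=(0.41, 0.71))
    )
    p_recover_combined: Uncertain = field(
        default_factory=lambda: Uncertain(1 - derive_recovery(0.43, 1.47), ci95=(0.51, 0.75))
    )

    # --- unit costs (fixed in PSA) -----------------------------------------
    midwife_rate_per_min: float = 0.92
    whooley_admin_min: float = 0.71
    whooley_scoring_min: float = 1.0
    epds_admin_min: float = 1.54       # PHQ-9 assumed to take the same time
    epds_scoring_min: float = 2.0
    instrument_time_multiplier: float = 1.0  # sensitivity analyses: 3x
    assessment_cost: float = 55.0      # 1 h midwife further assessment of screen positives
    gp_consult_cost: float = GP_CONSULT_COST
    gp_assessment_minutes: float = GP_CONSULT_MINUTES  # scenario: 13.83
    fsh_minutes: float = 175.0
    fsh_rate_per_min: float = 0.85
    fsh_materials: float = 7.0
    fsh_gp_consults: int = 3
    ipt_minutes: float = 440.0
    ipt_rate_per_min: float = 1.80
    ipt_gp_consults: int = 3
    sertraline_cost: float = 25.65
    pharma_gp_consults: int = 7
    fp_treatment_fraction: float = 0.20

    # --- utilities ---------------------------------------------------------
    u_nondep_whole: Uncertain = field(default_factory=lambda: Uncertain(0.910, se=0.01))
    u_nondep_high: Uncertain = field(default_factory=lambda: Uncertain(0.869, se=0.01))
    u_nondep_low: Uncertain = field(default_factory=lambda: Uncertain(0.910, se=0.01))
    decrement_mild: float = 0.12
    decrement_modsev: float = 0.26
    fp_utility_decrement: float = 0.0  # sensitivity analyses: 0.02, 0.10

    # --- time structure -----------------------------------------------------
    horizon_weeks: float = 20.0
    treatment_weeks: float = 8.0
    spont_recovery_weeks: float = 7.0
    fn_identify_week: float = 10.0
    weeks_per_year: float = 52.0

    #: fraction of screened women who also receive the second-stage instrument
    #: when the strategy is two-stage (the printed scenario arithmetic implies
    #: both stages are administered and costed for everyone: 1.0)
    first_stage_positive_rate: float = 1.0

    # ---------------------------------------------------------------- costs
    def whooley_cost(self) -> float:
        m = self.instrument_time_multiplier
        return instrument_cost(
            self.whooley_admin_min * m, self.whooley_scoring_min * m, self.midwife_rate_per_min
        )

    def epds_cost(self) -> float:
        """Cost of one EPDS (or PHQ-9) administration + scoring."""
        m = self.instrument_time_multiplier
        return instrument_cost(
            self.epds_admin_min * m, self.epds_scoring_min * m, self.midwife_rate_per_min
        )

    phq9_cost = epds_cost

    def fsh_cost(self) -> float:
        return treatment_cost(
            CostComponents(
                staff_minutes=self.fsh_minutes,
                rate_per_minute=self.fsh_rate_per_min,
                materials=self.fsh_materials,
                gp_consultations=self.fsh_gp_consults,
            )
        )

    def ipt_cost(self) -> float:
        return treatment_cost(
            CostComponents(
                staff_minutes=self.ipt_minutes,
                rate_per_minute=self.ipt_rate_per_min,
                gp_consultations=self.ipt_gp_consults,
            )
        )

    def pharma_cost(self) -> float:
        return treatment_cost(
            CostComponents(drug_cost=self.sertraline_cost, gp_consultations=self.pharma_gp_consults)
        )

    def combined_cost(self) -> float:
        return round_money(self.ipt_cost() + self.sertraline_cost)

    def fp_cost(self) -> float:
        return false_positive_cost(self.fsh_cost(), self.fp_treatment_fraction)

    def identification_consult_cost(self) -> float:
        """GP consultation to assess depressive symptoms, rescaled with its length."""
        return round_money(self.gp_consult_cost * self.gp_assessment_minutes / GP_CONSULT_MINUTES)

    # ------------------------------------------------------------- validate
    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first invalid field."""
        proportions = [
            "p_highrisk", "prev_whole", "prev_high", "prev_low", "p_modsev",
            "sens_std", "spec_std", "sens_cf_whole", "spec_cf_whole",
            "sens_cf_high", "spec_cf_high", "p_gp_visit_whole", "p_gp_visit_high",
            "p_gp_visit_low", "mix_ipt", "mix_pharma", "mix_both", "p_no_spont",
            "p_recover_fsh", "p_recover_ipt", "p_recover_pharma", "p_recover_combined",
            "u_nondep_whole", "u_nondep_high", "u_nondep_low",
        ]
        for name in proportions:
            v = getattr(self, name).value
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} is outside [0, 1]")
        for name in ["p_fn_identified", "decrement_mild", "decrement_modsev",
                     "fp_utility_decrement", "fp_treatment_fraction"]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} is outside [0, 1]")
        mix = self.mix_ipt.value + self.mix_pharma.value + self.mix_both.value
        if abs(mix - 1.0) > 1e-9:
            raise ConfigError(f"treatment mix sums to {mix}, expected 1")
        for name in ["midwife_rate_per_min", "whooley_admin_min", "whooley_scoring_min",
                     "epds_admin_min", "epds_scoring_min", "instrument_time_multiplier",
                     "assessment_cost", "gp_consult_cost", "gp_assessment_minutes",
                     "fsh_minutes", "fsh_rate_per_min", "fsh_materials", "ipt_minutes",
                     "ipt_rate_per_min", "sertraline_cost"]:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.horizon_weeks < self.treatment_weeks:
            raise ConfigError("horizon_weeks must be at least treatment_weeks")
        if self.fn_identify_week + self.treatment_weeks > self.horizon_weeks + 1e-9:
            raise ConfigError("fn_identify_week + treatment_weeks exceeds the horizon")

    # --------------------------------------------------------------- copies
    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    def treatment_modsev(self) -> list:
        """(label, mix weight, cost, recovery probability) for moderate/severe
        depression, with the mix renormalised to sum to one."""
        total = self.mix_ipt.value + self.mix_pharma.value + self.mix_both.value
        return [
            ("ipt", self.mix_ipt.value / total, self.ipt_cost(), self.p_recover_ipt.value),
            ("pharma", self.mix_pharma.value / total, self.pharma_cost(), self.p_recover_pharma.value),
            ("combined", self.mix_both.value / total, self.combined_cost(), self.p_recover_combined.value),
        ]

    # ------------------------------------------------------------ (de)serialise
    def to_dict(self) -> dict:
        out = {"schema": "casefind-params-v1"}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.to_dict() if isinstance(v, Uncertain) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        d.pop("schema", None)
        known = {f.name: f for f in fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown parameter fields: {sorted(unknown)}")
        kwargs = {}
        for name, raw in d.items():
            if isinstance(raw, dict) and "value" in raw:
                kwargs[name] = Uncertain.from_dict(raw)
            else:
                kwargs[name] = raw
        return cls(**kwargs)


def default_params() -> ModelParams:
    """The base-case parameter set."""
    p = ModelParams()
    p.validate()
    return p


def save_params(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params(path) -> ModelParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    p = ModelParams.from_dict(d)
    p.validate()
    return p
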