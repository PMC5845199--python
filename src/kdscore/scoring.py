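"""Declarative rule engine for point-based IVIG-resistance scores.

Six published prediction models are built in:

- **kobayashi** (Japan, 2006): Na ≤ 133 mmol/L (2), illness day ≤ 4 (2),
  AST ≥ 100 IU/L (2), N% ≥ 80 (2), CRP ≥ 100 mg/L (1), age ≤ 12 mo (1),
  PLT ≤ 300×10^9/L (1); high risk at a configurable cutoff (default 3).
- **egami** (Japan, 2006): age ≤ 6 mo (1), illness day ≤ 4 (1),
  CRP ≥ 80 mg/L (1), ALT ≥ 80 IU/L (2), PLT < 300 (1); high ≥ 3.
- **sano** (Japan, 2007): CRP ≥ 70 mg/L (1), TB ≥ 15.394 µmol/L (1),
  AST ≥ 200 IU/L (1); high ≥ 2.
- **formosa** (Taiwan, 2015): cervical lymphadenopathy (1), N% ≥ 60 (2),
  ALB < 35 g/L (1); high ≥ 3.
- **ours** (China, 2016): age < 6 mo (2), ALB < 35 g/L (2), rash (1),
  edema of extremities (1), N% ≥ 80 (1); high ≥ 3.
- **kawamura** (Japan, 2016): a points-free combination rule on the
  neutrophil-to-lymphocyte ratio (NLR ≥ 3.83) and the
  platelet-to-lymphocyte ratio (PLR ≥ 150).

Comparator boundaries are taken literally from the published tables:
``≥``/``≤`` are inclusive, ``>``/``<`` strict — so PLT = 300 satisfies
Kobayashi's "PLT ≤ 300" but not Egami's "PLT < 300".

Missing inputs are handled per model by a ``missing_policy``:

- ``indeterminate`` (default): a patient is classified high only when
  the already-met criteria guarantee the cutoff, low only when even
  meeting every missing criterion could not reach it, and
  ``indeterminate`` otherwise.  Downstream evaluation excludes
  indeterminate patients from that model's 2×2 table.
- ``treat_as_unmet``: missing criteria score zero points and every
  patient is classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import yaml

from .cohort import PatientRecord, derive_ratios
from .errors import ConfigurationError
from .units import TB_UMOL_PER_MG_DL

MET, UNMET, MISSING = "met", "unmet", "missing"
HIGH, LOW, INDETERMINATE = "high", "low", "indeterminate"

_NUMERIC_COMPARATORS = {"<=", "<", ">=", ">"}

#: Variables a criterion may reference, with how to fetch them.
_SIGN_VARIABLES = {"rash", "edema_extremities", "cervical_lymphadenopathy",
                   "oral_mucosal_changes", "strawberry_tongue",
                   "desquamation_fingertips", "conjunctival_injection"}
_RECORD_VARIABLES = {"age_months", "illness_day_at_treatment"}
_LAB_VARIABLES = {"crp", "alt", "ast", "na", "alb", "plt", "neut_pct",
                  "neut_count", "lymph_count", "tb"}
_RATIO_VARIABLES = {"nlr", "plr"}
KNOWN_VARIABLES = _SIGN_VARIABLES | _RECORD_VARIABLES | _LAB_VARIABLES | _RATIO_VARIABLES


@dataclass(frozen=True)
class ScoreCriterion:
    """One scoring rule: ``variable comparator threshold -> points``.

    ``comparator`` is one of ``<=``, ``<``, ``>=``, ``>`` or
    ``is_present`` (for clinical signs, which carry no threshold).
    Thresholds are in canonical units.
    """

    variable: str
    comparator: str
    threshold: Optional[float]
    points: int = 1

    def __post_init__(self):
        if self.variable not in KNOWN_VARIABLES:
            raise ConfigurationError(f"criterion references unknown variable {self.variable!r}")
        if self.comparator == "is_present":
            if self.threshold is not None:
                raise ConfigurationError("is_present criterion must not carry a threshold")
        elif self.comparator in _NUMERIC_COMPARATORS:
            if self.threshold is None:
                raise ConfigurationError(f"numeric comparator {self.comparator!r} needs a threshold")
        else:
            raise ConfigurationError(f"unknown comparator {self.comparator!r}")
        if self.points < 1:
            raise ConfigurationError("criterion points must be >= 1")

    @property
    def label(self) -> str:
        if self.comparator == "is_present":
            return f"{self.variable}"
        return f"{self.variable}{self.comparator}{self.threshold:g}"


@dataclass(frozen=True)
class RiskScoreModel:
    """A named set of point criteria with a high-risk cutoff."""

    name: str
    criteria: tuple[ScoreCriterion, ...]
    high_risk_cutoff: int
    missing_policy: str = INDETERMINATE

    def __post_init__(self):
        object.__setattr__(self, "criteria", tuple(self.criteria))
        vars_ = [c.variable for c in self.criteria]
        if len(set(vars_)) != len(vars_):
            raise ConfigurationError(f"model {self.name!r}: criterion variables must be distinct")
        if self.high_risk_cutoff > self.max_points:
            raise ConfigurationError(f"model {self.name!r}: cutoff exceeds maximum score")
        if self.missing_policy not in (INDETERMINATE, "treat_as_unmet"):
            raise ConfigurationError(f"unknown missing_policy {self.missing_policy!r}")

    @property
    def max_points(self) -> int:
        return sum(c.points for c in self.criteria)


BOTH_REQUIRED, EITHER_SUFFICIENT = "both_required", "either_sufficient"


@dataclass(frozen=True)
class CombinationRuleModel:
    """Points-free combination rule on derived NLR/PLR ratios.

    Under ``both_required`` a patient is high risk iff NLR ≥ 3.83 and
    PLR ≥ 150 both hold; under ``either_sufficient`` one suffices.
    """

    name: str = "kawamura"
    nlr_threshold: float = 3.83
    plr_threshold: float = 150.0
    combination: str = BOTH_REQUIRED
    missing_policy: str = INDETERMINATE

    def __post_init__(self):
        if self.combination not in (BOTH_REQUIRED, EITHER_SUFFICIENT):
            raise ConfigurationError(f"unknown combination {self.combination!r}")
        if self.missing_policy not in (INDETERMINATE, "treat_as_unmet"):
            raise ConfigurationError(f"unknown missing_policy {self.missing_policy!r}")


AnyModel = Union[RiskScoreModel, CombinationRuleModel]


@dataclass
class ScoreResult:
    """Per-patient, per-model outcome of score evaluation.

    ``total_points`` is the sum over met criteria (``None`` for the
    points-free combination model).  ``satisfied`` lists the labels of
    met criteria; ``missing_variables`` the variables that could not be
    evaluated.  ``risk_class`` is ``high``/``low``/``indeterminate``.
    """

    model: str
    total_points: Optional[int]
    satisfied: list[str] = field(default_factory=list)
    risk_class: str = LOW
    missing_variables: list[str] = field(default_factory=list)

    @property
    def ordinal_score(self) -> int:
        """Score used for ROC analysis: total points, or the number of
        satisfied criteria for the combination model."""
        return self.total_points if self.total_points is not None else len(self.satisfied)


def _lookup(patient: PatientRecord, variable: str):
    """Fetch a criterion variable from a record; None means unknown."""
    if variable in _RECORD_VARIABLES:
        return getattr(patient, variable)
    if variable in _LAB_VARIABLES:
        return getattr(patient.labs, variable)
    if variable in _SIGN_VARIABLES:
        return getattr(patient.signs, variable)
    if variable in _RATIO_VARIABLES:
        nlr, plr = derive_ratios(patient.labs)
        return nlr if variable == "nlr" else plr
    raise ConfigurationError(f"unknown variable {variable!r}")


def evaluate_criterion(criterion: ScoreCriterion, patient: PatientRecord) -> str:
    """Evaluate one criterion on one patient: ``met``/``unmet``/``missing``."""
    value = _lookup(patient, criterion.variable)
    if value is None:
        return MISSING
    if criterion.comparator == "is_present":
        return MET if value else UNMET
    t = criterion.threshold
    ok = {"<=": value <= t, "<": value < t, ">=": value >= t, ">": value > t}[criterion.comparator]
    return MET if ok else UNMET


def apply_point_model(model: RiskScoreModel, patient: PatientRecord) -> ScoreResult:
    """Score a patient under a point model and stratify high/low risk.

    With ``missing_policy='indeterminate'`` the risk class is ``high``
    when met points already reach the cutoff, ``low`` when met points
    plus every missing criterion's points stay below it, and
    ``indeterminate`` otherwise (the classification genuinely depends
    on the unobserved values).
    """
    met_points = 0
    satisfied: list[str] = []
    missing_vars: list[str] = []
    missing_points = 0
    for c in model.criteria:
        status = evaluate_criterion(c, patient)
        if status == MET:
            met_points += c.points
            satisfied.append(c.label)
        elif status == MISSING:
            missing_vars.append(c.variable)
            missing_points += c.points

    if model.missing_policy == "treat_as_unmet" or not missing_vars:
        risk = HIGH if met_points >= model.high_risk_cutoff else LOW
    elif met_points >= model.high_risk_cutoff:
        risk = HIGH  # guaranteed even if all missing criteria are unmet
    elif met_points + missing_points < model.high_risk_cutoff:
        risk = LOW  # guaranteed even if all missing criteria are met
    else:
        risk = INDETERMINATE
    return ScoreResult(model=model.name, total_points=met_points,
                       satisfied=satisfied, risk_class=risk,
                       missing_variables=missing_vars)


def apply_kawamura(patient: PatientRecord,
                   rule: Optional[CombinationRuleModel] = None) -> ScoreResult:
    """Classify a patient under the NLR/PLR combination rule.

    Patients whose lymphocyte (or companion) counts are missing cannot
    have the ratios derived; under the default policy they come out
    ``indeterminate`` unless the observed ratio already settles the
    outcome (e.g. PLR below threshold settles ``both_required`` as low).
    """
    rule = rule or CombinationRuleModel()
    nlr, plr = derive_ratios(patient.labs)
    satisfied: list[str] = []
    missing_vars: list[str] = []
    states = {}
    for name, value, threshold in (("nlr", nlr, rule.nlr_threshold),
                                   ("plr", plr, rule.plr_threshold)):
        if value is None:
            states[name] = MISSING
            missing_vars.append(name)
        elif value >= threshold:
            states[name] = MET
            satisfied.append(f"{name}>={threshold:g}")
        else:
            states[name] = UNMET

    met = sum(s == MET for s in states.values())
    unmet = sum(s == UNMET for s in states.values())
    if rule.missing_policy == "treat_as_unmet":
        high = met == 2 if rule.combination == BOTH_REQUIRED else met >= 1
        risk = HIGH if high else LOW
    elif rule.combination == BOTH_REQUIRED:
        if met == 2:
            risk = HIGH
        elif unmet >= 1:
            risk = LOW
        else:
            risk = INDETERMINATE
    else:  # either_sufficient
        if met >= 1:
            risk = HIGH
        elif unmet == 2:
            risk = LOW
        else:
            risk = INDETERMINATE
    return ScoreResult(model=rule.name, total_points=None, satisfied=satisfied,
                       risk_class=risk, missing_variables=missing_vars)


def score_patient(model: AnyModel, patient: PatientRecord) -> ScoreResult:
    """Dispatch to the point-model or combination-rule evaluator."""
    if isinstance(model, CombinationRuleModel):
        return apply_kawamura(patient, model)
    return apply_point_model(model, patient)


def builtin_models(kobayashi_cutoff: int = 3,
                   kawamura_combination: str = BOTH_REQUIRED,
                   missing_policy: str = INDETERMINATE) -> dict[str, AnyModel]:
    """Registry of the six built-in prediction models.

    Thresholds are expressed in canonical units (CRP mg/L, TB µmol/L,
    PLT 10^9/L).  The Kobayashi high-risk cutoff defaults to 3 but the
    original publication's cutoff of 4 can be selected.
    """
    C = ScoreCriterion
    models: dict[str, AnyModel] = {
        "kobayashi": RiskScoreModel("kobayashi", (
            C("age_months", "<=", 12, 1),
            C("illness_day_at_treatment", "<=", 4, 2),
            C("crp", ">=", 100.0, 1),          # 10 mg/dL
            C("ast", ">=", 100.0, 2),
            C("plt", "<=", 300.0, 1),
            C("na", "<=", 133.0, 2),
            C("neut_pct", ">=", 80.0, 2),
        ), kobayashi_cutoff, missing_policy),
        "egami": RiskScoreModel("egami", (
            C("age_months", "<=", 6, 1),
            C("illness_day_at_treatment", "<=", 4, 1),
            C("crp", ">=", 80.0, 1),           # 8 mg/dL
            C("alt", ">=", 80.0, 2),
            C("plt", "<", 300.0, 1),
        ), 3, missing_policy),
        "sano": RiskScoreModel("sano", (
            C("crp", ">=", 70.0, 1),           # 7 mg/dL
            C("tb", ">=", round(0.9 * TB_UMOL_PER_MG_DL, 3), 1),  # 0.9 mg/dL
            C("ast", ">=", 200.0, 1),
        ), 2, missing_policy),
        "formosa": RiskScoreModel("formosa", (
            C("cervical_lymphadenopathy", "is_present", None, 1),
            C("neut_pct", ">=", 60.0, 2),
            C("alb", "<", 35.0, 1),
        ), 3, missing_policy),
        "ours": RiskScoreModel("ours", (
            C("age_months", "<", 6, 2),
            C("rash", "is_present", None, 1),
            C("edema_extremities", "is_present", None, 1),
            C("neut_pct", ">=", 80.0, 1),
            C("alb", "<", 35.0, 2),
        ), 3, missing_policy),
        "kawamura": CombinationRuleModel(combination=kawamura_combination,
                                         missing_policy=missing_policy),
    }
    return models


MODEL_ORDER = ("kobayashi", "egami", "kawamura", "sano", "formosa", "ours")


# ---------------------------------------------------------------------------
# YAML/JSON (de)serialization of user-defined models


def model_to_dict(model: AnyModel) -> dict:
    if isinstance(model, CombinationRuleModel):
        return {"name": model.name, "kind": "combination",
                "nlr_threshold": model.nlr_threshold,
                "plr_threshold": model.plr_threshold,
                "combination": model.combination,
                "missing_policy": model.missing_policy}
    return {"name": model.name, "kind": "points",
            "high_risk_cutoff": model.high_risk_cutoff,
            "missing_policy": model.missing_policy,
            "criteria": [{"variable": c.variable, "comparator": c.comparator,
                          "threshold": c.threshold, "points": c.points}
                         for c in model.criteria]}


def model_from_dict(doc: dict) -> AnyModel:
    kind = doc.get("kind", "points")
    if kind == "combination":
        return CombinationRuleModel(
            name=doc.get("name", "kawamura"),
            nlr_threshold=float(doc.get("nlr_threshold", 3.83)),
            plr_threshold=float(doc.get("plr_threshold", 150.0)),
            combination=doc.get("combination", BOTH_REQUIRED),
            missing_policy=doc.get("missing_policy", INDETERMINATE))
    crits = tuple(ScoreCriterion(d["variable"], d["comparator"],
                                 d.get("threshold"), int(d.get("points", 1)))
                  for d in doc["criteria"])
    return RiskScoreModel(doc["name"], crits, int(doc["high_risk_cutoff"]),
                          doc.get("missing_policy", INDETERMINATE))


def dump_models(models: Sequence[AnyModel]) -> str:
    """Serialize models to a YAML document."""
    return yaml.safe_dump([model_to_dict(m) for m in models], sort_keys=False)


def load_models(text: str) -> list[AnyModel]:
    """Load models from a YAML document produced by :func:`dump_models`."""
    return [model_from_dict(d) for d in (yaml.safe_load(text) or [])]
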