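"""Model parameters: epidemiology, unit costs, and config file handling.

The base case describes a hypothetical one-million-member US health plan.
A 3 %/year incidence of a major depressive episode and a 50 % help-seeking
rate yield 15,000 new MDD diagnoses per year, of which a fraction
``ubp_prevalence`` are unrecognised bipolar-disorder patients (UBP).
Misdiagnosed patients have an annual probability ``annual_correction`` of
reaching their correct diagnosis without screening, and all patients leave
the plan at the all-cause ``attrition`` rate. Annual direct costs per
diagnostic state, the one-time screening and psychiatric-evaluation costs,
and the discount rate are held in :class:`CostParams` (2021 USD).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "EpidemiologyParams",
    "CostParams",
    "ModelParams",
    "target_population",
    "inflation_adjust",
    "load_params",
    "save_params",
    "apply_overrides",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Person counts are carried as exact reals internally and rounded only at
    presentation; this is the single rounding rule used throughout.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot round non-finite value {x!r}")
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


class EpidemiologyParams(BaseModel):
    """Population, prevalence, and transition-probability inputs."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    plan_size: float = Field(default=1_000_000.0, gt=0, allow_inf_nan=False,
                             description="health-plan membership, persons")
    mde_incidence: float = Field(default=0.03, ge=0, le=1,
                                 description="one-year incidence of a major depressive episode")
    help_seeking: float = Field(default=0.50, ge=0, le=1,
                                description="fraction of affected individuals who visit a physician")
    ubp_prevalence: float = Field(default=0.16, ge=0, le=1,
                                  description="fraction of new MDD diagnoses that are unrecognised BD")
    annual_correction: float = Field(default=0.15, ge=0, le=1,
                                     description="yearly probability incorrect -> correct diagnosis")
    attrition: float = Field(default=0.106, ge=0, le=1,
                             description="yearly all-cause plan disenrolment probability")
    referral_prob: float = Field(default=0.75, ge=0, le=1,
                                 description="probability a screen-positive visits a psychiatrist")
    psych_accuracy: float = Field(default=1.0, ge=0, le=1,
                                  description="probability the psychiatrist assigns the true diagnosis")
    horizon: int = Field(default=5, ge=1, description="follow-up horizon, years")

    @property
    def cohort_size(self) -> float:
        """Exact (unrounded) size of the yearly new-MDD cohort N0."""
        n0 = self.plan_size * self.mde_incidence * self.help_seeking
        if n0 <= 0:
            raise ValueError("derived cohort size must be positive")
        return n0


class CostParams(BaseModel):
    """Annual state costs, one-time costs, and discounting (2021 USD)."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    c_mdd: float = Field(default=11_760.0, ge=0, description="USD/year, correctly diagnosed MDD")
    c_rbp: float = Field(default=16_092.0, ge=0, description="USD/year, recognised BD")
    c_ubp: float = Field(default=23_696.0, ge=0, description="USD/year, unrecognised BD")
    # None means "track c_ubp", the model's stated base-case assumption for
    # MDD patients mislabelled as BD after an unconfirmed positive screen.
    c_mdd_as_bd: float | None = Field(default=None, ge=0,
                                      description="USD/year, MDD mislabelled as BD (default: equals c_ubp)")
    c_screen: float = Field(default=15.0, ge=0, description="USD one-time per screened person")
    c_eval: float = Field(default=230.0, ge=0, description="USD one-time per psychiatric evaluation")
    discount: float = Field(default=0.03, ge=0, description="annual discount rate")
    currency_year: int = Field(default=2021, description="calendar year of the cost basis")

    @property
    def mdd_as_bd_cost(self) -> float:
        """Effective annual cost of MDD-mislabelled-as-BD."""
        return self.c_ubp if self.c_mdd_as_bd is None else self.c_mdd_as_bd


class ModelParams(BaseModel):
    """Complete, validated parameter set for one model run."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    epi: EpidemiologyParams = Field(default_factory=EpidemiologyParams)
    costs: CostParams = Field(default_factory=CostParams)


def target_population(plan_size: float, mde_incidence: float, help_seeking: float) -> int:
    """Yearly number of plan members newly diagnosed with MDD.

    ``plan_size x mde_incidence x help_seeking`` rounded to the nearest
    whole person; the base case gives 1,000,000 x 0.03 x 0.50 = 15,000.
    """
    for name, value, upper in (("plan_size", plan_size, None),
                               ("mde_incidence", mde_incidence, 1.0),
                               ("help_seeking", help_seeking, 1.0)):
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")
        if upper is not None and value > upper:
            raise ValueError(f"{name} must be <= 1, got {value!r}")
    return round_half_up(plan_size * mde_incidence * help_seeking)


def inflation_adjust(cost: float, factor: float) -> int:
    """Re-express a historical cost in reference-year dollars.

    The multiplier is user-supplied (e.g. a CPI ratio); the result is
    rounded to the nearest dollar.
    """
    if not math.isfinite(cost) or cost < 0:
        raise ValueError(f"cost must be non-negative and finite, got {cost!r}")
    if not math.isfinite(factor) or factor <= 0:
        raise ValueError(f"factor must be positive and finite, got {factor!r}")
    return round_half_up(cost * factor)


def load_params(path: str | Path) -> ModelParams:
    """Load a parameter configuration from a YAML/JSON file.

    Absent fields fall back to the base case; unknown keys and
    out-of-range values are rejected with an error naming the field.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return ModelParams.model_validate(raw)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Serialise a parameter set to YAML; ``save(load(f))`` round-trips."""
    Path(path).write_text(
        yaml.safe_dump(params.model_dump(), sort_keys=True, default_flow_style=False)
    )


def _set_dotted(tree: dict[str, Any], dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = tree
    for part in parts[:-1]:
        node = node.setdefault(part, {})
        if not isinstance(node, dict):
            raise ValueError(f"cannot descend into scalar at {part!r} in {dotted!r}")
    node[parts[-1]] = value


def apply_overrides(params: ModelParams, overrides: dict[str, Any]) -> ModelParams:
    """Return a new ModelParams with dotted-path overrides applied.

    ``apply_overrides(p, {"epi.ubp_prevalence": 0.11})`` changes exactly
    that field; unknown paths fail validation.
    """
    tree = params.model_dump()
    for key, value in overrides.items():
        _set_dotted(tree, key, value)
    return ModelParams.model_validate(tree)
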