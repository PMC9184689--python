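"""One-way sensitivity analysis over the model's core assumptions.

Each variant perturbs exactly the named parameter(s), reruns both the
no-screening and screening scenarios, and reports the discounted
per-patient costs and the savings. The built-in plan reproduces the
published table: low/high UBP prevalence, the operating point's
confidence bounds, joint 50 %/150 % scalings of the state costs, setting
the MDD cost equal to the RBP cost, and low/high values for the annual
correction and psychiatric-referral probabilities.

Because ``c_mdd_as_bd`` is defined as equal to ``c_ubp`` unless
explicitly overridden, it follows ``c_ubp`` automatically through every
cost-scaling variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .cohort import run_no_screening, run_screening
from .params import ModelParams, apply_overrides

__all__ = ["VariantSpec", "SensitivityRow", "one_way_sensitivity",
           "builtin_table_plan", "rows_to_frame"]


@dataclass(frozen=True)
class VariantSpec:
    """One perturbation: parameter overrides and/or an operating point."""

    parameter: str                       # block label, e.g. "Prevalence of UBP"
    variant: str                         # e.g. "low (11%)"
    overrides: dict[str, Any] = field(default_factory=dict)   # dotted paths
    operating_point: tuple[float, float] | None = None        # (sens, spec)


@dataclass(frozen=True)
class SensitivityRow:
    parameter: str
    variant: str
    overrides: dict[str, Any]
    no_screen_pp: float
    screen_pp: float

    @property
    def savings_pp(self) -> float:
        return self.no_screen_pp - self.screen_pp


def one_way_sensitivity(params: ModelParams, sens: float, spec: float,
                        plan) -> list[SensitivityRow]:
    """Rerun both scenarios once per variant, base case restored between rows."""
    rows = []
    for variant in plan:
        perturbed = apply_overrides(params, variant.overrides)
        op = variant.operating_point if variant.operating_point is not None else (sens, spec)
        rows.append(SensitivityRow(
            parameter=variant.parameter,
            variant=variant.variant,
            overrides=dict(variant.overrides),
            no_screen_pp=run_no_screening(perturbed).per_patient_cost,
            screen_pp=run_screening(perturbed, *op).per_patient_cost,
        ))
    return rows


def builtin_table_plan(params: ModelParams) -> list[VariantSpec]:
    """The 13-variant published sensitivity plan, scaled from ``params``.

    Cost blocks scale both named unit costs jointly by 50 % or 150 %; the
    "RBP = MDD" variant sets the MDD cost to the (base) RBP cost.
    """
    c = params.costs
    return [
        VariantSpec("Prevalence of UBP in new MDD cases", "low (11%)",
                    {"epi.ubp_prevalence": 0.11}),
        VariantSpec("Prevalence of UBP in new MDD cases", "high (21%)",
                    {"epi.ubp_prevalence": 0.21}),
        VariantSpec("Sensitivity & specificity", "low sens, high spec (0.58, 0.97)",
                    operating_point=(0.58, 0.97)),
        VariantSpec("Sensitivity & specificity", "high sens, low spec (0.92, 0.75)",
                    operating_point=(0.92, 0.75)),
        VariantSpec("Cost of RBP relative to UBP", "high (150%)",
                    {"costs.c_rbp": c.c_rbp * 1.5, "costs.c_ubp": c.c_ubp * 1.5}),
        VariantSpec("Cost of RBP relative to UBP", "low (50%)",
                    {"costs.c_rbp": c.c_rbp * 0.5, "costs.c_ubp": c.c_ubp * 0.5}),
        VariantSpec("Cost of MDD relative to UBP", "high (150%)",
                    {"costs.c_mdd": c.c_mdd * 1.5, "costs.c_ubp": c.c_ubp * 1.5}),
        VariantSpec("Cost of MDD relative to UBP", "low (50%)",
                    {"costs.c_mdd": c.c_mdd * 0.5, "costs.c_ubp": c.c_ubp * 0.5}),
        VariantSpec("Cost of RBP relative to MDD", "RBP = MDD",
                    {"costs.c_mdd": c.c_rbp}),
        VariantSpec("Annual probability of diagnosis correction", "low (10%)",
                    {"epi.annual_correction": 0.10}),
        VariantSpec("Annual probability of diagnosis correction", "high (20%)",
                    {"epi.annual_correction": 0.20}),
        VariantSpec("Probability of psychiatric evaluation", "low (50%)",
                    {"epi.referral_prob": 0.50}),
        VariantSpec("Probability of psychiatric evaluation", "high (100%)",
                    {"epi.referral_prob": 1.00}),
    ]


def rows_to_frame(rows) -> pd.DataFrame:
    """Tabulate sensitivity rows (parameter, variant, costs, savings)."""
    return pd.DataFrame([{"parameter": r.parameter, "variant": r.variant,
                          "no_screening": r.no_screen_pp,
                          "screening": r.screen_pp,
                          "savings": r.savings_pp} for r in rows])
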