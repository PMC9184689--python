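"""Cutoff sweeps, optimal operating points, and scenario/test comparison.

The cost-minimising and misdiagnosis-minimising cutoffs are located by
exhaustive evaluation over the discrete cutoffs of the supplied operating
point table; ties break toward the lower cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import ppv_npv
from .cohort import CohortTrajectory, run_no_screening, run_screening
from .params import ModelParams
from .synthetic import TestProfile

__all__ = ["SweepResult", "ScenarioComparison", "sweep_cutoffs",
           "compare_scenarios", "compare_tests"]


@dataclass(frozen=True)
class SweepResult:
    """Scenario outcomes at every cutoff of one test profile."""

    profile_name: str
    records: pd.DataFrame        # cutoff, per_patient_cost, total_cost, misdiagnosed_end, correct_end
    best_cost_cutoff: float      # minimises per_patient_cost
    best_accuracy_cutoff: float  # minimises misdiagnosed_end


@dataclass(frozen=True)
class ScenarioComparison:
    """Screening at one cutoff versus the no-screening reference."""

    reference: CohortTrajectory
    comparator: CohortTrajectory
    savings_total: float
    savings_per_patient: float
    additional_correct: float
    cost_by_state_delta: dict[str, float]


def sweep_cutoffs(params: ModelParams, profile: TestProfile) -> SweepResult:
    """Evaluate the screening scenario at every cutoff of the profile."""
    rows = []
    for pt in profile.points:
        traj = run_screening(params, pt.sensitivity, pt.specificity)
        rows.append((pt.cutoff, traj.per_patient_cost, traj.total_discounted_cost,
                     traj.misdiagnosed_end, traj.correct_end))
    records = pd.DataFrame(rows, columns=["cutoff", "per_patient_cost", "total_cost",
                                          "misdiagnosed_end", "correct_end"])
    # idxmin returns the first minimum; cutoffs ascend, so ties go low
    best_cost = float(records.loc[records["per_patient_cost"].idxmin(), "cutoff"])
    best_acc = float(records.loc[records["misdiagnosed_end"].idxmin(), "cutoff"])
    return SweepResult(profile_name=profile.name, records=records,
                       best_cost_cutoff=best_cost, best_accuracy_cutoff=best_acc)


def compare_scenarios(params: ModelParams, profile: TestProfile,
                      cutoff: float) -> ScenarioComparison:
    """Compare screening at one cutoff of the profile with no screening."""
    pt = profile.lookup(cutoff)
    reference = run_no_screening(params)
    comparator = run_screening(params, pt.sensitivity, pt.specificity)
    delta = {k: comparator.cost_by_state[k] - reference.cost_by_state[k]
             for k in reference.cost_by_state}
    return ScenarioComparison(
        reference=reference,
        comparator=comparator,
        savings_total=reference.total_discounted_cost - comparator.total_discounted_cost,
        savings_per_patient=reference.per_patient_cost - comparator.per_patient_cost,
        additional_correct=comparator.correct_end - reference.correct_end,
        cost_by_state_delta=delta,
    )


def compare_tests(params: ModelParams, profiles) -> pd.DataFrame:
    """One comparison row per (profile, optimisation criterion).

    Columns mirror the screening-test comparison table: tool, cutoff,
    optimisation, sensitivity, specificity, PPV, NPV, per-person cost and
    year-5 misdiagnoses. When the cost and accuracy optima coincide a
    single row labelled ``costs & misdiagnoses`` is emitted.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile is required")
    p = params.epi.ubp_prevalence
    rows = []
    for profile in profiles:
        sweep = sweep_cutoffs(params, profile)
        if np.isclose(sweep.best_cost_cutoff, sweep.best_accuracy_cutoff):
            optima = [(sweep.best_cost_cutoff, "costs & misdiagnoses")]
        else:
            optima = [(sweep.best_accuracy_cutoff, "misdiagnoses"),
                      (sweep.best_cost_cutoff, "costs")]
        for cutoff, label in optima:
            pt = profile.lookup(cutoff)
            traj = run_screening(params, pt.sensitivity, pt.specificity)
            ppv, npv = ppv_npv(pt.sensitivity, pt.specificity, p)
            rows.append({"tool": profile.name, "cutoff": cutoff,
                         "optimisation": label,
                         "sensitivity": pt.sensitivity, "specificity": pt.specificity,
                         "ppv": ppv, "npv": npv,
                         "per_person_cost": traj.per_patient_cost,
                         "misdiagnoses_y5": traj.misdiagnosed_end})
    return pd.DataFrame(rows)
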