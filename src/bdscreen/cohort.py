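"""Five-year cohort propagation with correction, attrition and discounting.

The cohort occupies four diagnostic states: correctly diagnosed MDD,
recognised BD (RBP), unrecognised BD (UBP), and MDD mislabelled as BD.
Within each model year the order of events is fixed:

1. diagnosis correction at the year start — a fraction q of UBP moves to
   RBP and a fraction q of MDD-as-BD moves back to MDD;
2. the year's state costs accrue for the post-correction distribution;
3. the year's cost is discounted by (1 + r)^-(t-1), so year 1 is
   undiscounted;
4. attrition shrinks every state by (1 - a) at the year boundary, i.e.
   T - 1 times over a T-year horizon. Disenrolled patients stop
   accumulating costs.

Corrected patients never revert, and patients misdiagnosed in either
direction are corrected at the same annual rate. One-time screening and
evaluation costs are incurred at time zero and are not discounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import apply_cascade
from .params import ModelParams

__all__ = [
    "YearRecord",
    "CohortTrajectory",
    "run_no_screening",
    "run_screening",
    "closed_form_no_screening_cost",
    "simulate_microcohort",
]

STATE_MDD, STATE_RBP, STATE_UBP, STATE_MAB = 0, 1, 2, 3


@dataclass(frozen=True)
class YearRecord:
    """One model year's state counts and cost ledger entry."""

    year: int                 # 1-based
    n_alive: float            # persons enrolled at the start of year t
    mdd: float                # state counts after that year's correction
    rbp: float
    ubp: float
    mdd_as_bd: float
    undiscounted_cost: float
    discount_factor: float    # (1 + r)^-(t-1)
    discounted_cost: float


@dataclass(frozen=True)
class CohortTrajectory:
    """Per-year ledger and end-of-horizon summary for one scenario."""

    scenario: str
    years: tuple[YearRecord, ...]
    one_time_cost: float
    total_discounted_cost: float
    per_patient_cost: float
    survivors_end: float
    correct_end: float
    misdiagnosed_end: float
    cost_by_state: dict[str, float]   # discounted USD per patient: mdd, rbp, misdiagnosis


def _propagate(params: ModelParams, scenario: str, mdd: float, rbp: float,
               ubp: float, mab: float, one_time_cost: float) -> CohortTrajectory:
    epi, costs = params.epi, params.costs
    q = epi.annual_correction
    a = epi.attrition
    r = costs.discount
    horizon = epi.horizon
    n0 = mdd + rbp + ubp + mab
    c_mab = costs.mdd_as_bd_cost

    years: list[YearRecord] = []
    by_state = {"mdd": 0.0, "rbp": 0.0, "misdiagnosis": 0.0}
    total = one_time_cost
    for t in range(1, horizon + 1):
        moved = ubp * q
        rbp += moved
        ubp -= moved
        moved = mab * q
        mdd += moved
        mab -= moved

        df = (1.0 + r) ** -(t - 1)
        cost_mdd = mdd * costs.c_mdd
        cost_rbp = rbp * costs.c_rbp
        cost_mis = ubp * costs.c_ubp + mab * c_mab
        undisc = cost_mdd + cost_rbp + cost_mis

        years.append(YearRecord(year=t, n_alive=mdd + rbp + ubp + mab,
                                mdd=mdd, rbp=rbp, ubp=ubp, mdd_as_bd=mab,
                                undiscounted_cost=undisc, discount_factor=df,
                                discounted_cost=undisc * df))
        total += undisc * df
        by_state["mdd"] += cost_mdd * df
        by_state["rbp"] += cost_rbp * df
        by_state["misdiagnosis"] += cost_mis * df

        if t < horizon:
            keep = 1.0 - a
            mdd *= keep
            rbp *= keep
            ubp *= keep
            mab *= keep

    return CohortTrajectory(
        scenario=scenario,
        years=tuple(years),
        one_time_cost=one_time_cost,
        total_discounted_cost=total,
        per_patient_cost=total / n0,
        survivors_end=mdd + rbp + ubp + mab,
        correct_end=mdd + rbp,
        misdiagnosed_end=ubp + mab,
        cost_by_state={k: v / n0 for k, v in by_state.items()},
    )


def run_no_screening(params: ModelParams) -> CohortTrajectory:
    """Propagate the unscreened cohort: N0(1-p) correct MDD, N0 p UBP."""
    n0 = params.epi.cohort_size
    p = params.epi.ubp_prevalence
    return _propagate(params, "no-screening",
                      mdd=n0 * (1.0 - p), rbp=0.0, ubp=n0 * p, mab=0.0,
                      one_time_cost=0.0)


def run_screening(params: ModelParams, sens: float, spec: float) -> CohortTrajectory:
    """Propagate the cohort after a one-time screen at (sens, spec)."""
    outcome = apply_cascade(params, sens, spec)
    return _propagate(params, f"screening({sens:g},{spec:g})",
                      mdd=outcome.mdd0, rbp=outcome.rbp0,
                      ubp=outcome.ubp0, mab=outcome.mdd_as_bd0,
                      one_time_cost=outcome.one_time_cost_total)


def closed_form_no_screening_cost(params: ModelParams) -> float:
    """Analytic per-patient discounted cost of the no-screening scenario.

    With rho = (1 - a)/(1 + r), correction applied at every year start
    (so the surviving-UBP fraction in year t is (1-q)^t):

        sum_{t=1..T} rho^(t-1) [ (1-p) c_mdd + p (1-q)^t c_ubp
                                 + p (1 - (1-q)^t) c_rbp ]

    Must match ``run_no_screening(...).per_patient_cost`` to 1e-9 relative.
    """
    epi, costs = params.epi, params.costs
    p, q = epi.ubp_prevalence, epi.annual_correction
    rho = (1.0 - epi.attrition) / (1.0 + costs.discount)
    total = 0.0
    for t in range(1, epi.horizon + 1):
        stay = (1.0 - q) ** t
        total += rho ** (t - 1) * ((1.0 - p) * costs.c_mdd
                                   + p * stay * costs.c_ubp
                                   + p * (1.0 - stay) * costs.c_rbp)
    return total


def simulate_microcohort(params: ModelParams, sens: float | None, spec: float | None,
                         n_patients: int, seed: int,
                         return_patient_costs: bool = False):
    """Individual-level stochastic counterpart of the cohort engine.

    Each of ``n_patients`` simulated patients draws their true diagnosis,
    screening result, referral, yearly correction and disenrolment as
    independent Bernoulli events; costs aggregate to the same
    :class:`CohortTrajectory` shape. Identical seeds give identical
    output. Pass ``sens=spec=None`` for the no-screening scenario.

    With ``return_patient_costs=True`` also returns the per-patient
    discounted cost vector (for Monte-Carlo error estimates).
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients!r}")
    if (sens is None) != (spec is None):
        raise ValueError("sens and spec must both be given or both be None")
    epi, costs = params.epi, params.costs
    rng = np.random.default_rng(seed)
    n = n_patients

    is_bd = rng.random(n) < epi.ubp_prevalence
    state = np.where(is_bd, STATE_UBP, STATE_MDD).astype(np.int8)

    one_time = 0.0
    if sens is not None:
        u = rng.random(n)
        positive = np.where(is_bd, u < sens, u < (1.0 - spec))
        referred = positive & (rng.random(n) < epi.referral_prob)
        truth_assigned = referred & (rng.random(n) < epi.psych_accuracy)
        # positives carry a BD label unless a psychiatrist overrides it
        state[positive & is_bd] = STATE_RBP
        state[positive & ~is_bd] = STATE_MAB
        state[truth_assigned & is_bd] = STATE_RBP
        state[truth_assigned & ~is_bd] = STATE_MDD
        wrong = referred & ~truth_assigned
        state[wrong & is_bd] = STATE_UBP
        state[wrong & ~is_bd] = STATE_MAB
        one_time = n * costs.c_screen + int(referred.sum()) * costs.c_eval

    unit_cost = np.array([costs.c_mdd, costs.c_rbp, costs.c_ubp, costs.mdd_as_bd_cost])
    active = np.ones(n, dtype=bool)
    patient_cost = np.full(n, one_time / n)
    total = one_time
    by_state = {"mdd": 0.0, "rbp": 0.0, "misdiagnosis": 0.0}
    years: list[YearRecord] = []
    for t in range(1, epi.horizon + 1):
        corr = rng.random(n) < epi.annual_correction
        state[active & corr & (state == STATE_UBP)] = STATE_RBP
        state[active & corr & (state == STATE_MAB)] = STATE_MDD

        df = (1.0 + costs.discount) ** -(t - 1)
        counts = np.bincount(state[active], minlength=4).astype(float)
        undisc = float(counts @ unit_cost)
        years.append(YearRecord(year=t, n_alive=float(active.sum()),
                                mdd=counts[STATE_MDD], rbp=counts[STATE_RBP],
                                ubp=counts[STATE_UBP], mdd_as_bd=counts[STATE_MAB],
                                undiscounted_cost=undisc, discount_factor=df,
                                discounted_cost=undisc * df))
        total += undisc * df
        by_state["mdd"] += counts[STATE_MDD] * unit_cost[STATE_MDD] * df
        by_state["rbp"] += counts[STATE_RBP] * unit_cost[STATE_RBP] * df
        by_state["misdiagnosis"] += (counts[STATE_UBP] * unit_cost[STATE_UBP]
                                     + counts[STATE_MAB] * unit_cost[STATE_MAB]) * df
        patient_cost[active] += unit_cost[state[active]] * df

        if t < epi.horizon:
            active &= rng.random(n) >= epi.attrition

    last = years[-1]
    label = "micro-no-screening" if sens is None else f"micro-screening({sens:g},{spec:g})"
    trajectory = CohortTrajectory(
        scenario=label,
        years=tuple(years),
        one_time_cost=one_time,
        total_discounted_cost=total,
        per_patient_cost=total / n,
        survivors_end=last.n_alive,
        correct_end=last.mdd + last.rbp,
        misdiagnosed_end=last.ubp + last.mdd_as_bd,
        cost_by_state={k: v / n for k, v in by_state.items()},
    )
    if return_patient_costs:
        return trajectory, patient_cost
    return trajectory
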