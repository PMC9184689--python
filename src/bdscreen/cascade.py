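"""The screening cascade: from one operating point to a post-screen cohort.

All N0 patients are screened once at entry. Screen-positives carry a BD
label; a fraction ``referral_prob`` of them see a psychiatrist who assigns
the true diagnosis with probability ``psych_accuracy``. Referred false
positives are therefore returned to MDD, while unreferred false positives
keep the incorrect BD label (state MDD-as-BD, costed at the UBP rate).
True positives end up recognised BD whether referred (confirmed) or not
(the screen label happens to be correct). False negatives remain
unrecognised BD and true negatives remain correctly diagnosed MDD.

Counts are expectations carried as real numbers; the stochastic
counterpart lives in :func:`bdscreen.cohort.simulate_microcohort`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParams

__all__ = ["ScreenOutcome", "confusion_counts", "ppv_npv", "apply_cascade"]


@dataclass(frozen=True)
class ScreenOutcome:
    """Confusion counts, evaluation volume, one-time costs and the
    post-screen diagnostic-state distribution."""

    tp: float
    fp: float
    fn: float
    tn: float
    n_evaluated: float
    one_time_cost_total: float
    rbp0: float
    ubp0: float
    mdd_as_bd0: float
    mdd0: float


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def confusion_counts(n0: float, p: float, sens: float,
                     spec: float) -> tuple[float, float, float, float]:
    """Expected (tp, fp, fn, tn) when n0 patients with UBP prevalence p
    are screened at an operating point (sens, spec)."""
    if n0 <= 0:
        raise ValueError(f"n0 must be positive, got {n0!r}")
    for name, value in (("p", p), ("sens", sens), ("spec", spec)):
        _check_fraction(name, value)
    tp = n0 * p * sens
    fn = n0 * p * (1.0 - sens)
    fp = n0 * (1.0 - p) * (1.0 - spec)
    tn = n0 * (1.0 - p) * spec
    return tp, fp, fn, tn


def ppv_npv(sens: float, spec: float, p: float) -> tuple[float, float]:
    """Positive and negative predictive values at prevalence p."""
    for name, value in (("sens", sens), ("spec", spec), ("p", p)):
        _check_fraction(name, value)
    pos = p * sens + (1.0 - p) * (1.0 - spec)
    neg = (1.0 - p) * spec + p * (1.0 - sens)
    if pos == 0.0:
        raise ZeroDivisionError("PPV undefined: the test makes no positive calls")
    if neg == 0.0:
        raise ZeroDivisionError("NPV undefined: the test makes no negative calls")
    return p * sens / pos, (1.0 - p) * spec / neg


def apply_cascade(params: ModelParams, sens: float, spec: float) -> ScreenOutcome:
    """Run the one-time screen-and-refer cascade at an operating point."""
    epi, costs = params.epi, params.costs
    n0 = epi.cohort_size
    tp, fp, fn, tn = confusion_counts(n0, epi.ubp_prevalence, sens, spec)

    pi = epi.referral_prob
    acc = epi.psych_accuracy
    # a referred positive receives the true diagnosis with probability acc
    # and the wrong one otherwise; unreferred positives keep the BD label
    rbp0 = tp * (1.0 - pi) + tp * pi * acc
    ubp0 = fn + tp * pi * (1.0 - acc)
    mdd0 = tn + fp * pi * acc
    mdd_as_bd0 = fp * (1.0 - pi) + fp * pi * (1.0 - acc)

    n_evaluated = pi * (tp + fp)
    one_time = n0 * costs.c_screen + n_evaluated * costs.c_eval
    return ScreenOutcome(tp=tp, fp=fp, fn=fn, tn=tn,
                         n_evaluated=n_evaluated, one_time_cost_total=one_time,
                         rbp0=rbp0, ubp0=ubp0, mdd_as_bd0=mdd_as_bd0, mdd0=mdd0)
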