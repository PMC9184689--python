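"""Decision curve analysis: net benefit across threshold probabilities.

Net benefit at a threshold probability pt weighs true positives against
false positives at the exchange rate implied by pt:

    NB(pt) = sens * p - (1 - spec) * (1 - p) * pt / (1 - pt)

The model curve is compared with treat-all (sens = 1, spec = 0, i.e.
NB_all = p - (1 - p) pt/(1 - pt), which crosses zero at pt = p) and
treat-none (NB = 0). The screening model's score cutoff is read as a
predicted probability, so each threshold selects the profile row with the
nearest cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import TestProfile

__all__ = ["DecisionCurve", "net_benefit", "decision_curve", "default_threshold_grid"]


@dataclass(frozen=True)
class DecisionCurve:
    """Net benefit of model / treat-all / treat-none over a threshold grid."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "nb_model": self.nb_model,
                             "nb_all": self.nb_all, "nb_none": self.nb_none})


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(1, 100) / 100.0, 2)


def net_benefit(sens: float, spec: float, p: float, pt: float) -> float:
    """Per-patient net benefit of acting on positives at threshold pt."""
    if not 0.0 < pt < 1.0:
        raise ValueError(f"threshold probability must lie in (0, 1), got {pt!r}")
    return sens * p - (1.0 - spec) * (1.0 - p) * pt / (1.0 - pt)


def decision_curve(profile: TestProfile, p: float, thresholds=None) -> DecisionCurve:
    """Net benefit of the profile, treat-all and treat-none per threshold."""
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0.0) | (thresholds >= 1.0)):
        raise ValueError("all threshold probabilities must lie in (0, 1)")
    nb_model = np.empty_like(thresholds)
    nb_all = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        point = profile.nearest(pt)
        nb_model[i] = net_benefit(point.sensitivity, point.specificity, p, pt)
        nb_all[i] = net_benefit(1.0, 0.0, p, pt)
    return DecisionCurve(thresholds=thresholds, nb_model=nb_model,
                         nb_all=nb_all, nb_none=np.zeros_like(thresholds))
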