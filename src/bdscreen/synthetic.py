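"""Synthetic score populations and cutoff -> (sensitivity, specificity) tables.

The screening instruments enter the cohort model only through their
operating points. The published supplements tabulate those points for the
Delta algorithm (ROC AUC 0.92) and the MDQ, but the tables themselves are
not machine-readable here, so this module emulates them: scores follow an
equal-variance binormal model — controls ~ N(0, 1), cases ~ N(mu, 1) with
mu chosen to hit a target AUC — and operating-point tables with percentile
bootstrap confidence intervals are tabulated from a labelled sample.

Scores can be mapped to calibrated case probabilities (the posterior under
the generating binormal mixture), which puts cutoffs on the 0-1 axis the
published figures use and makes the profile directly usable for decision
curve analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "SyntheticPopulation",
    "OperatingPoint",
    "TestProfile",
    "binormal_separation",
    "binormal_auc",
    "generate_population",
    "profile_from_population",
    "synthetic_profile",
    "default_cutoff_grid",
    "read_profile_csv",
    "write_profile_csv",
]

_SQRT2 = np.sqrt(2.0)

PROFILE_COLUMNS = ["cutoff", "sensitivity", "specificity",
                   "sens_lo", "sens_hi", "spec_lo", "spec_hi"]


def binormal_separation(auc_target: float) -> float:
    """Case-mean shift mu giving the target AUC for unit-variance normals.

    For controls ~ N(0,1) and cases ~ N(mu,1), AUC = Phi(mu/sqrt(2)), so
    mu = sqrt(2) * Phi^-1(AUC).
    """
    if not 0.5 <= auc_target < 1.0:
        raise ValueError(f"auc_target must lie in [0.5, 1), got {auc_target!r}")
    return float(_SQRT2 * ndtri(auc_target))


def binormal_auc(mu: float) -> float:
    """AUC of the equal-variance binormal model with case-mean shift mu."""
    return float(ndtr(mu / _SQRT2))


@dataclass(frozen=True)
class SyntheticPopulation:
    """A labelled score sample from the binormal mixture."""

    labels: np.ndarray   # bool, True = case
    scores: np.ndarray   # float, same length
    seed: int
    auc_target: float
    prevalence: float

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.scores):
            raise ValueError("labels and scores must have equal length")
        n_case = int(self.labels.sum())
        if n_case == 0 or n_case == len(self.labels):
            raise ValueError("population must contain at least one case and one control")

    @property
    def case_scores(self) -> np.ndarray:
        return self.scores[self.labels]

    @property
    def control_scores(self) -> np.ndarray:
        return self.scores[~self.labels]

    def empirical_auc(self) -> float:
        """Mann-Whitney estimate of the AUC (ties counted half)."""
        controls = np.sort(self.control_scores)
        # for each case: number of controls below it, ties counted half
        ranks = (np.searchsorted(controls, self.case_scores, side="left")
                 + np.searchsorted(controls, self.case_scores, side="right")) / 2.0
        return float(np.mean(ranks) / len(controls))

    def calibrated(self) -> "SyntheticPopulation":
        """Map raw scores to posterior case probabilities P(case | score).

        Under the generating binormal mixture with this population's
        prevalence the posterior is a monotone logistic transform of the
        score, so ranking (and the ROC curve) is unchanged while cutoffs
        land on the (0, 1) probability axis.
        """
        mu = binormal_separation(self.auc_target)
        p = self.prevalence
        # log-likelihood ratio of case vs control for N(mu,1) vs N(0,1)
        llr = mu * self.scores - mu * mu / 2.0
        logit = llr + np.log(p / (1.0 - p))
        post = 1.0 / (1.0 + np.exp(-logit))
        return replace(self, scores=post)


@dataclass(frozen=True)
class OperatingPoint:
    """One cutoff of a screening test with its error rates."""

    cutoff: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float] | None = None
    spec_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        for name, point in (("sens_ci", self.sensitivity), ("spec_ci", self.specificity)):
            ci = getattr(self, name)
            if ci is not None and not (ci[0] <= point <= ci[1]):
                raise ValueError(f"{name} {ci} does not bracket the point estimate {point}")


@dataclass(frozen=True)
class TestProfile:
    """An ordered operating-point table for one screening test."""

    __test__ = False   # not a pytest collection target

    name: str
    points: tuple[OperatingPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        cutoffs = self.cutoffs
        if len(cutoffs) == 0:
            raise ValueError("profile must contain at least one operating point")
        if np.any(np.diff(cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")
        sens = np.array([pt.sensitivity for pt in self.points])
        spec = np.array([pt.specificity for pt in self.points])
        if np.any(np.diff(sens) > 1e-12):
            raise ValueError("sensitivity must be non-increasing in the cutoff")
        if np.any(np.diff(spec) < -1e-12):
            raise ValueError("specificity must be non-decreasing in the cutoff")

    @property
    def cutoffs(self) -> np.ndarray:
        return np.array([pt.cutoff for pt in self.points])

    def __len__(self) -> int:
        return len(self.points)

    def lookup(self, cutoff: float, atol: float = 1e-9) -> OperatingPoint:
        """The operating point at an exact cutoff value."""
        idx = np.nonzero(np.isclose(self.cutoffs, cutoff, rtol=0.0, atol=atol))[0]
        if len(idx) == 0:
            raise KeyError(f"cutoff {cutoff!r} not present in profile {self.name!r}")
        return self.points[int(idx[0])]

    def nearest(self, cutoff: float) -> OperatingPoint:
        """The operating point whose cutoff is closest (ties -> lower cutoff)."""
        return self.points[int(np.argmin(np.abs(self.cutoffs - cutoff)))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            sc = pt.sens_ci or (np.nan, np.nan)
            pc = pt.spec_ci or (np.nan, np.nan)
            rows.append((pt.cutoff, pt.sensitivity, pt.specificity, sc[0], sc[1], pc[0], pc[1]))
        return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def default_cutoff_grid() -> np.ndarray:
    """Cutoffs 0.01 ... 0.99 in steps of 0.01, matching the 0-1 score axis."""
    return np.round(np.arange(1, 100) / 100.0, 2)


def generate_population(n: int, prevalence: float, auc_target: float,
                        seed: int) -> SyntheticPopulation:
    """Draw a labelled binormal score sample.

    Labels are i.i.d. Bernoulli(prevalence); controls are drawn from
    N(0, 1) and cases from N(mu, 1) with mu = binormal_separation(auc).
    The same seed reproduces the sample exactly.
    """
    if n < 10:
        raise ValueError(f"n must be at least 10, got {n!r}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {prevalence!r}")
    mu = binormal_separation(auc_target)
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < prevalence
    scores = rng.standard_normal(n) + mu * labels
    if labels.all() or not labels.any():
        raise ValueError(
            f"degenerate draw: {int(labels.sum())} cases out of {n}; "
            "increase n or move prevalence away from the boundary")
    return SyntheticPopulation(labels=labels, scores=scores, seed=seed,
                               auc_target=auc_target, prevalence=prevalence)


def _sens_spec_at(case_scores: np.ndarray, control_scores: np.ndarray,
                  cutoffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # positive call: score >= cutoff (ties positive)
    cases = np.sort(case_scores)
    controls = np.sort(control_scores)
    sens = 1.0 - np.searchsorted(cases, cutoffs, side="left") / len(cases)
    spec = np.searchsorted(controls, cutoffs, side="left") / len(controls)
    return sens, spec


def profile_from_population(pop: SyntheticPopulation, cutoffs,
                            n_boot: int = 0, seed: int | None = None,
                            name: str = "synthetic",
                            ci_level: float = 0.95) -> TestProfile:
    """Tabulate empirical operating points at the given cutoffs.

    Sensitivity at cutoff c is the fraction of case scores >= c and
    specificity the fraction of control scores < c. With ``n_boot`` > 0,
    percentile bootstrap CIs over resampled (label, score) pairs are
    attached; the bootstrap stream is seeded independently (``seed``
    defaults to a child of the population's seed).
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size == 0:
        raise ValueError("cutoffs must be non-empty")
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    if n_boot < 0:
        raise ValueError(f"n_boot must be >= 0, got {n_boot!r}")

    sens, spec = _sens_spec_at(pop.case_scores, pop.control_scores, cutoffs)

    sens_ci = spec_ci = None
    if n_boot > 0:
        boot_seed = seed if seed is not None else np.random.SeedSequence(pop.seed).spawn(1)[0]
        rng = np.random.default_rng(boot_seed)
        n = len(pop.scores)
        sens_b = np.empty((n_boot, cutoffs.size))
        spec_b = np.empty((n_boot, cutoffs.size))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            lab = pop.labels[idx]
            if lab.all() or not lab.any():   # resample lost a class; redraw
                sens_b[b] = sens
                spec_b[b] = spec
                continue
            sc = pop.scores[idx]
            sens_b[b], spec_b[b] = _sens_spec_at(sc[lab], sc[~lab], cutoffs)
        alpha = (1.0 - ci_level) / 2.0
        sens_ci = np.quantile(sens_b, [alpha, 1.0 - alpha], axis=0)
        spec_ci = np.quantile(spec_b, [alpha, 1.0 - alpha], axis=0)

    points = []
    for i, c in enumerate(cutoffs):
        points.append(OperatingPoint(
            cutoff=float(c),
            sensitivity=float(sens[i]),
            specificity=float(spec[i]),
            sens_ci=(float(min(sens_ci[0, i], sens[i])), float(max(sens_ci[1, i], sens[i])))
            if sens_ci is not None else None,
            spec_ci=(float(min(spec_ci[0, i], spec[i])), float(max(spec_ci[1, i], spec[i])))
            if spec_ci is not None else None,
        ))
    return TestProfile(name=name, points=tuple(points))


def synthetic_profile(auc_target: float, prevalence: float = 0.16,
                      n: int = 10_000, seed: int = 0, cutoffs=None,
                      n_boot: int = 0, name: str | None = None) -> TestProfile:
    """A ready-to-use probability-scale profile for a given test AUC.

    Generates a binormal population, maps scores to calibrated case
    probabilities and tabulates operating points on the 0-1 cutoff grid —
    the stand-in for a transcribed supplementary table.
    """
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    pop = generate_population(n, prevalence, auc_target, seed).calibrated()
    label = name if name is not None else f"synthetic-auc{auc_target:g}"
    return profile_from_population(pop, cutoffs, n_boot=n_boot, name=label)


def write_profile_csv(profile: TestProfile, path) -> None:
    """Write the operating-point table as CSV (the ingestion format)."""
    profile.to_frame().to_csv(path, index=False)


def read_profile_csv(path, name: str | None = None) -> TestProfile:
    """Read an operating-point table (cutoff, sensitivity, specificity[, CIs])."""
    df = pd.read_csv(path)
    missing = {"cutoff", "sensitivity", "specificity"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    has_ci = {"sens_lo", "sens_hi", "spec_lo", "spec_hi"} <= set(df.columns)
    points = []
    for row in df.itertuples(index=False):
        sens_ci = spec_ci = None
        if has_ci and np.isfinite(row.sens_lo):
            sens_ci = (float(row.sens_lo), float(row.sens_hi))
            spec_ci = (float(row.spec_lo), float(row.spec_hi))
        points.append(OperatingPoint(cutoff=float(row.cutoff),
                                     sensitivity=float(row.sensitivity),
                                     specificity=float(row.specificity),
                                     sens_ci=sens_ci, spec_ci=spec_ci))
    label = name if name is not None else str(path)
    return TestProfile(name=label, points=tuple(points))
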