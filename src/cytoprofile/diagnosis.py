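"""Diagnosis: nearest-axis classification in CCR space.

Each test case yields a vector of three cell capture rates, one per
profile (Normal, CLL, FL).  A case matching exactly one profile sits near
that profile's axis in CCR space, so the diagnosis is the label whose axis
is closest:

    d_i = sqrt( sum_{j != i} CCR_j^2 ),      label = argmin_i d_i

i.e. the distance to axis i ignores the CCR along i itself and penalizes
capture by the competing profiles.  Exact ties are reported as
Inconclusive rather than silently resolved in favour of any label.

``CCRProfileClassifier`` wraps the full train/test procedure as a
scikit-learn estimator: ``fit`` pools each cohort's training cases into a
profile, ``transform`` returns CCR vectors, ``predict`` applies the
nearest-axis rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .fitting import fit_case, split_t_cells
from .preprocess import Point3Table
from .profile import AXIS_X, Profile, build_profile, merge_training_cases

__all__ = [
    "COHORTS",
    "DiagnosisResult",
    "axis_distances",
    "diagnose",
    "canonicalize_orientation",
    "build_cohort_profile",
    "CCRProfileClassifier",
]

COHORTS = ("Normal", "CLL", "FL")


@dataclass
class DiagnosisResult:
    """Label plus the per-axis distances that produced it."""

    label: str                    # Normal | CLL | FL | Inconclusive
    distances: dict[str, float]


def axis_distances(ccr: np.ndarray) -> np.ndarray:
    """Distance from a CCR vector to each cohort axis."""
    ccr = np.asarray(ccr, dtype=float)
    sq = ccr**2
    return np.sqrt(sq.sum(axis=-1, keepdims=True) - sq)


def diagnose(ccr: np.ndarray) -> DiagnosisResult:
    """Nearest-axis diagnosis of one CCR vector (Normal, CLL, FL order)."""
    ccr = np.asarray(ccr, dtype=float)
    if ccr.shape != (3,):
        raise ValueError("CCR vector must have exactly three components")
    if ((ccr < 0) | (ccr > 1)).any():
        raise ValueError("CCR components must lie in [0, 1]")
    d = axis_distances(ccr)
    winners = np.flatnonzero(d == d.min())
    label = COHORTS[winners[0]] if len(winners) == 1 else "Inconclusive"
    return DiagnosisResult(label=label, distances=dict(zip(COHORTS, d.tolist())))


def canonicalize_orientation(points: Point3Table) -> Point3Table:
    """Mirror a patient case to kappa orientation (B-cluster x mean > 0).

    Light-chain restriction puts a patient's single B cluster on one side
    of the x axis; flipping lambda-restricted cases before pooling lets
    kappa- and lambda-restricted training cases share one profile.  The
    mirror-and-take-max rule at fitting time undoes the arbitrariness for
    test cases.
    """
    t_mask = split_t_cells(points)
    if points.points[~t_mask, AXIS_X].mean() >= 0:
        return points
    mirrored = points.points.copy()
    mirrored[:, AXIS_X] *= -1
    return Point3Table(
        case_id=points.case_id,
        points=mirrored,
        cohort_label=points.cohort_label,
        population=points.population,
    )


def build_cohort_profile(
    cases: list[Point3Table],
    cohort_label: str,
    m: float = 2.0,
    seed: int = 0,
) -> Profile:
    """Pool training cases and fit the cohort's profile.

    Healthy cohorts fit k = 3 components; patient cohorts fit k = 2 after
    canonicalizing every training case to kappa orientation.
    """
    if cohort_label not in COHORTS:
        raise ValueError(f"unknown cohort {cohort_label!r}")
    if cohort_label in ("CLL", "FL"):
        cases = [canonicalize_orientation(c) for c in cases]
        k = 2
    else:
        k = 3
    merged = merge_training_cases(cases)
    return build_profile(merged, k=k, m=m, seed=seed, cohort_label=cohort_label)


class CCRProfileClassifier(BaseEstimator, ClassifierMixin):
    """Multi-profile lymphoma classifier over 3-D point tables.

    Parameters
    ----------
    m : float
        Ellipsoid size in standard deviations.
    random_state : int
        Seed for K-means initializations (profile building and fitting).

    Attributes
    ----------
    profiles_ : dict mapping cohort label to fitted :class:`Profile`.
    classes_ : the cohort labels seen in ``fit``.
    """

    def __init__(self, m: float = 2.0, random_state: int = 0) -> None:
        self.m = m
        self.random_state = random_state

    def fit(self, X: list[Point3Table], y: list[str]) -> "CCRProfileClassifier":
        """Build one profile per cohort from labelled training cases."""
        y = np.asarray(y, dtype=object)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        unknown = set(y) - set(COHORTS)
        if unknown:
            raise ValueError(f"unknown cohort labels: {sorted(unknown)}")
        self.profiles_ = {}
        for cohort in COHORTS:
            cohort_cases = [c for c, label in zip(X, y) if label == cohort]
            if not cohort_cases:
                raise ValueError(f"no training cases for cohort {cohort}")
            self.profiles_[cohort] = build_cohort_profile(
                cohort_cases, cohort, m=self.m, seed=self.random_state
            )
        self.classes_ = np.asarray(COHORTS, dtype=object)
        return self

    def transform(self, X: list[Point3Table]) -> np.ndarray:
        """CCR vectors, one row per case, columns in (Normal, CLL, FL) order."""
        return np.array([
            [fit_case(self.profiles_[c], case, seed=self.random_state) for c in COHORTS]
            for case in X
        ])

    def predict(self, X: list[Point3Table]) -> np.ndarray:
        return np.asarray(
            [diagnose(row).label for row in self.transform(X)], dtype=object
        )
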