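"""Cohort profiles: weighted Gaussian ellipsoids in the 3-D marker space.

A cohort profile is a k-component Gaussian mixture fitted to the pooled,
preprocessed events of the training cases, with each component rendered as
an ellipsoid at ``m`` standard deviations: the set of points whose
Mahalanobis distance from the component mean is at most ``m``.  Healthy
cohorts use k = 3 (kappa B cells, lambda B cells, T cells); CLL and FL
cohorts use k = 2 because light-chain restriction collapses the two B-cell
clusters into one.  The T-cell component is identified as the one with the
lowest CD19 (y) mean, since T cells lack CD19 expression.

The mixture is initialized with K-means (k-means++ seeding, 10 restarts,
best inertia) and refined by full-covariance EM to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Ellipsoid",
    "Profile",
    "GaussianProfileModel",
    "build_profile",
    "merge_training_cases",
    "contains",
]

# Axis order of the 3-D 5-parameter space.
AXIS_X, AXIS_Y, AXIS_Z = 0, 1, 2  # x = kappa - lambda, y = CD19, z = CD5 - CD10

_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class Ellipsoid:
    """One mixture component rendered as an m-standard-deviation ellipsoid.

    Contains every point whose Mahalanobis distance
    ``sqrt((p - mean)^T cov^{-1} (p - mean))`` is at most ``m``
    (boundary inclusive).
    """

    mean: np.ndarray
    covariance: np.ndarray
    m: float

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if mean.shape != (3,) or cov.shape != (3, 3):
            raise ValueError("ellipsoid must live in 3-D space")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")
        if self.m <= 0:
            raise ValueError("std multiplier m must be positive")

    def mahalanobis(self, points: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of each point from the ellipsoid center."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        diff = pts - self.mean
        sol = np.linalg.solve(self.covariance, diff.T)
        return np.sqrt(np.einsum("ij,ji->i", diff, sol))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership (Mahalanobis distance <= m) per point."""
        return self.mahalanobis(points) <= self.m


def contains(ellipsoid: Ellipsoid, point: np.ndarray) -> bool | np.ndarray:
    """Whether ``point`` lies inside (or on) the ellipsoid."""
    result = ellipsoid.contains(point)
    return bool(result[0]) if np.asarray(point).ndim == 1 else result


@dataclass
class Profile:
    """A cohort's fitted mixture: k weighted ellipsoids plus metadata.

    ``t_index`` marks the T-cell component; ``dominance`` records, for
    patient (k = 2) profiles, whether the restricted B cluster sits on the
    kappa (x > 0) or lambda (x < 0) side.
    """

    cohort_label: str
    weights: np.ndarray
    means: np.ndarray          # (k, 3)
    covariances: np.ndarray    # (k, 3, 3)
    m: float
    t_index: int
    dominance: str = "NA"      # kappa | lambda | NA

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        k = len(self.weights)
        if self.means.shape != (k, 3) or self.covariances.shape != (k, 3, 3):
            raise ValueError("inconsistent profile shapes")
        if not np.isclose(self.weights.sum(), 1.0) or (self.weights < 0).any():
            raise ValueError("weights must form a simplex")
        if self.cohort_label == "Normal" and k != 3:
            raise ValueError("Normal profiles must have k = 3")
        if self.cohort_label in ("CLL", "FL") and k != 2:
            raise ValueError("patient profiles must have k = 2")
        if not 0 <= self.t_index < k:
            raise ValueError("t_index out of range")
        if self.dominance not in ("kappa", "lambda", "NA"):
            raise ValueError(f"bad dominance {self.dominance!r}")

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def ellipsoids(self) -> list[Ellipsoid]:
        return [
            Ellipsoid(self.means[c], self.covariances[c], self.m)
            for c in range(self.k)
        ]

    @property
    def b_indices(self) -> list[int]:
        """Component indices of the B-cell ellipsoids (all but the T cluster)."""
        return [c for c in range(self.k) if c != self.t_index]

    @property
    def t_center(self) -> np.ndarray:
        return self.means[self.t_index]

    def shifted(self, delta: np.ndarray) -> "Profile":
        """Rigidly translate every ellipsoid by ``delta``; covariances unchanged."""
        delta = np.asarray(delta, dtype=float)
        return replace(self, means=self.means + delta, covariances=self.covariances.copy())

    def mirrored(self) -> "Profile":
        """Reflect the profile through the x = 0 plane (swap kappa/lambda roles)."""
        means = self.means @ _MIRROR
        covs = np.einsum("ij,cjk,kl->cil", _MIRROR, self.covariances, _MIRROR)
        dominance = {"kappa": "lambda", "lambda": "kappa"}.get(self.dominance, "NA")
        return replace(self, means=means, covariances=covs, dominance=dominance)


class GaussianProfileModel(BaseEstimator):
    """K-means-initialized EM Gaussian mixture profile of one cohort.

    Parameters
    ----------
    n_components : int
        Number of clusters k; 3 for healthy cohorts, 2 for patient cohorts.
    m : float
        Standard-deviation multiplier setting the ellipsoid size.
    random_state : int
        Seed for the k-means++ initialization.
    n_init : int
        K-means restarts; the best-inertia solution seeds EM.
    tol, max_iter : float, int
        EM stopping rule: relative log-likelihood change below ``tol`` or
        ``max_iter`` iterations.
    reg_covar : float
        Ridge added to covariance diagonals to keep them positive definite.

    Attributes
    ----------
    weights_, means_, covariances_ : fitted mixture parameters.
    t_index_ : component with the lowest CD19 (y) mean — the T-cell cluster.
    dominance_ : for k = 2, "kappa" if the B cluster's x mean is positive
        else "lambda"; "NA" for k = 3.
    """

    def __init__(
        self,
        n_components: int = 3,
        m: float = 2.0,
        random_state: int = 0,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        reg_covar: float = 1e-6,
    ) -> None:
        self.n_components = n_components
        self.m = m
        self.random_state = random_state
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar

    def fit(self, X: np.ndarray, y=None) -> "GaussianProfileModel":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be an (n, 3) array in the 3-D marker space")
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if len(X) < 10 * self.n_components:
            raise ValueError(
                f"need at least {10 * self.n_components} events to fit "
                f"{self.n_components} components, got {len(X)}"
            )
        try:
            self._fit_once(X, self.random_state)
        except _EmptyComponent:
            # one re-seed attempt before giving up
            try:
                self._fit_once(X, self.random_state + 1)
            except _EmptyComponent as exc:
                raise RuntimeError(
                    "EM produced an empty component twice; data may have fewer "
                    "clusters than requested"
                ) from exc
        return self

    def _fit_once(self, X: np.ndarray, seed: int) -> None:
        k = self.n_components
        km = KMeans(n_clusters=k, init="k-means++", n_init=self.n_init,
                    random_state=seed).fit(X)
        weights0 = np.bincount(km.labels_, minlength=k).astype(float)
        if (weights0 == 0).any():
            raise _EmptyComponent
        weights0 /= weights0.sum()
        covs0 = np.empty((k, 3, 3))
        for c in range(k):
            pts = X[km.labels_ == c]
            cov = np.cov(pts.T) if len(pts) > 3 else np.eye(3)
            cov = np.atleast_2d(cov) + self.reg_covar * np.eye(3)
            covs0[c] = cov
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            weights_init=weights0,
            means_init=km.cluster_centers_,
            precisions_init=np.linalg.inv(covs0),
            tol=self.tol,
            max_iter=self.max_iter,
            reg_covar=self.reg_covar,
            random_state=seed,
        ).fit(X)
        hard = gmm.predict(X)
        if len(np.unique(hard)) < k:
            raise _EmptyComponent
        self.weights_ = gmm.weights_
        self.means_ = gmm.means_
        self.covariances_ = gmm.covariances_
        self.converged_ = gmm.converged_
        self.n_iter_ = gmm.n_iter_
        self.t_index_ = int(np.argmin(self.means_[:, AXIS_Y]))
        if k == 2:
            b = 1 - self.t_index_
            self.dominance_ = "kappa" if self.means_[b, AXIS_X] > 0 else "lambda"
        else:
            self.dominance_ = "NA"

    def to_profile(self, cohort_label: str) -> Profile:
        check_is_fitted(self, "means_")
        return Profile(
            cohort_label=cohort_label,
            weights=self.weights_.copy(),
            means=self.means_.copy(),
            covariances=self.covariances_.copy(),
            m=self.m,
            t_index=self.t_index_,
            dominance=self.dominance_,
        )


class _EmptyComponent(RuntimeError):
    pass


def build_profile(points, k: int, m: float = 2.0, seed: int = 0,
                  cohort_label: str | None = None) -> Profile:
    """Fit a cohort profile to a 3-D point table.

    ``points`` may be a :class:`~cytoprofile.preprocess.Point3Table` or a
    plain (n, 3) array.  ``cohort_label`` defaults to the table's label, or
    to Normal/CLL by k when no label is available.
    """
    X = points.points if hasattr(points, "points") else np.asarray(points, dtype=float)
    if cohort_label is None:
        label = getattr(points, "cohort_label", None)
        cohort_label = label if label in ("Normal", "CLL", "FL") else \
            ("Normal" if k == 3 else "CLL")
    model = GaussianProfileModel(n_components=k, m=m, random_state=seed).fit(X)
    return model.to_profile(cohort_label)


def merge_training_cases(cases: list):
    """Pool events from several cases into one training table.

    Rows are concatenated in case order; per-event case provenance is kept
    in ``case_ids``.  Importing here avoids a module cycle.
    """
    from .preprocess import Point3Table

    if not cases:
        raise ValueError("cannot merge an empty list of cases")
    points = np.vstack([c.points for c in cases])
    case_ids = np.concatenate(
        [np.full(len(c.points), c.case_id, dtype=object) for c in cases]
    )
    labels = {c.cohort_label for c in cases}
    merged = Point3Table(
        case_id="+".join(c.case_id for c in cases),
        points=points,
        cohort_label=labels.pop() if len(labels) == 1 else "Unknown",
    )
    merged.case_ids = case_ids
    return merged
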