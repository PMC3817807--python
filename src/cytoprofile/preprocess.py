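"""Pre-processing: doublet removal, lymphocyte gating, 3-D projection.

Doublets (two cells read as one event) carry a disproportionate FSC-A
relative to FSC-H and are removed by a ratio band around the case median.
Lymphocytes are then selected on the (CD45, SSC-A) plane — CD45-bright,
low side scatter — by a two-component Gaussian mixture, replacing the
manual circular gate with an unattended equivalent.  Finally the five
modelling markers collapse into three axes:

    x = kappa - lambda      (light-chain balance; clonal B cells polarize)
    y = CD19                (pan-B marker; separates B from T cells)
    z = CD5 - CD10          (CLL sits at z > 0, FL at z < 0)

Subtracting paired markers cancels shared background signal, so a healthy
B cell sits near z = 0 while kappa- and lambda-expressing cells split along
x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .io import EventTable

__all__ = [
    "Point3Table",
    "DoubletFilter",
    "LymphocyteGate",
    "remove_doublets",
    "gate_lymphocytes",
    "to_point3",
    "preprocess_case",
]

MIN_GATE_EVENTS = 50


@dataclass
class Point3Table:
    """A case's events projected into the 3-D 5-parameter space."""

    case_id: str
    points: np.ndarray  # (n, 3): x = kappa - lambda, y = CD19, z = CD5 - CD10
    cohort_label: str = "Unknown"
    population: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")

    def __len__(self) -> int:
        return len(self.points)


class DoubletFilter(BaseEstimator):
    """Remove events whose FSC-A/FSC-H ratio strays from the case median.

    An event is kept when its area/height ratio lies inside
    ``[med * (1 - tol), med * (1 + tol)]`` where ``med`` is the median ratio
    of the case.  Doublets sit near twice the singlet ratio, far outside any
    moderate band.

    Attributes
    ----------
    median_ratio_ : float
    n_removed_ : int
    """

    def __init__(self, ratio_tolerance: float = 0.3) -> None:
        self.ratio_tolerance = ratio_tolerance

    def fit(self, table: EventTable, y=None) -> "DoubletFilter":
        h = table.data["FSC-H"].to_numpy(dtype=float)
        if (h <= 0).all():
            raise ValueError("FSC-H must be positive for ratio gating")
        ratio = table.data["FSC-A"].to_numpy(dtype=float) / np.where(h > 0, h, np.nan)
        self.median_ratio_ = float(np.nanmedian(ratio))
        return self

    def transform(self, table: EventTable) -> EventTable:
        h = table.data["FSC-H"].to_numpy(dtype=float)
        ratio = np.full(len(h), np.inf)
        pos = h > 0
        ratio[pos] = table.data["FSC-A"].to_numpy(dtype=float)[pos] / h[pos]
        med = self.median_ratio_
        tol = self.ratio_tolerance
        keep = (ratio >= med * (1 - tol)) & (ratio <= med * (1 + tol))
        self.n_removed_ = int((~keep).sum())
        if not keep.any():
            raise ValueError("doublet filter removed every event (degenerate case)")
        out = table.take(keep)
        out.meta["n_doublets_removed"] = self.n_removed_
        return out

    def fit_transform(self, table: EventTable, y=None) -> EventTable:
        return self.fit(table).transform(table)


class LymphocyteGate(BaseEstimator):
    """Select lymphocytes on (CD45, SSC-A) with a 2-component mixture.

    The lymphocyte component is the one with the highest CD45 mean (ties
    broken by the lower SSC-A mean).  Events assigned to it and within
    Mahalanobis distance 3 of its center are retained.  ``bypass=True``
    passes pre-gated input through unchanged.
    """

    def __init__(self, bypass: bool = False, random_state: int = 0,
                 mahalanobis_cut: float = 3.0) -> None:
        self.bypass = bypass
        self.random_state = random_state
        self.mahalanobis_cut = mahalanobis_cut

    def fit(self, table: EventTable, y=None) -> "LymphocyteGate":
        if self.bypass:
            return self
        if table.n_events < MIN_GATE_EVENTS:
            raise ValueError(
                f"need at least {MIN_GATE_EVENTS} events to fit the lymphocyte "
                f"gate, got {table.n_events}; pass bypass=True for pre-gated input"
            )
        X = table.data[["CD45", "SSC-A"]].to_numpy(dtype=float)
        gmm = GaussianMixture(n_components=2, covariance_type="full",
                              random_state=self.random_state, n_init=3).fit(X)
        for cov in gmm.covariances_:
            if np.linalg.eigvalsh(cov).min() <= 1e-10:
                raise ValueError(
                    "degenerate (CD45, SSC-A) mixture; input may already be "
                    "gated — pass bypass=True"
                )
        order = np.lexsort((gmm.means_[:, 1], -gmm.means_[:, 0]))
        self.component_ = int(order[0])  # highest CD45, then lowest SSC-A
        self.gmm_ = gmm
        return self

    def transform(self, table: EventTable) -> EventTable:
        if self.bypass:
            return table
        X = table.data[["CD45", "SSC-A"]].to_numpy(dtype=float)
        assigned = self.gmm_.predict(X) == self.component_
        mean = self.gmm_.means_[self.component_]
        cov = self.gmm_.covariances_[self.component_]
        diff = X - mean
        d2 = np.einsum("ij,ji->i", diff, np.linalg.solve(cov, diff.T))
        keep = assigned & (d2 <= self.mahalanobis_cut**2)
        if not keep.any():
            raise ValueError("lymphocyte gate retained no events")
        return table.take(keep)

    def fit_transform(self, table: EventTable, y=None) -> EventTable:
        return self.fit(table).transform(table)


def remove_doublets(table: EventTable, ratio_tolerance: float = 0.3) -> EventTable:
    """Functional wrapper over :class:`DoubletFilter`.

    The count of removed events is reported in the returned table's
    ``meta["n_doublets_removed"]``.
    """
    return DoubletFilter(ratio_tolerance).fit_transform(table)


def gate_lymphocytes(table: EventTable, bypass: bool = False,
                     random_state: int = 0) -> EventTable:
    """Functional wrapper over :class:`LymphocyteGate`."""
    return LymphocyteGate(bypass=bypass, random_state=random_state).fit_transform(table)


def to_point3(table: EventTable, asinh_cofactor: float | None = None) -> Point3Table:
    """Project events into the 3-D 5-parameter space, preserving order.

    With ``asinh_cofactor`` set, marker channels are first transformed by
    ``asinh(value / cofactor)``, a standard variance-stabilizing scale for
    cytometry; off by default.
    """
    cols = table.data[["kappa", "lambda", "CD19", "CD5", "CD10"]].to_numpy(dtype=float)
    if asinh_cofactor is not None:
        cols = np.arcsinh(cols / asinh_cofactor)
    kappa, lam, cd19, cd5, cd10 = cols.T
    points = np.column_stack([kappa - lam, cd19, cd5 - cd10])
    return Point3Table(
        case_id=table.case_id,
        points=points,
        cohort_label=table.cohort_label,
        population=table.population,
    )


def preprocess_case(
    table: EventTable,
    ratio_tolerance: float = 0.3,
    bypass_gate: bool = False,
    asinh_cofactor: float | None = None,
    random_state: int = 0,
) -> Point3Table:
    """Full pre-processing chain: doublets -> lymphocyte gate -> 3-D projection."""
    table = remove_doublets(table, ratio_tolerance)
    table = gate_lymphocytes(table, bypass=bypass_gate, random_state=random_state)
    return to_point3(table, asinh_cofactor=asinh_cofactor)
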