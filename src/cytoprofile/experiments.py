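"""Experiment designs: cross-validation bookkeeping and testing protocols.

Three designs are supported, mirroring how a multi-profile screen is
validated when cohorts are small:

* **Single-profile testing** — every case is fitted to the normal profile
  only; healthy cases should capture more B cells than patients.
* **Multi-profile cross-validation** — the normal profile uses 3-fold CV
  (each fold pools ``fold_size`` donors), the patient profiles use
  leave-one-out (each round trains on a single patient).  Every held-out
  case is fitted against every profile instance, and every triple of
  profile instances (normal fold x CLL round x FL round) diagnoses every
  case held out from all three of its trainings.
* **Selection-strategy protocol** — instead of CV, ~15% of each cohort is
  chosen as training data; patient training cases are those whose T-to-B
  cluster-center distance is closest to the cohort mean, a proxy for
  "typical" presentation.  The remaining cases are diagnosed once against
  the three pooled profiles.

All counts are exact closed-form functions of the cohort sizes, and a
leakage check asserts that no case is ever evaluated against a profile
trained on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnosis import COHORTS, build_cohort_profile, diagnose
from .fitting import fit_case, split_t_cells
from .preprocess import Point3Table, preprocess_case
from .profile import Profile

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "case_tb_distance",
    "select_by_distance",
    "select_training_cases",
    "box_stats",
    "run_single_profile",
    "run_multi_profile",
    "run_selection_protocol",
    "preprocess_cohorts",
]


@dataclass
class CVPlan:
    """Cross-validation design over three cohorts.

    ``normal_folds`` holds the training index sets (disjoint, size
    ``fold_size``); patient rounds train on one case each.
    """

    n_normal: int
    n_cll: int
    n_fl: int
    fold_size: int
    normal_folds: list[np.ndarray] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.normal_folds)

    # --- closed-form evaluation counts -------------------------------------
    @property
    def n_normal_evaluations(self) -> int:
        """CCRs computed against normal-profile instances."""
        return self.n_folds * (
            (self.n_normal - self.fold_size) + self.n_cll + self.n_fl
        )

    @property
    def n_cll_evaluations(self) -> int:
        return self.n_cll * (self.n_normal + (self.n_cll - 1) + self.n_fl)

    @property
    def n_fl_evaluations(self) -> int:
        return self.n_fl * (self.n_normal + self.n_cll + (self.n_fl - 1))

    @property
    def n_triples(self) -> int:
        return self.n_folds * self.n_cll * self.n_fl

    @property
    def n_diagnoses_by_cohort(self) -> dict[str, int]:
        """Triple-grid diagnosis counts split by the case's true cohort."""
        return {
            "Normal": self.n_triples * (self.n_normal - self.fold_size),
            "CLL": self.n_triples * (self.n_cll - 1),
            "FL": self.n_triples * (self.n_fl - 1),
        }

    @property
    def n_diagnoses(self) -> int:
        return sum(self.n_diagnoses_by_cohort.values())

    def counts(self) -> dict[str, int]:
        out = {
            "normal_profile_evaluations": self.n_normal_evaluations,
            "cll_profile_evaluations": self.n_cll_evaluations,
            "fl_profile_evaluations": self.n_fl_evaluations,
            "total_diagnoses": self.n_diagnoses,
        }
        for cohort, n in self.n_diagnoses_by_cohort.items():
            out[f"diagnoses_{cohort.lower()}"] = n
        return out


def make_cv_plan(n_normal: int = 36, n_cll: int = 21, n_fl: int = 15,
                 fold_size: int = 12, seed: int = 0) -> CVPlan:
    """Build the cross-validation design: 3 normal folds + patient LOO rounds."""
    if fold_size * 3 > n_normal:
        raise ValueError("need 3 disjoint normal folds of fold_size cases")
    if min(n_normal, n_cll, n_fl, fold_size) < 1:
        raise ValueError("cohort sizes and fold size must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_normal)
    folds = [np.sort(order[f * fold_size:(f + 1) * fold_size]) for f in range(3)]
    return CVPlan(n_normal, n_cll, n_fl, fold_size, folds)


# ---------------------------------------------------------------------------
# Training-case selection (~15% strategy)
# ---------------------------------------------------------------------------

def case_tb_distance(points: Point3Table) -> float:
    """Euclidean distance between a case's T- and B-cluster centers."""
    t_mask = split_t_cells(points)
    t_center = points.points[t_mask].mean(axis=0)
    b_center = points.points[~t_mask].mean(axis=0)
    return float(np.linalg.norm(t_center - b_center))


def _n_select(fraction: float, n: int) -> int:
    # nearest-int with a floor of one so small cohorts always train on >= 1
    return max(1, int(np.floor(fraction * n + 0.5)))


def select_by_distance(distances: np.ndarray, fraction: float = 0.15) -> list[int]:
    """Indices of the cases whose distance is nearest the cohort mean.

    Selects ``round(fraction * n)`` (at least one) cases; ties broken by
    case order.
    """
    distances = np.asarray(distances, dtype=float)
    if len(distances) < 2:
        raise ValueError("need at least two cases to select from")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    target = distances.mean()
    order = np.argsort(np.abs(distances - target), kind="stable")
    return sorted(int(i) for i in order[: _n_select(fraction, len(distances))])


def select_training_cases(cases: list[Point3Table],
                          fraction: float = 0.15) -> list[int]:
    """Pick ~``fraction`` of a patient cohort as training cases.

    The selection criterion is the distance between the T-cluster center
    and the B-cluster center: cases closest to the cohort-mean distance are
    the most typical and make the most transferable profile.
    """
    distances = np.array([case_tb_distance(c) for c in cases])
    return select_by_distance(distances, fraction)


# ---------------------------------------------------------------------------
# Result containers and protocols
# ---------------------------------------------------------------------------

def box_stats(values: np.ndarray) -> dict:
    """Box-plot summary: quartiles, 1.5 IQR whiskers, outliers."""
    values = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = values[(values >= lo) & (values <= hi)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inliers.min()), "whisker_high": float(inliers.max()),
        "outliers": values[(values < lo) | (values > hi)].tolist(),
    }


@dataclass
class SingleProfileResult:
    """Per-case CCRs against one profile plus per-cohort box summaries."""

    records: pd.DataFrame          # case_id, cohort, ccr
    summaries: dict[str, dict]     # cohort -> box_stats


def run_single_profile(cases: list[Point3Table], profile: Profile,
                       seed: int = 0) -> SingleProfileResult:
    """Fit every case against a single (normal) profile."""
    rows = [
        {"case_id": c.case_id, "cohort": c.cohort_label,
         "ccr": fit_case(profile, c, seed=seed)}
        for c in cases
    ]
    records = pd.DataFrame(rows)
    summaries = {
        cohort: box_stats(grp["ccr"].to_numpy())
        for cohort, grp in records.groupby("cohort")
    }
    return SingleProfileResult(records=records, summaries=summaries)


@dataclass
class MultiProfileResult:
    """Full cross-validation output: CCR records, mean CCRs, confusion."""

    ccr_records: pd.DataFrame      # case_id, cohort, profile, profile_idx, ccr
    mean_ccr: pd.DataFrame         # true cohort x profile type
    confusion_counts: pd.DataFrame
    confusion_rates: pd.DataFrame
    counts: dict[str, int]


def _ccr_matrix(profiles: list[Profile], cases: list[Point3Table],
                seed: int) -> np.ndarray:
    """(n_profiles, n_cases) CCR cache."""
    return np.array([[fit_case(p, c, seed=seed) for c in cases] for p in profiles])


def run_multi_profile(plan: CVPlan,
                      cases_by_cohort: dict[str, list[Point3Table]],
                      m: float = 2.0, seed: int = 0) -> MultiProfileResult:
    """Execute the full cross-validation grid.

    Builds every profile instance, computes each eligible (case, profile)
    CCR once, then diagnoses every case on every profile triple it is held
    out from.  Raises if any cohort list disagrees with the plan sizes or
    if a case would be evaluated against a profile trained on it.
    """
    normals = cases_by_cohort["Normal"]
    clls = cases_by_cohort["CLL"]
    fls = cases_by_cohort["FL"]
    if (len(normals), len(clls), len(fls)) != (plan.n_normal, plan.n_cll, plan.n_fl):
        raise ValueError("case lists disagree with the plan's cohort sizes")

    normal_profiles = [
        build_cohort_profile([normals[i] for i in fold], "Normal", m=m, seed=seed)
        for fold in plan.normal_folds
    ]
    cll_profiles = [build_cohort_profile([c], "CLL", m=m, seed=seed) for c in clls]
    fl_profiles = [build_cohort_profile([c], "FL", m=m, seed=seed) for c in fls]

    all_cases = {"Normal": normals, "CLL": clls, "FL": fls}
    # CCR caches: rows = profile instances, cols = cases of one cohort.
    ccr = {
        (ptype, cohort): _ccr_matrix(profs, all_cases[cohort], seed)
        for ptype, profs in (("Normal", normal_profiles), ("CLL", cll_profiles),
                             ("FL", fl_profiles))
        for cohort in COHORTS
    }

    # Eligibility masks per (profile type, instance): True where the case was
    # not part of that instance's training set.
    def eligible(ptype: str, idx: int, cohort: str) -> np.ndarray:
        n = len(all_cases[cohort])
        mask = np.ones(n, dtype=bool)
        if ptype == "Normal" and cohort == "Normal":
            mask[plan.normal_folds[idx]] = False
        elif ptype == cohort:  # patient LOO
            mask[idx] = False
        return mask

    rows = []
    for ptype, profs in (("Normal", normal_profiles), ("CLL", cll_profiles),
                         ("FL", fl_profiles)):
        for idx in range(len(profs)):
            for cohort in COHORTS:
                mask = eligible(ptype, idx, cohort)
                for case_idx in np.flatnonzero(mask):
                    rows.append({
                        "case_id": all_cases[cohort][case_idx].case_id,
                        "cohort": cohort, "profile": ptype,
                        "profile_idx": idx,
                        "ccr": ccr[(ptype, cohort)][idx, case_idx],
                    })
    ccr_records = pd.DataFrame(rows)
    mean_ccr = (
        ccr_records.pivot_table(index="cohort", columns="profile", values="ccr")
        .reindex(index=COHORTS, columns=COHORTS)
    )

    # Triple grid: vectorized nearest-axis diagnosis per (fold, cll, fl).
    labels = list(COHORTS) + ["Inconclusive"]
    confusion = pd.DataFrame(0, index=list(COHORTS), columns=labels)
    for f in range(plan.n_folds):
        for i in range(plan.n_cll):
            for j in range(plan.n_fl):
                for cohort in COHORTS:
                    mask = (eligible("Normal", f, cohort)
                            & eligible("CLL", i, cohort)
                            & eligible("FL", j, cohort))
                    vecs = np.column_stack([
                        ccr[("Normal", cohort)][f, mask],
                        ccr[("CLL", cohort)][i, mask],
                        ccr[("FL", cohort)][j, mask],
                    ])
                    sq = vecs**2
                    d = np.sqrt(sq.sum(axis=1, keepdims=True) - sq)
                    pred = np.argmin(d, axis=1)
                    ties = (d == d.min(axis=1, keepdims=True)).sum(axis=1) > 1
                    for lbl_idx in range(3):
                        confusion.loc[cohort, COHORTS[lbl_idx]] += int(
                            ((pred == lbl_idx) & ~ties).sum()
                        )
                    confusion.loc[cohort, "Inconclusive"] += int(ties.sum())

    counts = plan.counts()
    observed = ccr_records.groupby("profile").size()
    assert observed["Normal"] == counts["normal_profile_evaluations"]
    assert observed["CLL"] == counts["cll_profile_evaluations"]
    assert observed["FL"] == counts["fl_profile_evaluations"]
    assert int(confusion.to_numpy().sum()) == counts["total_diagnoses"]

    confusion_rates = confusion.div(confusion.sum(axis=1), axis=0)
    return MultiProfileResult(ccr_records, mean_ccr, confusion,
                              confusion_rates, counts)


@dataclass
class SelectionProtocolResult:
    """Outcome of the ~15%-selection multi-profile screen."""

    training_ids: dict[str, list[str]]
    ccr_vectors: pd.DataFrame      # case_id, cohort, ccr_normal, ccr_cll, ccr_fl
    predictions: pd.DataFrame      # case_id, cohort, label
    mean_ccr: pd.DataFrame
    confusion_counts: pd.DataFrame
    confusion_rates: pd.DataFrame
    accuracy: dict[str, float]


def run_selection_protocol(
    cases_by_cohort: dict[str, list[Point3Table]],
    fraction: float = 0.15,
    m: float = 2.0,
    seed: int = 0,
) -> SelectionProtocolResult:
    """Build one profile per cohort from ~15% of its cases, test the rest.

    Healthy training donors are a seeded random sample (healthy samples are
    homogeneous, so no criterion is needed); patient training cases use the
    T-to-B distance criterion.  Every held-out case is fitted to all three
    profiles and diagnosed by the nearest-axis rule.
    """
    rng = np.random.default_rng(seed)
    train_idx: dict[str, list[int]] = {}
    normals = cases_by_cohort["Normal"]
    train_idx["Normal"] = sorted(
        rng.choice(len(normals), size=_n_select(fraction, len(normals)),
                   replace=False).tolist()
    )
    for cohort in ("CLL", "FL"):
        train_idx[cohort] = select_training_cases(cases_by_cohort[cohort], fraction)

    profiles = {
        cohort: build_cohort_profile(
            [cases_by_cohort[cohort][i] for i in train_idx[cohort]],
            cohort, m=m, seed=seed,
        )
        for cohort in COHORTS
    }

    rows = []
    for cohort in COHORTS:
        held_out = [c for i, c in enumerate(cases_by_cohort[cohort])
                    if i not in set(train_idx[cohort])]
        for case in held_out:
            vec = [fit_case(profiles[p], case, seed=seed) for p in COHORTS]
            rows.append({
                "case_id": case.case_id, "cohort": cohort,
                "ccr_normal": vec[0], "ccr_cll": vec[1], "ccr_fl": vec[2],
                "label": diagnose(np.array(vec)).label,
            })
    table = pd.DataFrame(rows)

    labels = list(COHORTS) + ["Inconclusive"]
    confusion = pd.DataFrame(0, index=list(COHORTS), columns=labels)
    for cohort, grp in table.groupby("cohort"):
        for lbl, n in grp["label"].value_counts().items():
            confusion.loc[cohort, lbl] += int(n)
    confusion_rates = confusion.div(confusion.sum(axis=1), axis=0)
    accuracy = {c: float(confusion_rates.loc[c, c]) for c in COHORTS}
    mean_ccr = (
        table.groupby("cohort")[["ccr_normal", "ccr_cll", "ccr_fl"]].mean()
        .reindex(COHORTS)
        .set_axis(list(COHORTS), axis=1)
    )
    return SelectionProtocolResult(
        training_ids={
            c: [cases_by_cohort[c][i].case_id for i in train_idx[c]]
            for c in COHORTS
        },
        ccr_vectors=table[["case_id", "cohort", "ccr_normal", "ccr_cll", "ccr_fl"]],
        predictions=table[["case_id", "cohort", "label"]],
        mean_ccr=mean_ccr,
        confusion_counts=confusion,
        confusion_rates=confusion_rates,
        accuracy=accuracy,
    )


def preprocess_cohorts(tables, **kwargs) -> dict[str, list[Point3Table]]:
    """Preprocess a list of event tables and group them by cohort label."""
    out: dict[str, list[Point3Table]] = {c: [] for c in COHORTS}
    for table in tables:
        out[table.cohort_label].append(preprocess_case(table, **kwargs))
    return out
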