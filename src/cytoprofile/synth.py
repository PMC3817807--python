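"""Synthetic flow-cytometry cohorts with known ground truth.

No public FCS repository carries the cohort structure this method needs
(healthy, CLL and FL cases over the CD5/CD10/CD19/kappa/lambda panel), so
every stage of the pipeline is exercised against generated data whose
event-level labels are known by construction.

Each case is a mixture of Gaussian populations over the nine channels:

* a granulocyte population (CD45 mid, SSC-A high) that the lymphocyte gate
  must reject;
* T lymphocytes (CD45 high, SSC-A low, CD19 negative);
* B lymphocytes — in healthy cases an even kappa/lambda pair, in CLL a
  single light-chain-restricted CD5+ population (z > 0), in FL a single
  restricted CD10+ population (z < 0).

Instrument artifacts are injected on top: doublets (FSC-A doubled at a
configurable rate) and a per-case global intensity shift, realized on the
kappa/CD19/CD5 channels so the 3-D projection translates rigidly — the
batch effect the T-cell anchoring is designed to cancel.

Default geometry places cluster means 8 units apart at a per-channel
standard deviation of 0.5 (>= 11 pooled standard deviations), the easy
regime in which the model's assumptions clearly hold; the ``difficulty``
knob shrinks the marker offsets to probe failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SEMANTIC_CHANNELS, EventTable

__all__ = [
    "Population",
    "CohortSpec",
    "normal_spec",
    "cll_spec",
    "fl_spec",
    "generate_case",
    "generate_cohorts",
]

# Channel-level building blocks (arbitrary instrument units).
_BACKGROUND = 1.0       # unstained fluorescence level
_MARKER_OFFSET = 8.0    # positive-marker level above background
_MARKER_STD = 0.5
_LYMPH = {"FSC-H": (100.0, 6.0), "SSC-A": (50.0, 8.0), "CD45": (100.0, 5.0)}
_GRAN = {"FSC-H": (140.0, 10.0), "SSC-A": (150.0, 15.0), "CD45": (60.0, 5.0)}
_FSC_RATIO_STD = 0.03   # singlet FSC-A/FSC-H jitter
_GRANULOCYTE_FRACTION = 0.25


@dataclass(frozen=True)
class Population:
    """One generating cluster: per-channel Gaussian means and stds."""

    name: str
    proportion: float
    means: dict[str, float]
    stds: dict[str, float]


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic case."""

    cohort: str
    n_events: int = 5000
    populations: list[Population] = field(default_factory=list)
    dominance: str = "NA"
    global_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    doublet_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort not in ("Normal", "CLL", "FL"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not self.populations:
            raise ValueError("spec must define at least one population")
        total = sum(p.proportion for p in self.populations)
        if not np.isclose(total, 1.0) or any(p.proportion < 0 for p in self.populations):
            raise ValueError("population proportions must be a simplex")
        if not 0.0 <= self.doublet_rate <= 0.5:
            raise ValueError("doublet_rate must lie in [0, 0.5]")
        if self.n_events < 1:
            raise ValueError("n_events must be positive")


def _population(name: str, proportion: float, scatter: dict,
                positive: dict[str, float]) -> Population:
    """A population with given scatter levels and positive markers."""
    means = {"FSC-H": scatter["FSC-H"][0], "SSC-A": scatter["SSC-A"][0],
             "CD45": scatter["CD45"][0]}
    stds = {"FSC-H": scatter["FSC-H"][1], "SSC-A": scatter["SSC-A"][1],
            "CD45": scatter["CD45"][1]}
    for marker in ("CD5", "CD10", "CD19", "kappa", "lambda"):
        means[marker] = _BACKGROUND + positive.get(marker, 0.0)
        stds[marker] = _MARKER_STD
    return Population(name, proportion, means, stds)


def _lymph_populations(cohort: str, dominance: str, difficulty: float) -> list[Population]:
    off = _MARKER_OFFSET * difficulty
    lymph_frac = 1.0 - _GRANULOCYTE_FRACTION
    if cohort == "Normal":
        split = {"T": 0.6, "kappa_B": 0.2, "lambda_B": 0.2}
        pops = [
            _population("T", split["T"] * lymph_frac, _LYMPH, {}),
            _population("kappa_B", split["kappa_B"] * lymph_frac, _LYMPH,
                        {"CD19": off, "kappa": off}),
            _population("lambda_B", split["lambda_B"] * lymph_frac, _LYMPH,
                        {"CD19": off, "lambda": off}),
        ]
    else:
        t_frac = 0.4 if cohort == "CLL" else 0.5
        chain = "kappa" if dominance == "kappa" else "lambda"
        cd = "CD5" if cohort == "CLL" else "CD10"
        pops = [
            _population("T", t_frac * lymph_frac, _LYMPH, {}),
            _population("B", (1 - t_frac) * lymph_frac, _LYMPH,
                        {"CD19": off, chain: off, cd: off}),
        ]
    pops.append(_population("granulocyte", _GRANULOCYTE_FRACTION, _GRAN, {}))
    return pops


def normal_spec(n_events: int = 5000, seed: int = 0,
                global_shift=(0.0, 0.0, 0.0), doublet_rate: float = 0.05,
                difficulty: float = 1.0) -> CohortSpec:
    """Healthy cohort: even kappa/lambda B populations plus T cells."""
    return CohortSpec("Normal", n_events, _lymph_populations("Normal", "NA", difficulty),
                      "NA", tuple(global_shift), doublet_rate, seed)


def cll_spec(dominance: str = "kappa", n_events: int = 5000, seed: int = 0,
             global_shift=(0.0, 0.0, 0.0), doublet_rate: float = 0.05,
             difficulty: float = 1.0) -> CohortSpec:
    """CLL cohort: one CD5+, light-chain-restricted B population (z > 0)."""
    if dominance not in ("kappa", "lambda"):
        raise ValueError("dominance must be kappa or lambda")
    return CohortSpec("CLL", n_events, _lymph_populations("CLL", dominance, difficulty),
                      dominance, tuple(global_shift), doublet_rate, seed)


def fl_spec(dominance: str = "kappa", n_events: int = 5000, seed: int = 0,
            global_shift=(0.0, 0.0, 0.0), doublet_rate: float = 0.05,
            difficulty: float = 1.0) -> CohortSpec:
    """FL cohort: one CD10+, light-chain-restricted B population (z < 0)."""
    if dominance not in ("kappa", "lambda"):
        raise ValueError("dominance must be kappa or lambda")
    return CohortSpec("FL", n_events, _lymph_populations("FL", dominance, difficulty),
                      dominance, tuple(global_shift), doublet_rate, seed)


def generate_case(spec: CohortSpec, case_id: str | None = None) -> EventTable:
    """Draw one synthetic case; reproducible for a fixed spec (incl. seed).

    Ground truth is attached to the returned table: ``population`` names
    the generating cluster per event and ``is_doublet`` flags injected
    doublets.
    """
    rng = np.random.default_rng(spec.seed)
    props = np.array([p.proportion for p in spec.populations])
    counts = rng.multinomial(spec.n_events, props)
    blocks, labels = [], []
    for pop, n in zip(spec.populations, counts):
        if n == 0:
            continue
        cols = {}
        for ch in ("FSC-H", "SSC-A", "CD45", "CD5", "CD10", "CD19", "kappa", "lambda"):
            cols[ch] = rng.normal(pop.means[ch], pop.stds[ch], size=n)
        cols["FSC-A"] = cols["FSC-H"] * rng.normal(1.0, _FSC_RATIO_STD, size=n)
        blocks.append(pd.DataFrame(cols))
        labels.extend([pop.name] * n)
    data = pd.concat(blocks, ignore_index=True)
    population = np.asarray(labels, dtype=object)

    is_doublet = rng.random(len(data)) < spec.doublet_rate
    data.loc[is_doublet, "FSC-A"] *= 2.0

    vx, vy, vz = spec.global_shift
    data["kappa"] += vx
    data["CD19"] += vy
    data["CD5"] += vz

    order = rng.permutation(len(data))
    data = data.iloc[order].reset_index(drop=True)[list(SEMANTIC_CHANNELS)]
    return EventTable(
        case_id=case_id or f"{spec.cohort.lower()}-{spec.seed}",
        cohort_label=spec.cohort,
        data=data,
        population=population[order],
        is_doublet=is_doublet[order],
        meta={"dominance": spec.dominance, "global_shift": spec.global_shift},
    )


def generate_cohorts(
    n_normal: int = 44,
    n_cll: int = 21,
    n_fl: int = 15,
    master_seed: int = 0,
    n_events_range: tuple[int, int] = (2000, 4000),
    shift_range: float = 2.0,
    doublet_rate: float = 0.05,
    difficulty: float = 1.0,
) -> list[EventTable]:
    """Generate a full three-cohort study with per-case variation.

    Each case gets its own seed (derived from ``master_seed``), event count
    (uniform in ``n_events_range``), global shift (uniform per axis in
    ``[-shift_range, shift_range]``) and, for patient cases, a random
    light-chain dominance.
    """
    rng = np.random.default_rng(master_seed)
    factories = {"Normal": normal_spec, "CLL": cll_spec, "FL": fl_spec}
    cases = []
    for cohort, count in (("Normal", n_normal), ("CLL", n_cll), ("FL", n_fl)):
        for i in range(count):
            seed = int(rng.integers(0, 2**31 - 1))
            n = int(rng.integers(n_events_range[0], n_events_range[1] + 1))
            shift = tuple(rng.uniform(-shift_range, shift_range, size=3))
            kwargs = dict(n_events=n, seed=seed, global_shift=shift,
                          doublet_rate=doublet_rate, difficulty=difficulty)
            if cohort == "Normal":
                spec = factories[cohort](**kwargs)
            else:
                dominance = "kappa" if rng.random() < 0.5 else "lambda"
                spec = factories[cohort](dominance=dominance, **kwargs)
            cases.append(generate_case(spec, case_id=f"{cohort.lower()}-{i:03d}"))
    return cases
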