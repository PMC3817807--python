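"""Event-table and profile I/O.

Flow cytometry event data is read either from delimited text tables (one
header row of instrument channel names) or from FCS 3.0/3.1 files written
in list mode with float data.  A :class:`ChannelMap` resolves instrument
channel names to the nine semantic channels the lymphoma-detection model
needs: forward/side scatter for doublet removal and gating, CD45 for the
lymphocyte gate, and the five modelling markers CD5, CD10, CD19, kappa and
lambda.

Profiles (sets of weighted Gaussian ellipsoids) serialize to a versioned
JSON document so they are diffable and language-portable.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profile import Profile

#: The nine semantic channels, in canonical column order.
SEMANTIC_CHANNELS: tuple[str, ...] = (
    "FSC-A", "FSC-H", "SSC-A", "CD45", "CD5", "CD10", "CD19", "kappa", "lambda",
)

#: The five fluorescence markers entering the 3-D model.
MARKER_CHANNELS: tuple[str, ...] = ("CD5", "CD10", "CD19", "kappa", "lambda")

COHORTS = ("Normal", "CLL", "FL")
PROFILE_SCHEMA = "cytoprofile-profile/1"


class ChannelError(ValueError):
    """A required semantic channel could not be resolved."""


class FormatError(ValueError):
    """The file is not a readable event-data format."""


@dataclass(frozen=True)
class ChannelMap:
    """Maps each semantic channel name to an instrument channel name.

    All nine semantic channels must be present and the instrument names
    must be unique (two semantic channels cannot share a detector).
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in SEMANTIC_CHANNELS if c not in self.mapping]
        if missing:
            raise ChannelError(f"channel map missing semantic channels: {missing}")
        instrument = list(self.mapping.values())
        if len(set(instrument)) != len(instrument):
            raise ChannelError("instrument channel names must be unique")

    @classmethod
    def identity(cls) -> "ChannelMap":
        """Map each semantic channel to itself."""
        return cls({c: c for c in SEMANTIC_CHANNELS})

    def instrument_name(self, semantic: str) -> str:
        return self.mapping[semantic]

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelMap":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.mapping, fh, indent=2)


@dataclass
class EventTable:
    """One case's events by semantic channel.

    ``data`` holds the event matrix with the nine semantic channel names as
    columns, in instrument (arbitrary) units.  Synthetic cases may carry
    per-event ground-truth annotations: ``population`` (generating cluster
    name per event) and ``is_doublet``.
    """

    case_id: str
    cohort_label: str
    data: pd.DataFrame
    population: np.ndarray | None = None
    is_doublet: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort_label not in COHORTS + ("Unknown",):
            raise ValueError(f"unknown cohort label {self.cohort_label!r}")
        if len(self.data) < 1:
            raise ValueError("event table must contain at least one event")
        missing = [c for c in SEMANTIC_CHANNELS if c not in self.data.columns]
        if missing:
            raise ChannelError(f"event table missing channels: {missing}")
        if self.data[list(SEMANTIC_CHANNELS)].isna().any().any():
            raise ValueError("event table contains missing values")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def matrix(self) -> np.ndarray:
        """Events as an (n, 9) float array in canonical column order."""
        return self.data[list(SEMANTIC_CHANNELS)].to_numpy(dtype=float)

    def take(self, index: np.ndarray) -> "EventTable":
        """Subset events by boolean mask or integer index, keeping annotations."""
        index = np.asarray(index)
        idx = np.flatnonzero(index) if index.dtype == bool else index
        return EventTable(
            case_id=self.case_id,
            cohort_label=self.cohort_label,
            data=self.data.iloc[idx].reset_index(drop=True),
            population=None if self.population is None else self.population[idx],
            is_doublet=None if self.is_doublet is None else self.is_doublet[idx],
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Delimited and FCS readers/writers
# ---------------------------------------------------------------------------

def _is_fcs(path: Path) -> bool:
    with open(path, "rb") as fh:
        magic = fh.read(6)
    return magic in (b"FCS3.0", b"FCS3.1")


def read_case(
    path: str | Path,
    channel_map: ChannelMap | None = None,
    case_id: str | None = None,
    cohort_label: str = "Unknown",
) -> EventTable:
    """Read one case from an FCS 3.0/3.1 file or a delimited table.

    Columns are resolved through ``channel_map`` (identity by default) and
    renamed to the nine semantic channels; event order is preserved.
    Raises :class:`ChannelError` naming any unresolved semantic channel.
    """
    path = Path(path)
    cmap = channel_map or ChannelMap.identity()
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_fcs(path):
        names, matrix = _read_fcs(path)
        raw = pd.DataFrame(matrix, columns=names)
    else:
        try:
            raw = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise FormatError(f"cannot parse {path} as a delimited table: {exc}") from exc
    missing = [s for s in SEMANTIC_CHANNELS if cmap.instrument_name(s) not in raw.columns]
    if missing:
        raise ChannelError(
            f"file {path.name} lacks channels for semantic names: {missing}"
        )
    data = raw[[cmap.instrument_name(s) for s in SEMANTIC_CHANNELS]].copy()
    data.columns = list(SEMANTIC_CHANNELS)
    return EventTable(case_id or path.stem, cohort_label, data)


def write_case(
    table: EventTable,
    path: str | Path,
    channel_map: ChannelMap | None = None,
) -> Path:
    """Write a case to ``path``; ``.fcs`` suffix selects FCS 3.1, else CSV.

    The output is round-trippable by :func:`read_case` (exactly for CSV,
    to float32 precision for FCS).
    """
    path = Path(path)
    cmap = channel_map or ChannelMap.identity()
    names = [cmap.instrument_name(s) for s in SEMANTIC_CHANNELS]
    if any(not n for n in names):
        raise ChannelError("empty instrument channel name")
    matrix = table.matrix()
    if path.suffix.lower() == ".fcs":
        _write_fcs(path, names, matrix)
    else:
        out = pd.DataFrame(matrix, columns=names)
        out.to_csv(path, index=False)
    return path


# Minimal FCS 3.1 support: list mode, float32, little/big endian.  Covers
# channel names and event data only, which is all the pipeline consumes.

def _read_fcs(path: Path) -> tuple[list[str], np.ndarray]:
    blob = path.read_bytes()
    try:
        text_start = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise FormatError(f"{path.name}: malformed FCS header") from exc
    text = blob[text_start:text_end + 1].decode("latin-1")
    if not text:
        raise FormatError(f"{path.name}: empty TEXT segment")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i].strip().upper(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE", "L") != "L":
        raise FormatError(f"{path.name}: only list-mode float FCS is supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    data_start = int(kw.get("$BEGINDATA") or blob[26:34])
    data_end = int(kw.get("$ENDDATA") or blob[34:42])
    raw = blob[data_start:data_end + 1]
    n_vals = n_par * n_tot
    if len(raw) < 4 * n_vals:
        raise FormatError(f"{path.name}: truncated DATA segment")
    matrix = np.frombuffer(raw[: 4 * n_vals], dtype=f"{endian}f4").reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return names, matrix.astype(float)


def _write_fcs(path: Path, names: list[str], matrix: np.ndarray) -> None:
    n_tot, n_par = matrix.shape
    data = np.ascontiguousarray(matrix, dtype="<f4").tobytes()
    delim = "/"
    kw = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"

    header_len = 58
    # Two passes: offsets depend on the TEXT length, which contains offsets.
    def render(data_start: int, data_end: int) -> bytes:
        items = dict(kw, **{"$BEGINDATA": str(data_start), "$ENDDATA": str(data_end)})
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in items.items()) + delim
        return body.encode("latin-1")

    text = render(0, 0)
    for _ in range(3):
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data) - 1
        new_text = render(data_start, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode() + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode() + f"{data_end:8d}".encode()
        + f"{0:8d}".encode() + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    path.write_bytes(header + text + data)


# ---------------------------------------------------------------------------
# Profile serialization
# ---------------------------------------------------------------------------

def save_profile(profile: Profile, path: str | Path) -> Path:
    """Serialize a profile to a versioned JSON document."""
    doc = {
        "schema": PROFILE_SCHEMA,
        "cohort_label": profile.cohort_label,
        "k": profile.k,
        "m": profile.m,
        "weights": profile.weights.tolist(),
        "means": profile.means.tolist(),
        "covariances": profile.covariances.tolist(),
        "t_index": profile.t_index,
        "dominance": profile.dominance,
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return path


def load_profile(path: str | Path) -> Profile:
    """Load a profile saved by :func:`save_profile`.

    Raises :class:`FormatError` on truncated documents or a schema-version
    mismatch.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse profile document {path}: {exc}") from exc
    if doc.get("schema") != PROFILE_SCHEMA:
        raise FormatError(
            f"profile schema mismatch: expected {PROFILE_SCHEMA!r}, "
            f"got {doc.get('schema')!r}"
        )
    return Profile(
        cohort_label=doc["cohort_label"],
        weights=np.asarray(doc["weights"], dtype=float),
        means=np.asarray(doc["means"], dtype=float),
        covariances=np.asarray(doc["covariances"], dtype=float),
        m=float(doc["m"]),
        t_index=int(doc["t_index"]),
        dominance=doc["dominance"],
    )
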