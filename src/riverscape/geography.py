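"""Bioregions, geographic-range states, and landscape evolution models (LEMs).

A *bioregion* is an atomic geographic unit (e.g. a shield or sedimentary
basin); a lineage's geographic range is a subset of bioregions, encoded as a
bitset (:class:`RangeState`).  A *landscape evolution model* (LEM) is a named
biogeographic scenario: an ordered list of bioregions plus one or more time
slices, each carrying an ``n_areas x n_areas`` matrix of non-negative
dispersal multipliers that scale the macroevolutionary dispersal rate between
ordered pairs of regions.  A stepping-stone model is the special case of a
single slice whose multipliers are a binary adjacency matrix.

Time slices are ordered oldest to youngest and tile the interval from the
root age down to the present with no gaps.  A slice with bounds
``(start_age, end_age)`` contains ages ``end_age <= a < start_age`` — an
event exactly at a boundary age belongs to the older slice, and age 0
belongs to the youngest slice.  The oldest slice's ``start_age`` may be
declared unbounded (``inf``): it is clamped to the tree's root age at
analysis time, so the likelihood does not depend on an arbitrary older bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

NULL_TOKEN = "∅"  # ∅


@dataclass(frozen=True)
class Bioregion:
    """One atomic area: a single-letter code, a display name and a 0-based index."""

    code: str
    name: str
    index: int


@dataclass(frozen=True, order=True)
class RangeState:
    """A geographic range: a subset of bioregion indices, encoded as a bitset.

    Bit ``i`` of :attr:`bits` corresponds to bioregion index ``i``.  The empty
    (null) range ``bits == 0`` is a valid internal state of the DEC process
    (reachable by extinction from singletons) but never a tip observation.
    """

    bits: int

    def __post_init__(self) -> None:
        if self.bits < 0:
            raise ValidationError("RangeState.bits must be non-negative")

    @classmethod
    def from_areas(cls, areas: Iterable[int]) -> "RangeState":
        bits = 0
        for a in areas:
            a = int(a)  # tolerate numpy integers
            if a < 0:
                raise ValidationError(f"area index {a} is negative")
            bits |= 1 << a
        return cls(bits)

    @property
    def areas(self) -> frozenset[int]:
        return frozenset(i for i in range(self.bits.bit_length()) if self.bits >> i & 1)

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def is_null(self) -> bool:
        return self.bits == 0

    def __contains__(self, area: int) -> bool:
        return bool(self.bits >> area & 1)

    def add(self, area: int) -> "RangeState":
        return RangeState(self.bits | 1 << area)

    def remove(self, area: int) -> "RangeState":
        return RangeState(self.bits & ~(1 << area))

    def __iter__(self):
        return iter(sorted(self.areas))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"RangeState({{{','.join(map(str, sorted(self.areas)))}}})"


NULL_RANGE = RangeState(0)


def enumerate_ranges(n_areas: int, max_range_size: int) -> list[RangeState]:
    """Enumerate the DEC state space: the null range first, then all non-empty
    subsets of up to ``max_range_size`` areas, sorted by (size, bitset value).

    The ordering is the fixed convention used everywhere in the package (rate
    matrices, conditional-likelihood vectors, serialized reports).
    """
    if n_areas < 1 or n_areas > 16:
        raise ValidationError(f"n_areas must be in [1, 16], got {n_areas}")
    if not 1 <= max_range_size <= n_areas:
        raise ValidationError(
            f"max_range_size must be in [1, n_areas={n_areas}], got {max_range_size}"
        )
    states = [NULL_RANGE]
    for k in range(1, max_range_size + 1):
        sized = [RangeState.from_areas(c) for c in combinations(range(n_areas), k)]
        states.extend(sorted(sized, key=lambda s: s.bits))
    return states


@dataclass
class TimeSlice:
    """One stratum of a LEM: an age interval and its dispersal multipliers.

    ``start_age`` is the older bound (possibly ``inf`` for the oldest slice),
    ``end_age`` the younger; both in Ma.  The diagonal of ``multipliers`` is
    ignored by the DEC process.
    """

    start_age: float
    end_age: float
    multipliers: np.ndarray

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        m = self.multipliers
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(
                f"multipliers must be a square matrix, got shape {m.shape}"
            )
        if not np.all(np.isfinite(m)):
            raise ValidationError("multipliers must be finite")
        if np.any(m < 0):
            raise ValidationError("multipliers must be non-negative")
        if not self.start_age > self.end_age:
            raise ValidationError(
                f"slice start_age ({self.start_age}) must exceed end_age ({self.end_age})"
            )
        if self.end_age < 0:
            raise ValidationError(f"slice end_age must be >= 0, got {self.end_age}")

    def contains(self, age: float) -> bool:
        """Half-open membership ``end_age <= age < start_age``: a boundary
        age belongs to the older slice (ages increase into the past)."""
        return self.end_age <= age < self.start_age


@dataclass
class LEMSpec:
    """A landscape evolution model: bioregions + time-sliced dispersal multipliers."""

    name: str
    bioregions: list[Bioregion]
    slices: list[TimeSlice]
    max_range_size: int = 0  # 0 -> defaults to n_areas in __post_init__

    def __post_init__(self) -> None:
        if not self.bioregions:
            raise ValidationError("bioregions: at least one region is required")
        codes = [b.code for b in self.bioregions]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"bioregions: duplicate region codes {dupes}")
        indices = [b.index for b in self.bioregions]
        if sorted(indices) != list(range(len(self.bioregions))):
            raise ValidationError("bioregions: indices must be contiguous from 0")
        if self.max_range_size == 0:
            self.max_range_size = self.n_areas
        if not 1 <= self.max_range_size <= self.n_areas:
            raise ValidationError(
                f"max_range_size must be in [1, {self.n_areas}], got {self.max_range_size}"
            )
        if not self.slices:
            raise ValidationError("slices: at least one time slice is required")
        for i, sl in enumerate(self.slices):
            if sl.multipliers.shape != (self.n_areas, self.n_areas):
                raise ValidationError(
                    f"slices[{i}].multipliers has shape {sl.multipliers.shape}, "
                    f"expected ({self.n_areas}, {self.n_areas})"
                )
        for older, younger in zip(self.slices, self.slices[1:]):
            if older.end_age != younger.start_age:
                raise ValidationError(
                    "slices must tile contiguously oldest to youngest: "
                    f"slice ending at {older.end_age} Ma followed by slice "
                    f"starting at {younger.start_age} Ma"
                )
        if self.slices[-1].end_age != 0.0:
            raise ValidationError(
                f"last slice must end at 0 Ma, got {self.slices[-1].end_age}"
            )

    @property
    def n_areas(self) -> int:
        return len(self.bioregions)

    @property
    def codes(self) -> list[str]:
        return [b.code for b in self.bioregions]

    def states(self) -> list[RangeState]:
        return enumerate_ranges(self.n_areas, self.max_range_size)

    def slice_index_for_age(self, age: float) -> int:
        """Index of the slice containing ``age``; the oldest slice is open
        toward the past (its declared start is treated as unbounded)."""
        if age < 0:
            raise ValidationError(f"age must be >= 0, got {age}")
        for i, sl in enumerate(self.slices):
            if sl.contains(age):
                return i
        if age > self.slices[0].end_age:
            return 0  # older than the declared start of the oldest slice: clamp
        raise ValidationError(f"no slice contains age {age}")

    def boundaries(self, root_age: float) -> list[float]:
        """Slice boundary ages clamped to [0, root_age], oldest first."""
        ages = [min(self.slices[0].start_age, root_age)]
        for sl in self.slices:
            if sl.end_age < root_age:
                ages.append(sl.end_age)
        if ages[-1] != 0.0:
            ages.append(0.0)
        return ages

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "regions": [{"code": b.code, "name": b.name} for b in self.bioregions],
            "max_range_size": self.max_range_size,
            "slices": [
                {
                    "start_age": "inf" if math.isinf(s.start_age) else float(s.start_age),
                    "end_age": float(s.end_age),
                    "matrix": s.multipliers.tolist(),
                }
                for s in self.slices
            ],
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_lem(config: Mapping) -> LEMSpec:
    """Build and validate a :class:`LEMSpec` from a structured description.

    The description (typically parsed from YAML/JSON) has keys ``name``,
    ``regions`` (list of ``{code, name}``), optional ``max_range_size`` and
    either ``slices`` (list of ``{start_age, end_age, matrix}``) or, for a
    single-slice stepping-stone model, a top-level ``adjacency`` matrix whose
    0/1 entries become the multipliers of one unbounded slice.
    """
    if "regions" not in config:
        raise ValidationError("regions: missing required field")
    regions = []
    for i, r in enumerate(config["regions"]):
        if isinstance(r, str):
            code, rname = r, r
        else:
            code, rname = r["code"], r.get("name", r["code"])
        regions.append(Bioregion(code=str(code), name=str(rname), index=i))

    name = str(config.get("name", "LEM"))
    max_range_size = int(config.get("max_range_size", 0) or 0)

    if "adjacency" in config and "slices" in config:
        raise ValidationError("config: give either 'adjacency' or 'slices', not both")
    if "adjacency" in config:
        adj = np.asarray(config["adjacency"], dtype=float)
        if not np.all(np.isin(adj, (0.0, 1.0))):
            raise ValidationError("adjacency: entries must be 0 or 1")
        slices = [TimeSlice(start_age=math.inf, end_age=0.0, multipliers=adj)]
    elif "slices" in config:
        slices = []
        for i, s in enumerate(config["slices"]):
            start = s["start_age"]
            start = math.inf if start in ("inf", None) else float(start)
            slices.append(
                TimeSlice(
                    start_age=start,
                    end_age=float(s["end_age"]),
                    multipliers=np.asarray(s["matrix"], dtype=float),
                )
            )
    else:
        raise ValidationError("config: missing 'slices' (or 'adjacency') field")

    return LEMSpec(name=name, bioregions=regions, slices=slices,
                   max_range_size=max_range_size)


def load_lem(path) -> LEMSpec:
    """Read a LEM config from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        return build_lem(yaml.safe_load(fh))


def stepping_stone_chain(codes: Sequence[str], name: str = "chain") -> LEMSpec:
    """Convenience: a linear-chain stepping-stone LEM over the given regions."""
    n = len(codes)
    adj = np.zeros((n, n))
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1.0
    return build_lem({"name": name, "regions": list(codes), "adjacency": adj.tolist()})


def range_label(state: RangeState, lem: LEMSpec, null_token: str = NULL_TOKEN) -> str:
    """Human-readable label: concatenated region codes in index order."""
    if state.is_null:
        return null_token
    areas = sorted(state.areas)
    if areas[-1] >= lem.n_areas:
        raise ValidationError(
            f"state references area index {areas[-1]} but the LEM has "
            f"{lem.n_areas} regions"
        )
    return "".join(lem.codes[i] for i in areas)


def parse_range_label(label: str, lem: LEMSpec, null_token: str = NULL_TOKEN) -> RangeState:
    if label == null_token:
        return NULL_RANGE
    try:
        return RangeState.from_areas(lem.codes.index(c) for c in label)
    except ValueError:
        raise ValidationError(f"label {label!r} contains a code not in {lem.codes}")


# -- range matrix I/O ----------------------------------------------------


def read_range_matrix(path, lem: LEMSpec, sep: str = None) -> dict[str, RangeState]:
    """Read a species x bioregion presence/absence matrix.

    Delimited text with a header row; first column holds species names, the
    remaining columns are region codes matching the LEM.  Cells are 0/1.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    cols = list(df.columns[1:])
    if cols != lem.codes:
        raise ValidationError(
            f"range-matrix columns {cols} do not match LEM regions {lem.codes}"
        )
    vals = df[cols].to_numpy()
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError("range-matrix cells must be 0 or 1")
    out: dict[str, RangeState] = {}
    for sp, row in zip(df.iloc[:, 0].astype(str), vals):
        if sp in out:
            raise ValidationError(f"duplicate species {sp!r} in range matrix")
        out[sp] = RangeState.from_areas(np.flatnonzero(row))
    return out


def write_range_matrix(ranges: Mapping[str, RangeState], lem: LEMSpec, path) -> None:
    rows = []
    for sp, st in ranges.items():
        rows.append([sp] + [1 if i in st else 0 for i in range(lem.n_areas)])
    pd.DataFrame(rows, columns=["species"] + lem.codes).to_csv(path, index=False)
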