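"""Shared domain types and elementary interval / membrane-geometry arithmetic.

All residue coordinates are 1-based and intervals are closed on both ends,
matching the UniProt TRANSMEM convention. Membrane sides are the abstract
labels ``side1``/``side2``: for a planar membrane they are the half-spaces
below and above the slab, for a spherical membrane the inside and outside of
the shell. Per-residue model confidence (pLDDT) is stored on the 0-100 scale
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

Side = Literal["side1", "side2"]
SIDES: Tuple[Side, Side] = ("side1", "side2")

Orientation = Tuple[Side, Side]


# ---------------------------------------------------------------------------
# Intervals


@dataclass(frozen=True, order=True)
class ResidueRange:
    """Closed 1-based residue interval [start, end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.start},{self.end}]"


def overlap_len(a: ResidueRange, b: ResidueRange) -> int:
    """Number of residues shared by two closed intervals (0 if disjoint)."""
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def gap_len(a: ResidueRange, b: ResidueRange) -> int:
    """Number of residues strictly between ``a`` and ``b`` (``a`` before ``b``).

    Abutting intervals have gap 0. Raises if the intervals overlap or are out
    of order, because a gap is then undefined.
    """
    if a.end >= b.start:
        raise ValueError(f"ranges {a} and {b} overlap or are out of order")
    return b.start - a.end - 1


# ---------------------------------------------------------------------------
# Segments


@dataclass(frozen=True)
class TMSegment:
    """A membrane-embedded segment with its topology.

    ``orientation`` is the ordered (entry side, exit side) pair. A true
    transmembrane segment crosses the bilayer, so its entry and exit sides
    differ; a re-entrant segment dips into the membrane and returns, so they
    are equal. ``kind='raw'`` marks segments as reported by the upstream
    placement tool, before classification.
    """

    range: ResidueRange
    orientation: Orientation
    kind: Literal["transmembrane", "re-entrant", "raw"] = "raw"
    source: str = ""

    def __post_init__(self) -> None:
        if self.orientation[0] not in SIDES or self.orientation[1] not in SIDES:
            raise ValueError(f"unknown membrane side in {self.orientation}")
        if self.kind == "re-entrant" and self.orientation[0] != self.orientation[1]:
            raise ValueError("re-entrant segment must enter and exit on the same side")
        if self.kind == "transmembrane" and self.orientation[0] == self.orientation[1]:
            raise ValueError("transmembrane segment must cross the membrane")


def reverse_orientation(orientation: Orientation) -> Orientation:
    return (orientation[1], orientation[0])


# ---------------------------------------------------------------------------
# Membrane geometry


@dataclass(frozen=True)
class MembraneGeometry:
    """Two parallel boundary planes or two concentric boundary spheres.

    Planar: boundaries are ``dot(normal, x) = o1`` and ``dot(normal, x) = o2``
    with ``o1 < o2`` and a unit ``normal``. Spherical: boundaries are spheres
    of radii ``0 < r1 < r2`` around ``center``.
    """

    variant: Literal["planar", "spherical"]
    normal: Optional[Tuple[float, float, float]] = None
    offsets: Optional[Tuple[float, float]] = None
    center: Optional[Tuple[float, float, float]] = None
    radii: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.variant == "planar":
            if self.normal is None or self.offsets is None:
                raise ValueError("planar geometry needs normal and offsets")
            n = np.asarray(self.normal, dtype=float)
            norm = float(np.linalg.norm(n))
            if norm == 0.0:
                raise ValueError("zero-length membrane normal")
            if abs(norm - 1.0) > 1e-9:
                raise ValueError(f"membrane normal must be unit length, |n|={norm!r}")
            o1, o2 = self.offsets
            if not o2 - o1 > 0:
                raise ValueError(f"boundary offsets must satisfy o1 < o2, got {self.offsets}")
        elif self.variant == "spherical":
            if self.center is None or self.radii is None:
                raise ValueError("spherical geometry needs center and radii")
            r1, r2 = self.radii
            if not 0 < r1 < r2:
                raise ValueError(f"radii must satisfy 0 < r1 < r2, got {self.radii}")
        else:
            raise ValueError(f"unknown geometry variant {self.variant!r}")

    @property
    def thickness(self) -> float:
        if self.variant == "planar":
            return self.offsets[1] - self.offsets[0]
        return self.radii[1] - self.radii[0]

    def side_of(self, point: Sequence[float]) -> Side:
        """Which membrane side a point outside the slab/shell lies on.

        side1 = below the lower plane / inside the inner sphere;
        side2 = above the upper plane / outside the outer sphere. Points
        inside the membrane are assigned to the nearer boundary's side.
        """
        p = np.asarray(point, dtype=float)
        if self.variant == "planar":
            proj = float(np.dot(np.asarray(self.normal), p))
            mid = 0.5 * (self.offsets[0] + self.offsets[1])
            return "side1" if proj < mid else "side2"
        r = float(np.linalg.norm(p - np.asarray(self.center)))
        mid = 0.5 * (self.radii[0] + self.radii[1])
        return "side1" if r < mid else "side2"


def boundary_distance(
    point: Sequence[float], geometry: MembraneGeometry, which: int
) -> float:
    """Unsigned distance (Å) from a point to membrane boundary 1 or 2."""
    if which not in (1, 2):
        raise ValueError(f"which must be 1 or 2, got {which}")
    p = np.asarray(point, dtype=float)
    if geometry.variant == "planar":
        proj = float(np.dot(np.asarray(geometry.normal, dtype=float), p))
        return abs(proj - geometry.offsets[which - 1])
    r = float(np.linalg.norm(p - np.asarray(geometry.center, dtype=float)))
    return abs(r - geometry.radii[which - 1])


# ---------------------------------------------------------------------------
# Structures


@dataclass(frozen=True)
class Residue:
    """One residue: its (original) number, main-chain atoms and confidence."""

    number: int
    atoms: Dict[str, Tuple[float, float, float]]
    plddt: float

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.number} has no main-chain atoms")
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"pLDDT {self.plddt} outside [0, 100]")


@dataclass(frozen=True)
class StructureModel:
    """An ordered single-chain model with per-residue confidence.

    Residue numbers are strictly increasing but may have gaps: trimming and
    domain extraction never renumber, so coordinates from sub-models remain
    directly comparable to the full model.
    """

    protein_id: str
    residues: Tuple[Residue, ...]

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> List[int]:
        return [r.number for r in self.residues]

    def residue_by_number(self, number: int) -> Optional[Residue]:
        # residues are sorted by number; binary search
        lo, hi = 0, len(self.residues)
        while lo < hi:
            mid = (lo + hi) // 2
            if self.residues[mid].number < number:
                lo = mid + 1
            else:
                hi = mid
        if lo < len(self.residues) and self.residues[lo].number == number:
            return self.residues[lo]
        return None

    def residues_in(self, rng: ResidueRange) -> List[Residue]:
        return [r for r in self.residues if rng.start <= r.number <= rng.end]

    def span(self) -> Optional[ResidueRange]:
        if not self.residues:
            return None
        return ResidueRange(self.residues[0].number, self.residues[-1].number)


@dataclass(frozen=True)
class PAEMatrix:
    """L x L predicted-aligned-error matrix (Å); may be asymmetric as exported."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"PAE matrix must be square, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("PAE matrix has negative entries")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def symmetrized(self) -> np.ndarray:
        """Per-pair error as min of the two export directions."""
        return np.minimum(self.values, self.values.T)


@dataclass(frozen=True)
class MembranePlacement:
    """A structure positioned in a membrane, with the raw embedded segments."""

    structure: StructureModel
    geometry: MembraneGeometry
    raw_segments: Tuple[TMSegment, ...]
    membrane_type: str = "undefined"

    def __post_init__(self) -> None:
        prev: Optional[TMSegment] = None
        for seg in self.raw_segments:
            if prev is not None:
                if seg.range.start <= prev.range.end:
                    raise ValueError(
                        f"raw segments must be sorted and non-overlapping: "
                        f"{prev.range} then {seg.range}"
                    )
            prev = seg


# ---------------------------------------------------------------------------
# Annotations


class AnnotationSet:
    """Per-protein, per-source sorted lists of TMS ranges."""

    def __init__(self) -> None:
        self._data: Dict[Tuple[str, str], List[ResidueRange]] = {}

    def add(self, protein_id: str, source: str, rng: ResidueRange) -> None:
        key = (protein_id, source)
        ranges = self._data.setdefault(key, [])
        if rng in ranges:
            return
        ranges.append(rng)
        ranges.sort()

    def get(self, protein_id: str, source: str) -> List[ResidueRange]:
        return list(self._data.get((protein_id, source), []))

    def proteins(self) -> List[str]:
        return sorted({pid for pid, _ in self._data})

    def sources(self) -> List[str]:
        return sorted({src for _, src in self._data})

    def items(self) -> Iterable[Tuple[Tuple[str, str], List[ResidueRange]]]:
        for key in sorted(self._data):
            yield key, list(self._data[key])

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._data == other._data


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class Config:
    """All tunable thresholds of the annotation pipeline.

    Defaults are the values of the published procedure:

    - ``pae_low_threshold``: a residue pair is "low PAE" below 12 Å.
    - ``split_min_len`` / ``split_big_len``: segments are split only above
      500 residues; the ratio bar drops from 20 to 10 above 1000.
    - ``plddt_min``: residues below pLDDT 50 (0-100 scale) are trimmed.
    - ``tms_extension``: raw segments are widened by 10 residues per side
      before geometric classification.
    - ``boundary_dist_max``: both boundary distances < 10 Å => transmembrane.
    - ``merge_gap_max``: same-orientation segments < 10 residues apart merge.
    - ``missing_gap_min`` / ``missing_halfwidth``: same-orientation pairs
      >= 15 residues apart trigger recovery of a missed crossing, inserted as
      the membrane-center residue +/- 5.
    - ``match_overlap_min``: two TMSs match when they overlap >= 10 residues.
    - ``identity_min``: alignment hits are kept at identity > 95 %.
    - ``min_fragment_len``: smallest segment a split may produce (30),
      excluding degenerate near-end split sites.
    """

    pae_low_threshold: float = 12.0
    split_min_len: int = 500
    split_big_len: int = 1000
    ratio_small: float = 20.0
    ratio_big: float = 10.0
    plddt_min: float = 50.0
    tms_extension: int = 10
    boundary_dist_max: float = 10.0
    merge_gap_max: int = 10
    missing_gap_min: int = 15
    missing_halfwidth: int = 5
    match_overlap_min: int = 10
    identity_min: float = 95.0
    min_fragment_len: int = 30

    def __post_init__(self) -> None:
        for name in (
            "pae_low_threshold", "split_min_len", "split_big_len", "ratio_small",
            "ratio_big", "plddt_min", "tms_extension", "boundary_dist_max",
            "merge_gap_max", "missing_gap_min", "missing_halfwidth",
            "match_overlap_min", "identity_min", "min_fragment_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"Config.{name} must be > 0")
        if self.ratio_small < self.ratio_big:
            raise ValueError("ratio_small must be >= ratio_big")


DEFAULT_CONFIG = Config()
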