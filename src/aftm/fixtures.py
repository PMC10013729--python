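"""Seeded synthetic fixtures: helical bundles, block PAE matrices, perturbed
placements and perturbed annotation sets.

Every generator is deterministic given its seed and emits objects satisfying
the package invariants, together with the ground truth it planted, so each
pipeline stage can be tested without any external structure, error matrix or
database download.

The structural idealisation is deliberately minimal: helices are residues on
a helical curve with the canonical axial rise of 1.5 Å per residue along the
membrane normal, with the four main-chain atoms placed on that curve close to
the CA position. This reproduces the geometry that the distance-based
classification, merging and recovery rules actually consume; it makes no
attempt at sequence realism, side chains or AlphaFold-like error statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AnnotationSet,
    MembraneGeometry,
    MembranePlacement,
    PAEMatrix,
    Residue,
    ResidueRange,
    StructureModel,
    TMSegment,
)

RISE_PER_RESIDUE = 1.5  # Å along the helix axis
HELIX_RADIUS = 2.3  # Å, CA distance from the helix axis
TURN_PER_RESIDUE = math.radians(100.0)


def _helix_atoms(axis_xy: Tuple[float, float], z: float, phase: float) -> Dict[str, Tuple[float, float, float]]:
    """Main-chain atoms near one helical-curve position."""
    atoms = {}
    # park N/C/O slightly before/after the CA along the curve
    for name, dt in (("N", -0.35), ("CA", 0.0), ("C", 0.35), ("O", 0.55)):
        ang = phase + dt * TURN_PER_RESIDUE
        atoms[name] = (
            axis_xy[0] + HELIX_RADIUS * math.cos(ang),
            axis_xy[1] + HELIX_RADIUS * math.sin(ang),
            z + dt * RISE_PER_RESIDUE,
        )
    return atoms


def default_planar_geometry(thickness: float = 30.0) -> MembraneGeometry:
    return MembraneGeometry(
        variant="planar", normal=(0.0, 0.0, 1.0), offsets=(0.0, thickness)
    )


def make_helix_bundle(
    n_helices: int,
    membrane_thickness: float = 30.0,
    loop_len: int = 8,
    seed: int = 0,
    cap_len: int = 8,
    helix_spacing: float = 10.0,
    helix_plddt: float = 95.0,
    loop_plddt: float = 80.0,
    protein_id: str = "bundle",
) -> Tuple[StructureModel, List[TMSegment], MembraneGeometry]:
    """An ideal helical bundle crossing a planar membrane slab alternately.

    Each helix rises 1.5 Å per residue along the membrane normal, so a slab of
    thickness ``d`` is crossed by ``ceil(d / 1.5)`` residues (the planted TMS);
    ``cap_len`` extra helical residues extend beyond the slab on both sides and
    ``loop_len``-residue loops connect consecutive helices outside the
    membrane. Residues are placed half a rise off the boundaries so none sits
    exactly on a boundary plane. Returns (model, true TMS list with alternating
    orientations, geometry). The seed jitters helix phases only; geometry and
    truth ranges are seed-independent.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if membrane_thickness <= 0:
        raise ValueError("membrane_thickness must be > 0")
    if loop_len < 1 or cap_len < 1:
        raise ValueError("loop_len and cap_len must be >= 1")

    rng = np.random.default_rng(seed)
    d = membrane_thickness
    n_cross = math.ceil(d / RISE_PER_RESIDUE)
    geometry = default_planar_geometry(d)

    residues: List[Residue] = []
    truth: List[TMSegment] = []
    number = 0
    z_lo = -cap_len * RISE_PER_RESIDUE + RISE_PER_RESIDUE / 2.0
    helix_len = 2 * cap_len + n_cross

    for h in range(n_helices):
        going_up = h % 2 == 0
        axis_xy = (h * helix_spacing, 0.0)
        phase0 = float(rng.uniform(0, 2 * math.pi))
        first_tm: Optional[int] = None
        last_tm: Optional[int] = None
        for j in range(helix_len):
            number += 1
            z = z_lo + j * RISE_PER_RESIDUE
            if not going_up:
                z = (d - RISE_PER_RESIDUE / 2.0 + cap_len * RISE_PER_RESIDUE) - j * RISE_PER_RESIDUE
            atoms = _helix_atoms(axis_xy, z, phase0 + j * TURN_PER_RESIDUE)
            residues.append(Residue(number=number, atoms=atoms, plddt=helix_plddt))
            if 0.0 < z < d:
                first_tm = number if first_tm is None else first_tm
                last_tm = number
        orientation = ("side1", "side2") if going_up else ("side2", "side1")
        truth.append(
            TMSegment(
                range=ResidueRange(first_tm, last_tm),
                orientation=orientation,
                kind="transmembrane",
                source="truth",
            )
        )
        if h < n_helices - 1:
            # loop outside the slab, on the exit side of this helix
            loop_z = (
                d + (cap_len + 2) * RISE_PER_RESIDUE
                if going_up
                else -(cap_len + 2) * RISE_PER_RESIDUE
            )
            x0 = axis_xy[0]
            x1 = (h + 1) * helix_spacing
            for k in range(loop_len):
                number += 1
                frac = (k + 1) / (loop_len + 1)
                bump = 3.0 * math.sin(math.pi * frac)
                z = loop_z + bump if going_up else loop_z - bump
                atoms = {
                    "N": (x0 + frac * (x1 - x0) - 0.4, 0.0, z),
                    "CA": (x0 + frac * (x1 - x0), 0.0, z),
                    "C": (x0 + frac * (x1 - x0) + 0.4, 0.0, z),
                    "O": (x0 + frac * (x1 - x0) + 0.6, 0.6, z),
                }
                residues.append(Residue(number=number, atoms=atoms, plddt=loop_plddt))

    model = StructureModel(protein_id=protein_id, residues=tuple(residues))
    return model, truth, geometry


def make_reentrant_hairpin(
    membrane_thickness: float = 30.0,
    depth: float = 12.0,
    cap_len: int = 8,
    seed: int = 0,
    protein_id: str = "hairpin",
) -> Tuple[StructureModel, TMSegment, MembraneGeometry]:
    """A membrane-dipping hairpin entering and exiting on the same side.

    The chain climbs from below the slab to ``depth`` Å above the lower
    boundary (strictly less than thickness, so the far boundary is never
    approached) and descends back. Returns the model, the raw embedded
    segment (entry = exit = side1) and the geometry.
    """
    if not 0 < depth < membrane_thickness:
        raise ValueError("depth must be inside (0, membrane_thickness)")
    rng = np.random.default_rng(seed)
    geometry = default_planar_geometry(membrane_thickness)
    phase0 = float(rng.uniform(0, 2 * math.pi))

    n_up = math.ceil(depth / RISE_PER_RESIDUE) + cap_len
    zs: List[float] = []
    z0 = depth - (n_up - 1) * RISE_PER_RESIDUE - RISE_PER_RESIDUE / 2.0
    for j in range(n_up):
        zs.append(z0 + j * RISE_PER_RESIDUE)
    for j in range(1, n_up + 1):  # back down, second leg offset in x
        zs.append(zs[n_up - 1] - j * RISE_PER_RESIDUE)

    residues: List[Residue] = []
    first_in: Optional[int] = None
    last_in: Optional[int] = None
    for i, z in enumerate(zs, start=1):
        leg2 = i > n_up
        atoms = _helix_atoms((6.0 if leg2 else 0.0, 0.0), z, phase0 + i * TURN_PER_RESIDUE)
        residues.append(Residue(number=i, atoms=atoms, plddt=90.0))
        if 0.0 < z < membrane_thickness:
            first_in = i if first_in is None else first_in
            last_in = i
    model = StructureModel(protein_id=protein_id, residues=tuple(residues))
    segment = TMSegment(
        range=ResidueRange(first_in, last_in),
        orientation=("side1", "side1"),
        kind="raw",
        source="truth",
    )
    return model, segment, geometry


def make_pae_blocks(
    domain_lengths: Sequence[int],
    intra_value: float = 4.0,
    inter_value: float = 20.0,
    flip_fraction: float = 0.0,
    seed: int = 0,
) -> PAEMatrix:
    """Block-structured symmetric PAE matrix with optional noise flips.

    Within-domain pairs get ``intra_value``, cross-domain pairs
    ``inter_value``; a seeded ``flip_fraction`` of unordered pairs is swapped
    across the low-PAE line (intra pairs to ``inter_value`` and vice versa),
    applied symmetrically. Diagonal is 0.
    """
    if intra_value < 0 or inter_value < 0:
        raise ValueError("PAE values must be >= 0")
    if not 0.0 <= flip_fraction < 1.0:
        raise ValueError("flip_fraction must be in [0, 1)")
    L = int(sum(domain_lengths))
    values = np.full((L, L), inter_value, dtype=float)
    pos = 0
    for length in domain_lengths:
        values[pos : pos + length, pos : pos + length] = intra_value
        pos += length
    np.fill_diagonal(values, 0.0)

    if flip_fraction > 0.0:
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(L, k=1)
        n_pairs = len(iu)
        n_flip = int(round(flip_fraction * n_pairs))
        chosen = rng.choice(n_pairs, size=n_flip, replace=False)
        fi, fj = iu[chosen], ju[chosen]
        flipped = np.where(values[fi, fj] == intra_value, inter_value, intra_value)
        values[fi, fj] = flipped
        values[fj, fi] = flipped
    return PAEMatrix(values)


def make_placement(
    model: StructureModel,
    truth: Sequence[TMSegment],
    geometry: MembraneGeometry,
    drop_indices: Sequence[int] = (),
    split_spec: Optional[Dict[int, int]] = None,
    seed: int = 0,
    membrane_type: str = "undefined",
) -> MembranePlacement:
    """Raw placement emulating upstream misses and broken helices.

    ``drop_indices`` removes those crossings from the raw output (a missed
    TMS); ``split_spec`` maps a crossing index to a gap width, breaking that
    crossing into two raw sub-segments around a seed-jittered midpoint (a
    broken/kinked helix reported as two pieces).
    """
    split_spec = dict(split_spec or {})
    rng = np.random.default_rng(seed)
    for idx in list(drop_indices) + list(split_spec):
        if not 0 <= idx < len(truth):
            raise ValueError(f"crossing index {idx} out of range")

    raw: List[TMSegment] = []
    for idx, seg in enumerate(truth):
        if idx in drop_indices:
            continue
        if idx in split_spec:
            gap = split_spec[idx]
            length = seg.range.length
            if gap < 1 or gap > length - 2:
                raise ValueError(f"split gap {gap} impossible on {seg.range}")
            jitter = int(rng.integers(-1, 2))
            left_len = max(1, min(length - gap - 1, (length - gap) // 2 + jitter))
            left = ResidueRange(seg.range.start, seg.range.start + left_len - 1)
            right = ResidueRange(left.end + gap + 1, seg.range.end)
            raw.append(TMSegment(left, seg.orientation, kind="raw", source="sim"))
            raw.append(TMSegment(right, seg.orientation, kind="raw", source="sim"))
        else:
            raw.append(TMSegment(seg.range, seg.orientation, kind="raw", source="sim"))
    raw.sort(key=lambda s: s.range.start)
    return MembranePlacement(
        structure=model,
        geometry=geometry,
        raw_segments=tuple(raw),
        membrane_type=membrane_type,
    )


@dataclass(frozen=True)
class Perturbation:
    """Per-source, per-protein annotation perturbation.

    ``shift``: magnitude (residues) applied to every range, sign drawn per
    range from the seed; ``drop``: 0-based indices of ranges to remove;
    ``add``: spurious ranges to append.
    """

    shift: int = 0
    drop: Tuple[int, ...] = ()
    add: Tuple[ResidueRange, ...] = ()


def make_annotation_sets(
    truth: Dict[str, List[ResidueRange]],
    specs: Dict[str, Dict[str, Perturbation]],
    seed: int = 0,
) -> AnnotationSet:
    """Per-source annotation sets derived from a shared ground truth.

    ``specs`` maps source label -> protein id -> Perturbation; proteins not
    named by a source get the unperturbed truth. The planted three-way
    category of each protein follows in closed form from the spec (a shift
    larger than range length minus the match threshold breaks consistency;
    drops and adds change counts and hence break it too).
    """
    rng = np.random.default_rng(seed)
    out = AnnotationSet()
    for source in sorted(specs):
        per_protein = specs[source]
        for pid in sorted(truth):
            ranges = list(truth[pid])
            pert = per_protein.get(pid, Perturbation())
            kept = [r for i, r in enumerate(ranges) if i not in pert.drop]
            for r in kept:
                if pert.shift:
                    sign = 1 if rng.integers(0, 2) else -1
                    delta = sign * pert.shift
                    if r.start + delta < 1:
                        delta = pert.shift
                    out.add(pid, source, ResidueRange(r.start + delta, r.end + delta))
                else:
                    out.add(pid, source, r)
            for r in pert.add:
                out.add(pid, source, r)
    return out
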