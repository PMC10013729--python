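"""Readers and writers for every external representation the pipeline touches.

Formats
-------
- Coordinate files: PDB or mmCIF, single chain, per-residue confidence in the
  temperature-factor column (Bio.PDB does the parsing).
- Pair-error matrices: the AlphaFold PAE JSON export, either the nested
  ``predicted_aligned_error`` matrix or the older flat
  ``residue1``/``residue2``/``distance`` triplet schema.
- Membrane placements: a package-native, versioned text schema
  (``AFTM-PLACEMENT/1``) holding the boundary geometry and the raw embedded
  segments, with a reference to the coordinate file. The native schema exists
  because upstream placement tools emit a mix of dummy boundary atoms and
  free-text reports that varies between versions.
- Alignment hits: BLAST/DIAMOND 12-column tabular output (outfmt 6),
  optionally extended with the aligned query/subject sequences.
- Annotations: 4-column TSV (protein id, source, start, end).
- Config: flat YAML mirroring the Config fields.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import yaml

from .core import (
    AnnotationSet,
    Config,
    MembraneGeometry,
    MembranePlacement,
    PAEMatrix,
    Residue,
    ResidueRange,
    StructureModel,
    TMSegment,
    MAIN_CHAIN_ATOMS,
)

PLACEMENT_MAGIC = "AFTM-PLACEMENT/1"

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Structures (PDB / mmCIF)


def read_structure(path: PathLike, confidence_scale: str = "auto") -> StructureModel:
    """Read a single-chain coordinate file into a StructureModel.

    The temperature-factor column carries the per-residue confidence (pLDDT).
    ``confidence_scale`` is ``'auto'`` (0-1 if every value <= 1), ``'0-1'`` or
    ``'0-100'``; values are normalised to 0-100 internally.
    """
    if confidence_scale not in ("auto", "0-1", "0-100"):
        raise ValueError(f"unknown confidence_scale {confidence_scale!r}")
    path = Path(path)
    from Bio.PDB import MMCIFParser, PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() in (".cif", ".mmcif"):
            structure = MMCIFParser(QUIET=True).get_structure(path.stem, str(path))
        else:
            structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))

    model = next(structure.get_models())
    chains = list(model.get_chains())
    if len(chains) != 1:
        raise ValueError(f"{path}: expected a single chain, found {len(chains)}")
    chain = chains[0]

    raw: List[Tuple[int, dict, float]] = []
    seen = set()
    for res in chain.get_residues():
        hetflag, resseq, _icode = res.get_id()
        if hetflag.strip():
            continue
        if resseq in seen:
            raise ValueError(f"{path}: duplicate residue number {resseq}")
        seen.add(resseq)
        atoms = {}
        bvals = []
        for atom in res.get_atoms():
            name = atom.get_name()
            if name in MAIN_CHAIN_ATOMS:
                atoms[name] = tuple(float(x) for x in atom.coord)
            b = atom.get_bfactor()
            if b is None:
                raise ValueError(f"{path}: missing temperature factor on {name}")
            bvals.append(float(b))
        if not atoms:
            continue
        raw.append((int(resseq), atoms, float(np.mean(bvals))))

    raw.sort(key=lambda t: t[0])
    confidences = [b for _, _, b in raw]
    scale01 = confidence_scale == "0-1" or (
        confidence_scale == "auto" and confidences and max(confidences) <= 1.0
    )
    residues = tuple(
        Residue(number=n, atoms=a, plddt=b * 100.0 if scale01 else b)
        for n, a, b in raw
    )
    return StructureModel(protein_id=path.stem, residues=residues)


def write_structure(model: StructureModel, path: PathLike) -> None:
    """Write a StructureModel as a minimal single-chain PDB file.

    Confidence is stored in the B-factor column on the 0-100 scale; residues
    are written as alanines (the pipeline never uses residue identity).
    """
    path = Path(path)
    lines = []
    serial = 1
    for res in model.residues:
        for name in MAIN_CHAIN_ATOMS:
            if name not in res.atoms:
                continue
            x, y, z = res.atoms[name]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} ALA A{res.number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{res.plddt:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PAE matrices (AlphaFold JSON export)


def read_pae(path: PathLike) -> PAEMatrix:
    """Read an AlphaFold PAE export (nested matrix or flat triplet schema)."""
    path = Path(path)
    payload = json.loads(path.read_text())
    if isinstance(payload, list):
        if len(payload) != 1 or not isinstance(payload[0], dict):
            raise ValueError(f"{path}: unrecognised PAE payload")
        payload = payload[0]
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: unrecognised PAE payload")

    matrix = None
    for key in ("predicted_aligned_error", "pae"):
        if key in payload:
            matrix = payload[key]
            break
    if matrix is not None:
        lengths = {len(row) for row in matrix}
        if len(lengths) > 1 or (matrix and len(matrix) not in lengths):
            raise ValueError(f"{path}: ragged or non-square PAE matrix")
        values = np.asarray(matrix, dtype=float)
    elif {"residue1", "residue2", "distance"} <= payload.keys():
        r1 = np.asarray(payload["residue1"], dtype=int)
        r2 = np.asarray(payload["residue2"], dtype=int)
        d = np.asarray(payload["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(d)):
            raise ValueError(f"{path}: triplet arrays have unequal lengths")
        L = int(max(r1.max(), r2.max()))
        if len(d) != L * L:
            raise ValueError(f"{path}: triplet schema does not cover an LxL matrix")
        values = np.zeros((L, L), dtype=float)
        values[r1 - 1, r2 - 1] = d
    else:
        raise ValueError(f"{path}: no PAE matrix found in payload")
    return PAEMatrix(values)  # validates shape and non-negativity


def write_pae(pae: PAEMatrix, path: PathLike) -> None:
    payload = {"predicted_aligned_error": pae.values.tolist(),
               "max_predicted_aligned_error": float(pae.values.max(initial=0.0))}
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Membrane placements (native schema)


def write_placement(placement: MembranePlacement, path: PathLike,
                    structure_path: Optional[PathLike] = None) -> None:
    """Write a placement in the native ``AFTM-PLACEMENT/1`` schema.

    If ``structure_path`` is given the structure is also written there and the
    placement references it; otherwise a sibling ``<stem>.pdb`` is written.
    """
    path = Path(path)
    if structure_path is None:
        structure_path = path.with_suffix(".pdb")
    structure_path = Path(structure_path)
    write_structure(placement.structure, structure_path)
    try:
        ref = structure_path.relative_to(path.parent)
    except ValueError:
        ref = structure_path

    g = placement.geometry
    lines = [
        PLACEMENT_MAGIC,
        f"protein\t{placement.structure.protein_id}",
        f"structure\t{ref}",
        f"membrane_type\t{placement.membrane_type}",
        f"geometry\t{g.variant}",
    ]
    if g.variant == "planar":
        lines.append("normal\t" + "\t".join(f"{v:.9g}" for v in g.normal))
        lines.append("offsets\t" + "\t".join(f"{v:.9g}" for v in g.offsets))
    else:
        lines.append("center\t" + "\t".join(f"{v:.9g}" for v in g.center))
        lines.append("radii\t" + "\t".join(f"{v:.9g}" for v in g.radii))
    lines.append("segments\tstart\tend\tentry\texit")
    for seg in placement.raw_segments:
        lines.append(
            f"segment\t{seg.range.start}\t{seg.range.end}"
            f"\t{seg.orientation[0]}\t{seg.orientation[1]}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_placement(path: PathLike) -> MembranePlacement:
    """Read a native-schema placement file (and the structure it references)."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or lines[0].strip() != PLACEMENT_MAGIC:
        raise ValueError(f"{path}: missing {PLACEMENT_MAGIC} header")

    fields = {}
    segments: List[TMSegment] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        key = parts[0]
        if key == "segment":
            if len(parts) != 5:
                raise ValueError(f"{path}: malformed segment line {ln!r}")
            rng = ResidueRange(int(parts[1]), int(parts[2]))
            segments.append(TMSegment(rng, (parts[3], parts[4]), kind="raw"))
        elif key == "segments":
            continue
        else:
            fields[key] = parts[1:]

    variant = fields.get("geometry", [None])[0]
    if variant == "planar":
        geometry = MembraneGeometry(
            variant="planar",
            normal=tuple(float(v) for v in fields["normal"]),
            offsets=tuple(float(v) for v in fields["offsets"]),
        )
    elif variant == "spherical":
        geometry = MembraneGeometry(
            variant="spherical",
            center=tuple(float(v) for v in fields["center"]),
            radii=tuple(float(v) for v in fields["radii"]),
        )
    else:
        raise ValueError(f"{path}: unknown geometry variant {variant!r}")

    structure_ref = fields.get("structure", [None])[0]
    if structure_ref is None:
        raise ValueError(f"{path}: missing structure reference")
    structure_path = Path(structure_ref)
    if not structure_path.is_absolute():
        structure_path = path.parent / structure_path
    structure = read_structure(structure_path, confidence_scale="0-100")
    protein_id = fields.get("protein", [structure.protein_id])[0]
    structure = StructureModel(protein_id=protein_id, residues=structure.residues)

    segments.sort(key=lambda s: s.range.start)
    return MembranePlacement(
        structure=structure,
        geometry=geometry,
        raw_segments=tuple(segments),
        membrane_type=fields.get("membrane_type", ["undefined"])[0],
    )


# ---------------------------------------------------------------------------
# Alignment hits (BLAST/DIAMOND tabular)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of BLAST/DIAMOND tabular output (outfmt 6).

    ``qseq``/``sseq`` hold the aligned sequences with gap characters when the
    search was run with the extended output format; they enable per-column
    coordinate projection across indels.
    """

    query_id: str
    subject_id: str
    identity: float
    align_len: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float = 0.0
    bitscore: float = 0.0
    qseq: Optional[str] = None
    sseq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(f"qstart {self.qstart} > qend {self.qend}")
        if self.sstart > self.send:
            raise ValueError(f"sstart {self.sstart} > send {self.send}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if (self.qseq is None) != (self.sseq is None):
            raise ValueError("qseq and sseq must be given together")
        if self.qseq is not None and len(self.qseq) != len(self.sseq):
            raise ValueError("aligned sequences must have equal length")


def read_hits(path: PathLike) -> List[AlignmentHit]:
    """Parse 12-column BLAST/DIAMOND tabular output (+ optional qseq/sseq)."""
    hits: List[AlignmentHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise ValueError(f"{path}:{lineno}: expected >= 12 columns, got {len(cols)}")
        try:
            hit = AlignmentHit(
                query_id=cols[0],
                subject_id=cols[1],
                identity=float(cols[2]),
                align_len=int(cols[3]),
                qstart=int(cols[6]),
                qend=int(cols[7]),
                sstart=int(cols[8]),
                send=int(cols[9]),
                evalue=float(cols[10]),
                bitscore=float(cols[11]),
                qseq=cols[12] if len(cols) > 13 else None,
                sseq=cols[13] if len(cols) > 13 else None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hits(hits: List[AlignmentHit], path: PathLike) -> None:
    lines = []
    for h in hits:
        cols = [h.query_id, h.subject_id, f"{h.identity:.1f}", str(h.align_len),
                "0", "0", str(h.qstart), str(h.qend), str(h.sstart), str(h.send),
                f"{h.evalue:g}", f"{h.bitscore:g}"]
        if h.qseq is not None:
            cols += [h.qseq, h.sseq]
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Annotation tables


def write_annotations(ann: AnnotationSet, path: PathLike) -> None:
    """Write a 4-column TSV sorted by protein id, source, start."""
    lines = ["protein_id\tsource\tstart\tend"]
    for (pid, source), ranges in ann.items():
        for rng in ranges:
            lines.append(f"{pid}\t{source}\t{rng.start}\t{rng.end}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: PathLike) -> AnnotationSet:
    ann = AnnotationSet()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if lineno == 1 and cols[:2] == ["protein_id", "source"]:
            continue
        if len(cols) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
        try:
            rng = ResidueRange(int(cols[2]), int(cols[3]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        ann.add(cols[0], cols[1], rng)
    return ann


# ---------------------------------------------------------------------------
# Config


def read_config(path: PathLike) -> Config:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return Config(**payload)


def write_config(cfg: Config, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))
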