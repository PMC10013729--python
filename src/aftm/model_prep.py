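"""Model preprocessing before membrane placement.

Annotated N-terminal peptides (signal / mitochondrial transit peptides) and
low-confidence residues are removed before a model is positioned in the
membrane, and domain sub-models are extracted for the per-domain track. Every
operation preserves the original residue numbering, so TMS coordinates from
trimmed or per-domain models are directly comparable to full-model and
sequence-database coordinates. Trimming may fragment the chain; fragments stay
in one model with numbering gaps.
"""

from __future__ import annotations

from typing import Iterable, List

from .core import Config, DEFAULT_CONFIG, ResidueRange, StructureModel


def strip_annotated_peptides(
    model: StructureModel, peptide_ranges: Iterable[ResidueRange]
) -> StructureModel:
    """Remove residues inside any annotated peptide range.

    Ranges must lie within the model's residue numbering span; survivors keep
    their numbers.
    """
    ranges = list(peptide_ranges)
    span = model.span()
    for rng in ranges:
        if span is None or rng.start < span.start or rng.end > span.end:
            raise ValueError(f"peptide range {rng} outside model span {span}")
    kept = tuple(
        r for r in model.residues
        if not any(rng.contains(r.number) for rng in ranges)
    )
    return StructureModel(protein_id=model.protein_id, residues=kept)


def trim_low_plddt(model: StructureModel, cfg: Config = DEFAULT_CONFIG) -> StructureModel:
    """Drop residues whose confidence is below ``cfg.plddt_min`` (0-100 scale)."""
    kept = tuple(r for r in model.residues if r.plddt >= cfg.plddt_min)
    return StructureModel(protein_id=model.protein_id, residues=kept)


def extract_domain(model: StructureModel, domain: ResidueRange) -> StructureModel:
    """Sub-model containing exactly the residues in ``domain``, numbering kept."""
    kept = tuple(r for r in model.residues if domain.contains(r.number))
    if not kept:
        raise ValueError(f"domain {domain} contains no residues of {model.protein_id}")
    return StructureModel(protein_id=model.protein_id, residues=kept)
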