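"""Multi-source comparison of TMS annotation sets.

Two TMSs from different sources match when they overlap by at least 10
residues; two sources annotate a protein consistently when their TMS lists can
be matched one-to-one completely (which implies equal counts; two empty lists
are vacuously consistent). On top of this, per-protein three-way consistency
categories, a single-pass benchmark classification, missed-TMS counts and TMS
count cross-tabulations are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import AnnotationSet, Config, DEFAULT_CONFIG, ResidueRange, overlap_len

logger = logging.getLogger("aftm")

CATEGORY_LABELS = ("AUH", "AU\\H", "AH\\U", "HU\\A", "A\\U\\H")


@dataclass(frozen=True)
class ComparisonRecord:
    protein_id: str
    counts: Dict[str, int]
    pair_consistent: Dict[Tuple[str, str], bool]
    category: str


def match_sets(
    a: Sequence[ResidueRange],
    b: Sequence[ResidueRange],
    cfg: Config = DEFAULT_CONFIG,
) -> Tuple[bool, List[Tuple[ResidueRange, ResidueRange]]]:
    """Greedy one-to-one matching of two TMS lists.

    Candidate pairs are taken in order of descending overlap (ties: earlier
    start in ``a``, then in ``b``). The sources are consistent iff every range
    in both lists ends up paired with overlap >= ``cfg.match_overlap_min``.
    """
    candidates = []
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            ov = overlap_len(ra, rb)
            if ov >= cfg.match_overlap_min:
                candidates.append((-ov, ra.start, rb.start, i, j))
    candidates.sort()

    used_a: set = set()
    used_b: set = set()
    pairing: List[Tuple[ResidueRange, ResidueRange]] = []
    for _negov, _sa, _sb, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairing.append((a[i], b[j]))
    consistent = len(used_a) == len(a) and len(used_b) == len(b)
    return consistent, pairing


def categorize(
    ann_a: Sequence[ResidueRange],
    ann_u: Sequence[ResidueRange],
    ann_h: Sequence[ResidueRange],
    cfg: Config = DEFAULT_CONFIG,
) -> str:
    """Three-way consistency category for one protein.

    ``AUH`` when all three pairs are consistent; a two-source label when
    exactly one pair is; ``A\\U\\H`` when none is. The non-transitive case
    (two pairs consistent but not all three) gets the lexicographically first
    consistent-pair label and is logged.
    """
    au = match_sets(ann_a, ann_u, cfg)[0]
    ah = match_sets(ann_a, ann_h, cfg)[0]
    uh = match_sets(ann_u, ann_h, cfg)[0]
    if au and ah and uh:
        return "AUH"
    labels = sorted(
        label
        for flag, label in ((ah, "AH\\U"), (au, "AU\\H"), (uh, "HU\\A"))
        if flag
    )
    if not labels:
        return "A\\U\\H"
    if len(labels) > 1:
        logger.info("non-transitive pairwise consistency; assigning %s", labels[0])
    return labels[0]


def comparison_record(
    protein_id: str,
    ann_a: Sequence[ResidueRange],
    ann_u: Sequence[ResidueRange],
    ann_h: Sequence[ResidueRange],
    cfg: Config = DEFAULT_CONFIG,
) -> ComparisonRecord:
    return ComparisonRecord(
        protein_id=protein_id,
        counts={"A": len(ann_a), "U": len(ann_u), "H": len(ann_h)},
        pair_consistent={
            ("A", "U"): match_sets(ann_a, ann_u, cfg)[0],
            ("A", "H"): match_sets(ann_a, ann_h, cfg)[0],
            ("U", "H"): match_sets(ann_u, ann_h, cfg)[0],
        },
        category=categorize(ann_a, ann_u, ann_h, cfg),
    )


def benchmark_single_pass(
    pred: Sequence[ResidueRange],
    reference_single: ResidueRange,
    cfg: Config = DEFAULT_CONFIG,
) -> str:
    """Classify a prediction against a single-TMS reference protein.

    Returns one of ``no_TM``, ``singleTM_match``, ``singleTM_unmatch``,
    ``multiple_TM``.
    """
    if len(pred) == 0:
        return "no_TM"
    if len(pred) >= 2:
        return "multiple_TM"
    if overlap_len(pred[0], reference_single) >= cfg.match_overlap_min:
        return "singleTM_match"
    return "singleTM_unmatch"


def count_missed(
    reference: Sequence[ResidueRange],
    pred: Sequence[ResidueRange],
    cfg: Config = DEFAULT_CONFIG,
) -> int:
    """Reference TMSs with no prediction overlapping >= match_overlap_min."""
    return sum(
        1
        for ref in reference
        if not any(overlap_len(ref, p) >= cfg.match_overlap_min for p in pred)
    )


def crosstab_counts(
    ann: AnnotationSet, source_x: str, source_y: str
) -> Dict[Tuple[int, int], int]:
    """Protein counts per (TMS count in source_x, TMS count in source_y) cell.

    Proteins absent from one source contribute a count of 0 there; the cell
    totals sum to the number of proteins present in either source.
    """
    table: Dict[Tuple[int, int], int] = {}
    for pid in ann.proteins():
        nx = len(ann.get(pid, source_x))
        ny = len(ann.get(pid, source_y))
        key = (nx, ny)
        table[key] = table.get(key, 0) + 1
    return table
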