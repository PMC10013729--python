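"""Correction core: raw membrane-placement segments to final TMS calls.

Upstream placement tools report membrane-embedded segments without deciding
whether a segment actually crosses the bilayer. Three geometric corrections
turn that raw output into curated transmembrane segments (TMSs):

1. *Classification*: each raw segment, widened by 10 residues on both sides,
   is a TMS only if its main-chain atoms approach both membrane boundaries to
   within 10 Å; otherwise it enters and exits on one side (re-entrant) and is
   kept on a separate track.
2. *Merging*: consecutive TMSs with the same orientation separated by fewer
   than 10 residues are joined — broken or kinked helices reported as two
   pieces become one crossing.
3. *Recovery*: two consecutive TMSs with the same orientation separated by 15
   or more residues imply an odd number of missed crossings between them; the
   gap residue closest to the membrane centre (smallest |d1 - d2| over its
   main-chain atoms) seeds one recovered TMS of up to 11 residues with the
   reversed orientation.

Finally, the full-model and per-domain tracks are combined, preferring
full-model boundaries where the two tracks agree.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence, Tuple

from .core import (
    Config,
    DEFAULT_CONFIG,
    MembranePlacement,
    ResidueRange,
    TMSegment,
    boundary_distance,
    gap_len,
    overlap_len,
    reverse_orientation,
)

logger = logging.getLogger("aftm")


def _min_boundary_distances(
    placement: MembranePlacement, residue_numbers: Sequence[int]
) -> Tuple[float, float]:
    """Min distance over the residues' main-chain atoms to each boundary."""
    d1 = d2 = math.inf
    for num in residue_numbers:
        res = placement.structure.residue_by_number(num)
        if res is None:
            continue
        for coord in res.atoms.values():
            d1 = min(d1, boundary_distance(coord, placement.geometry, 1))
            d2 = min(d2, boundary_distance(coord, placement.geometry, 2))
    return d1, d2


def classify_segment(
    placement: MembranePlacement, seg: TMSegment, cfg: Config = DEFAULT_CONFIG
) -> str:
    """Label one raw segment ``'transmembrane'`` or ``'re-entrant'``.

    The segment is extended by ``cfg.tms_extension`` residues on each side
    (in numbering space, clipped to residues that exist) and the minimum
    main-chain-atom distance to each membrane boundary is taken over the
    extended window. Both minima < ``cfg.boundary_dist_max`` => transmembrane.
    """
    lo = max(1, seg.range.start - cfg.tms_extension)
    hi = seg.range.end + cfg.tms_extension
    window = [
        r.number for r in placement.structure.residues if lo <= r.number <= hi
    ]
    if not window:
        raise ValueError(
            f"extended window [{lo},{hi}] contains no residues with coordinates"
        )
    d1, d2 = _min_boundary_distances(placement, window)
    if d1 < cfg.boundary_dist_max and d2 < cfg.boundary_dist_max:
        return "transmembrane"
    return "re-entrant"


def merge_segments(
    segments: Sequence[TMSegment], cfg: Config = DEFAULT_CONFIG
) -> List[TMSegment]:
    """Merge same-orientation neighbours separated by < ``merge_gap_max``.

    Runs to fixpoint: a merged segment may in turn sit close enough to its
    next neighbour. Input must be sorted and non-overlapping. Idempotent.
    """
    merged = list(segments)
    changed = True
    while changed:
        changed = False
        out: List[TMSegment] = []
        for seg in merged:
            if (
                out
                and out[-1].orientation == seg.orientation
                and gap_len(out[-1].range, seg.range) < cfg.merge_gap_max
            ):
                prev = out.pop()
                joined = TMSegment(
                    range=ResidueRange(prev.range.start, seg.range.end),
                    orientation=prev.orientation,
                    kind=prev.kind,
                    source=prev.source,
                )
                logger.info(
                    "merge: %s + %s -> %s", prev.range, seg.range, joined.range
                )
                out.append(joined)
                changed = True
            else:
                out.append(seg)
        merged = out
    return merged


def recover_missing(
    placement: MembranePlacement,
    segments: Sequence[TMSegment],
    cfg: Config = DEFAULT_CONFIG,
) -> List[TMSegment]:
    """Insert one recovered TMS into each qualifying inter-segment gap.

    A gap qualifies when its flanking segments share an orientation and are
    separated by >= ``cfg.missing_gap_min`` residues. The recovered segment is
    centred on the gap residue closest to the membrane centre (smallest
    |d1 - d2|; ties to the smaller residue number), extends
    ``cfg.missing_halfwidth`` residues each side, is clipped so it overlaps
    neither flank, and takes the reversed orientation of the flanks. Gaps
    whose residues all lack coordinates are skipped with a warning.
    """
    out = list(segments)
    insertions: List[TMSegment] = []
    for left, right in zip(out, out[1:]):
        if left.orientation != right.orientation:
            continue
        if gap_len(left.range, right.range) < cfg.missing_gap_min:
            continue
        gap_numbers = [
            r.number
            for r in placement.structure.residues
            if left.range.end < r.number < right.range.start
        ]
        best_num: Optional[int] = None
        best_diff = math.inf
        for num in gap_numbers:
            d1, d2 = _min_boundary_distances(placement, [num])
            if math.isinf(d1) or math.isinf(d2):
                continue
            diff = abs(d1 - d2)
            if diff < best_diff:
                best_diff = diff
                best_num = num
        if best_num is None:
            logger.warning(
                "recovery skipped: gap (%s, %s) has no residues with coordinates",
                left.range, right.range,
            )
            continue
        start = max(best_num - cfg.missing_halfwidth, left.range.end + 1)
        end = min(best_num + cfg.missing_halfwidth, right.range.start - 1)
        recovered = TMSegment(
            range=ResidueRange(start, end),
            orientation=reverse_orientation(left.orientation),
            kind="transmembrane",
            source=left.source,
        )
        logger.info(
            "recovery: inserted %s (centre %d) between %s and %s",
            recovered.range, best_num, left.range, right.range,
        )
        insertions.append(recovered)
    out.extend(insertions)
    out.sort(key=lambda s: s.range.start)
    return out


def call_tms(
    placement: MembranePlacement, cfg: Config = DEFAULT_CONFIG, source: str = "AFTM"
) -> Tuple[List[TMSegment], List[TMSegment]]:
    """Full correction pipeline for one placement.

    Classifies every raw segment, keeps the transmembrane ones (re-entrant
    segments go to the second return value and are excluded from the TMS
    track), merges close same-orientation neighbours, then recovers missed
    crossings. Returns (TMS list, re-entrant list), both sorted.
    """
    tms: List[TMSegment] = []
    reentrant: List[TMSegment] = []
    for seg in placement.raw_segments:
        kind = classify_segment(placement, seg, cfg)
        if kind == "transmembrane":
            orientation = seg.orientation
            if orientation[0] == orientation[1]:
                # raw orientation disagrees with the geometric call; infer the
                # exit side from the far boundary
                orientation = (orientation[0], "side2" if orientation[0] == "side1" else "side1")
            tms.append(TMSegment(seg.range, orientation, kind="transmembrane", source=source))
        else:
            logger.info("re-entrant exclusion: %s", seg.range)
            reentrant.append(
                TMSegment(
                    seg.range,
                    (seg.orientation[0], seg.orientation[0]),
                    kind="re-entrant",
                    source=source,
                )
            )
    tms = merge_segments(tms, cfg)
    tms = recover_missing(placement, tms, cfg)
    return tms, reentrant


def combine_full_domain(
    full: Sequence[TMSegment],
    per_domain: Sequence[Sequence[TMSegment]],
    cfg: Config = DEFAULT_CONFIG,
) -> List[TMSegment]:
    """Combine the full-model and per-domain TMS tracks.

    A domain-derived segment that overlaps a full-model segment by at least
    ``cfg.match_overlap_min`` residues is considered the same crossing and the
    full-model boundaries win. Any remaining overlapping survivors are merged
    to their union span.
    """
    combined: List[TMSegment] = list(full)
    for track in per_domain:
        for seg in track:
            if any(
                overlap_len(seg.range, f.range) >= cfg.match_overlap_min
                for f in full
            ):
                continue  # already represented; full-model boundaries kept
            combined.append(seg)
    combined.sort(key=lambda s: (s.range.start, s.range.end))

    out: List[TMSegment] = []
    for seg in combined:
        if out and seg.range.start <= out[-1].range.end:
            prev = out.pop()
            out.append(
                TMSegment(
                    range=ResidueRange(
                        prev.range.start, max(prev.range.end, seg.range.end)
                    ),
                    orientation=prev.orientation,
                    kind=prev.kind,
                    source=prev.source,
                )
            )
        else:
            out.append(seg)
    return out
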