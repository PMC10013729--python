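"""Transfer reference TMSs onto target proteins through alignment hits.

Reference databases report TMSs on their own chains (e.g. PDB chains or
curated single-pass entries). High-identity alignment hits (> 95 %) project
those coordinates onto the target proteome; per target protein the projected
ranges are grouped by single-linkage clustering (any chain of pairwise
overlaps of >= 10 residues joins a cluster) and each cluster is reduced to a
consensus TMS whose start and end are the floored medians of the members'
starts and ends.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import AnnotationSet, Config, DEFAULT_CONFIG, ResidueRange, overlap_len
from .io_formats import AlignmentHit


def filter_hits(
    hits: Sequence[AlignmentHit], cfg: Config = DEFAULT_CONFIG
) -> List[AlignmentHit]:
    """Keep hits with identity strictly above ``cfg.identity_min`` percent."""
    return [h for h in hits if h.identity > cfg.identity_min]


def project_range(
    hit: AlignmentHit, subject_range: ResidueRange
) -> Optional[ResidueRange]:
    """Map a subject-coordinate range onto the query through one hit.

    With aligned sequences present, each subject column is walked to its query
    column (gap-aware); otherwise the hit must be ungapped (equal query and
    subject span lengths) and a constant offset is applied. The projection is
    clipped to the aligned span; returns None when the range does not overlap
    the hit's subject span at all, or no query residue survives.
    """
    s_lo = max(subject_range.start, hit.sstart)
    s_hi = min(subject_range.end, hit.send)
    if s_lo > s_hi:
        return None

    if hit.qseq is not None:
        s_to_q: Dict[int, int] = {}
        q = hit.qstart - 1
        s = hit.sstart - 1
        for qc, sc in zip(hit.qseq, hit.sseq):
            q_real = qc != "-"
            s_real = sc != "-"
            if q_real:
                q += 1
            if s_real:
                s += 1
                if q_real:
                    s_to_q[s] = q
        cols = [s_to_q[pos] for pos in range(s_lo, s_hi + 1) if pos in s_to_q]
        if not cols:
            return None
        return ResidueRange(min(cols), max(cols))

    if hit.qend - hit.qstart != hit.send - hit.sstart:
        raise ValueError(
            "ungapped projection on a hit with unequal query/subject span "
            "lengths; aligned sequences are required"
        )
    offset = hit.qstart - hit.sstart
    return ResidueRange(s_lo + offset, s_hi + offset)


def cluster_ranges(
    ranges: Sequence[ResidueRange], cfg: Config = DEFAULT_CONFIG
) -> List[List[ResidueRange]]:
    """Single-linkage clusters under 'overlap >= match_overlap_min' links.

    Two ranges share a cluster iff they are connected by a chain of pairwise
    overlaps of at least ``cfg.match_overlap_min`` residues. Clusters are
    returned sorted by their minimal start; members sorted within.
    """
    n = len(ranges)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if overlap_len(ranges[i], ranges[j]) >= cfg.match_overlap_min:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    groups: Dict[int, List[ResidueRange]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ranges[i])
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda g: (g[0].start, g[0].end))
    return clusters


def consensus_range(cluster: Sequence[ResidueRange]) -> ResidueRange:
    """Floored median of starts and of ends over the cluster members."""
    if not cluster:
        raise ValueError("empty cluster")
    start = int(np.floor(np.median([r.start for r in cluster])))
    end = int(np.floor(np.median([r.end for r in cluster])))
    return ResidueRange(start, end)


def build_reference(
    annotation_rows: Sequence[Tuple[str, ResidueRange]],
    hits: Sequence[AlignmentHit],
    cfg: Config = DEFAULT_CONFIG,
    source: str = "reference",
) -> AnnotationSet:
    """Filter hits, project every reference TMS, cluster and take consensus.

    ``annotation_rows`` are (subject id, TMS range) pairs on reference-chain
    coordinates. Output is one consensus TMS per overlap cluster per query
    protein, under the given source label. Order of input rows is immaterial.
    """
    kept = filter_hits(hits, cfg)
    projected: Dict[str, List[ResidueRange]] = {}
    for subject_id, rng in sorted(annotation_rows, key=lambda t: (t[0], t[1])):
        for hit in kept:
            if hit.subject_id != subject_id:
                continue
            proj = project_range(hit, rng)
            if proj is not None:
                projected.setdefault(hit.query_id, []).append(proj)

    out = AnnotationSet()
    for query_id, ranges in projected.items():
        for cluster in cluster_ranges(sorted(ranges), cfg):
            out.add(query_id, source, consensus_range(cluster))
    return out
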