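"""Geometric classification, merging, missing-TMS recovery and combination."""

import numpy as np
import pytest

from aftm import (
    Config,
    MembraneGeometry,
    MembranePlacement,
    Residue,
    ResidueRange,
    StructureModel,
    TMSegment,
    boundary_distance,
    call_tms,
    classify_segment,
    combine_full_domain,
    gap_len,
    merge_segments,
    recover_missing,
)
from aftm.fixtures import make_helix_bundle, make_placement, make_reentrant_hairpin
from conftest import random_rotation

CFG = Config()


def seg(start, end, orientation=("side1", "side2"), kind="raw"):
    return TMSegment(ResidueRange(start, end), orientation, kind=kind)


def brute_merge(segments, cfg):
    """Fixpoint oracle: repeatedly merge the first mergeable adjacent pair."""
    segs = list(segments)
    while True:
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a.orientation == b.orientation and gap_len(a.range, b.range) < cfg.merge_gap_max:
                segs[i : i + 2] = [
                    TMSegment(ResidueRange(a.range.start, b.range.end), a.orientation,
                              kind=a.kind, source=a.source)
                ]
                break
        else:
            return segs


def random_segment_list(rng, max_segments=8):
    segs = []
    pos = 1
    for _ in range(int(rng.integers(0, max_segments + 1))):
        pos += int(rng.integers(0, 25))
        length = int(rng.integers(3, 30))
        orientation = ("side1", "side2") if rng.integers(0, 2) else ("side2", "side1")
        segs.append(seg(pos, pos + length - 1, orientation))
        pos += length + 1
    return segs


# ---------------------------------------------------------------------------
# classify_segment


def test_true_crossings_classify_transmembrane(bundle4, bundle4_placement):
    _, truth, _ = bundle4
    for t in truth:
        raw = seg(t.range.start, t.range.end, t.orientation)
        assert classify_segment(bundle4_placement, raw, CFG) == "transmembrane"


def test_hairpin_classifies_reentrant(hairpin_placement):
    placement, segment = hairpin_placement
    assert classify_segment(placement, segment, CFG) == "re-entrant"
    # threshold monotonicity: a permissive boundary distance flips the call
    assert classify_segment(placement, segment, Config(boundary_dist_max=20.0)) == "transmembrane"


def test_classify_rigid_transform_invariance(bundle4, bundle4_placement):
    _, truth, geometry = bundle4
    placement = bundle4_placement
    rng = np.random.default_rng(5)
    for _ in range(5):
        rot = random_rotation(rng)
        t = rng.uniform(-60, 60, size=3)
        n2 = rot @ np.array(geometry.normal)
        shift = float(n2 @ t)
        geom2 = MembraneGeometry(
            variant="planar",
            normal=tuple(n2 / np.linalg.norm(n2)),
            offsets=(geometry.offsets[0] + shift, geometry.offsets[1] + shift),
        )
        residues2 = tuple(
            Residue(
                number=r.number,
                atoms={k: tuple(rot @ np.array(v) + t) for k, v in r.atoms.items()},
                plddt=r.plddt,
            )
            for r in placement.structure.residues
        )
        placement2 = MembranePlacement(
            structure=StructureModel(placement.structure.protein_id, residues2),
            geometry=geom2,
            raw_segments=placement.raw_segments,
        )
        for raw in placement.raw_segments:
            assert classify_segment(placement2, raw, CFG) == classify_segment(
                placement, raw, CFG
            )


def test_classify_empty_window_rejected(bundle4_placement):
    orphan = seg(5000, 5020)
    with pytest.raises(ValueError, match="no residues"):
        classify_segment(bundle4_placement, orphan, CFG)


# ---------------------------------------------------------------------------
# merge_segments


def test_merge_same_orientation_close_gap():
    merged = merge_segments([seg(100, 115), seg(121, 134)], CFG)
    assert [s.range for s in merged] == [ResidueRange(100, 134)]


def test_no_merge_when_gap_too_wide():
    segs = [seg(100, 115), seg(128, 140)]  # gap 12
    assert [s.range for s in merge_segments(segs, CFG)] == [s.range for s in segs]


def test_no_merge_across_orientations():
    segs = [seg(100, 115), seg(121, 134, ("side2", "side1"))]
    assert [s.range for s in merge_segments(segs, CFG)] == [s.range for s in segs]


def test_merge_cascades_to_fixpoint():
    segs = [seg(1, 10), seg(15, 24), seg(29, 38)]
    merged = merge_segments(segs, CFG)
    assert [s.range for s in merged] == [ResidueRange(1, 38)]


def test_merge_matches_bruteforce_oracle_and_is_idempotent():
    rng = np.random.default_rng(123)
    for _ in range(100):
        segs = random_segment_list(rng)
        merged = merge_segments(segs, CFG)
        oracle = brute_merge(segs, CFG)
        assert [(s.range, s.orientation) for s in merged] == [
            (s.range, s.orientation) for s in oracle
        ]
        again = merge_segments(merged, CFG)
        assert [s.range for s in again] == [s.range for s in merged]


# ---------------------------------------------------------------------------
# recover_missing


def straight_chain_placement(n=150, thickness=30.0, center_residue=87):
    """Straight chain whose residue ``center_residue`` sits mid-membrane."""
    geometry = MembraneGeometry(variant="planar", normal=(0.0, 0.0, 1.0),
                                offsets=(0.0, thickness))
    residues = tuple(
        Residue(
            number=i,
            atoms={"CA": (0.0, 0.0, thickness / 2.0 + (i - center_residue) * 1.0)},
            plddt=90.0,
        )
        for i in range(1, n + 1)
    )
    return MembranePlacement(
        structure=StructureModel("chain", residues), geometry=geometry, raw_segments=()
    )


def test_recover_inserts_at_membrane_center():
    placement = straight_chain_placement()
    flanks = [seg(50, 70, kind="transmembrane"), seg(100, 120, kind="transmembrane")]
    out = recover_missing(placement, flanks, CFG)
    assert [s.range for s in out] == [
        ResidueRange(50, 70), ResidueRange(82, 92), ResidueRange(100, 120)
    ]
    inserted = out[1]
    assert inserted.orientation == ("side2", "side1")
    assert inserted.kind == "transmembrane"
    # oracle: residue 87 has the minimal |d1 - d2| among the gap residues
    diffs = {}
    for num in range(71, 100):
        res = placement.structure.residue_by_number(num)
        p = res.atoms["CA"]
        diffs[num] = abs(
            boundary_distance(p, placement.geometry, 1)
            - boundary_distance(p, placement.geometry, 2)
        )
    assert min(diffs, key=diffs.get) == 87


def test_no_recovery_for_opposite_orientations():
    placement = straight_chain_placement()
    flanks = [
        seg(50, 70, ("side1", "side2"), kind="transmembrane"),
        seg(100, 120, ("side2", "side1"), kind="transmembrane"),
    ]
    assert [s.range for s in recover_missing(placement, flanks, CFG)] == [
        ResidueRange(50, 70), ResidueRange(100, 120)
    ]


def test_no_recovery_below_gap_threshold():
    placement = straight_chain_placement()
    flanks = [seg(50, 70, kind="transmembrane"), seg(85, 105, kind="transmembrane")]  # gap 14
    assert len(recover_missing(placement, flanks, CFG)) == 2


def test_recovery_clips_against_flanks():
    placement = straight_chain_placement(center_residue=73)
    flanks = [seg(50, 70, kind="transmembrane"), seg(86, 105, kind="transmembrane")]  # gap 15
    out = recover_missing(placement, flanks, CFG)
    inserted = out[1].range
    assert inserted.start >= 71 and inserted.end <= 85
    assert inserted == ResidueRange(71, 78)


# ---------------------------------------------------------------------------
# call_tms


def test_empty_placement_yields_no_tms(bundle4):
    model, _, geometry = bundle4
    placement = MembranePlacement(structure=model, geometry=geometry, raw_segments=())
    tms, reentrant = call_tms(placement, CFG)
    assert tms == [] and reentrant == []


def test_full_bundle_yields_alternating_tms(bundle4, bundle4_placement):
    _, truth, _ = bundle4
    tms, reentrant = call_tms(bundle4_placement, CFG)
    assert [s.range for s in tms] == [t.range for t in truth]
    assert [s.orientation for s in tms] == [t.orientation for t in truth]
    assert reentrant == []


def test_dropped_crossing_is_recovered(bundle4):
    from aftm.core import overlap_len
    model, truth, geometry = bundle4
    placement = make_placement(model, truth, geometry, drop_indices=[1], seed=2)
    tms, _ = call_tms(placement, CFG)
    assert len(tms) == 4
    recovered = tms[1]
    assert overlap_len(recovered.range, truth[1].range) >= 10
    assert recovered.orientation == truth[1].orientation


def test_split_crossing_is_remerged(bundle4):
    model, truth, geometry = bundle4
    placement = make_placement(model, truth, geometry, split_spec={2: 5}, seed=4)
    tms, _ = call_tms(placement, CFG)
    assert [s.range for s in tms] == [t.range for t in truth]


def test_reentrant_excluded_from_tms_track(hairpin_placement):
    placement, _ = hairpin_placement
    tms, reentrant = call_tms(placement, CFG)
    assert tms == []
    assert len(reentrant) == 1 and reentrant[0].kind == "re-entrant"


# ---------------------------------------------------------------------------
# combine_full_domain


def tm(start, end, orientation=("side1", "side2")):
    return TMSegment(ResidueRange(start, end), orientation, kind="transmembrane")


def test_combine_prefers_full_model_boundaries():
    out = combine_full_domain([tm(10, 30)], [[tm(12, 32), tm(60, 80)]], CFG)
    assert [s.range for s in out] == [ResidueRange(10, 30), ResidueRange(60, 80)]


def test_combine_with_empty_full_track():
    out = combine_full_domain([], [[tm(60, 80)]], CFG)
    assert [s.range for s in out] == [ResidueRange(60, 80)]


def test_combine_with_empty_domain_track():
    out = combine_full_domain([tm(10, 30)], [[]], CFG)
    assert [s.range for s in out] == [ResidueRange(10, 30)]


def test_combine_merges_overlapping_survivors():
    # overlap below the match threshold: both kept, then unioned
    out = combine_full_domain([tm(10, 30)], [[tm(28, 50)]], CFG)
    assert [s.range for s in out] == [ResidueRange(10, 50)]
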