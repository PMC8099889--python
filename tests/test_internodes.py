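"""Internode classification, merging, summaries and the spatial envelope."""

import numpy as np
import pytest

from oligotrace import internodes as ino
from oligotrace import morphometry as mo
from oligotrace import (
    InjuryParams,
    InternodeCriteria,
    NoAnnotationsError,
    apply_injury,
    generate_cell,
    preset_params,
)

from conftest import make_recon, thick_branch_cell

CRITERIA = InternodeCriteria(mode="criteria")
ANNOT = InternodeCriteria(mode="annotation")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_thick_straight_long_branch_is_myelinating():
    d = mo.decompose(thick_branch_cell(run_length=60.0))
    labels = ino.classify_branches(d, CRITERIA)
    thick = [s for s in d.segments.values() if s.median_radius > 1.0]
    assert len(thick) == 1
    assert labels[thick[0].segment_id] == ino.M_PB
    fine = [s for s in d.segments.values() if s.median_radius < 1.0]
    assert all(labels[s.segment_id] == ino.NM_PB for s in fine)


def test_short_thick_branch_is_not_myelinating():
    d = mo.decompose(thick_branch_cell(run_length=10.0))
    labels = ino.classify_branches(d, CRITERIA)
    assert all(lab == ino.NM_PB for lab in labels.values())


def test_thin_branch_is_not_myelinating():
    d = mo.decompose(thick_branch_cell(run_length=60.0, radius=0.4))
    labels = ino.classify_branches(d, CRITERIA)
    assert all(lab == ino.NM_PB for lab in labels.values())


def test_annotation_mode_requires_annotations(three_arbor_cell):
    d = mo.decompose(three_arbor_cell)
    with pytest.raises(NoAnnotationsError):
        ino.classify_branches(d, ANNOT)


def test_auto_mode_prefers_annotations(annotated_cell, three_arbor_cell):
    auto = InternodeCriteria(mode="auto")
    assert auto.resolve_mode(mo.decompose(annotated_cell)) == "annotation"
    assert auto.resolve_mode(mo.decompose(three_arbor_cell)) == "criteria"


@pytest.mark.parametrize(
    "kwargs", [dict(mode="x"), dict(min_length_um=0), dict(radius_ratio=0.5),
               dict(min_straightness=0.0), dict(min_straightness=1.5)]
)
def test_invalid_criteria_rejected(kwargs):
    with pytest.raises(ValueError):
        InternodeCriteria(**kwargs)


@pytest.mark.parametrize("seed", range(20))
def test_criteria_mode_matches_generator_truth(seed):
    """Criteria-mode labels agree with the generator's branch classes."""
    recon, gt = generate_cell(preset_params("control", seed=seed))
    d = mo.decompose(recon)
    labels = ino.classify_branches(d, CRITERIA)
    truth_pts = gt.internode_point_ids
    n_match = 0
    for sid, seg in d.segments.items():
        inside = sum(1 for i in seg.proper_point_ids if i in truth_pts)
        want = ino.M_PB if inside * 2 > len(seg.proper_point_ids) else ino.NM_PB
        n_match += labels[sid] == want
    assert n_match / len(d.segments) >= 0.95


def _enumerate_runs_oracle(d, criteria):
    """Exhaustive oracle: every maximal thick run, tested independently.

    Walks the segment tree recursively (rather than the implementation's
    iterative frontier) and recomputes lengths from raw coordinates.
    """
    labels = {sid: ino.NM_PB for sid in d.segments}

    def run_members(start):
        ref = start.median_radius
        members = [start]
        for cid in start.child_segment_ids:
            child = d.segments[cid]
            if child.median_radius * criteria.radius_ratio >= ref:
                members.extend(run_members(child))
        return members

    def longest_path(seg, member_ids):
        kids = [
            d.segments[c] for c in seg.child_segment_ids if c in member_ids
        ]
        if not kids:
            return seg.length, seg
        best = max((longest_path(k, member_ids) for k in kids),
                   key=lambda t: t[0])
        return seg.length + best[0], best[1]

    for sid in sorted(d.segments):
        seg = d.segments[sid]
        if seg.parent_segment_id is None:
            continue
        parent = d.segments[seg.parent_segment_id]
        if labels[parent.segment_id] == ino.M_PB:
            continue
        if seg.median_radius < criteria.radius_ratio * parent.median_radius:
            continue
        members = run_members(seg)
        total = sum(
            mo.polyline_length(d.segment_points(m)) for m in members
        )
        if total < criteria.min_length_um:
            continue
        member_ids = {m.segment_id for m in members}
        plen, end_seg = longest_path(seg, member_ids)
        chord = float(
            np.linalg.norm(
                d.segment_points(end_seg)[-1] - d.segment_points(seg)[0]
            )
        )
        if plen > 0 and chord / plen < criteria.min_straightness:
            continue
        for m in members:
            labels[m.segment_id] = ino.M_PB
    return labels


@pytest.mark.parametrize("seed", range(10))
def test_criteria_mode_matches_enumeration_oracle(seed):
    recon, _ = generate_cell(preset_params("control", seed=seed))
    d = mo.decompose(recon)
    if len(d.segments) > 50:
        pytest.skip("oracle restricted to small cells")
    assert ino.classify_branches(d, CRITERIA) == _enumerate_runs_oracle(d, CRITERIA)


# ---------------------------------------------------------------------------
# internode assembly
# ---------------------------------------------------------------------------

def test_contiguous_annotated_run_merges_to_one_internode(annotated_cell):
    d = mo.decompose(annotated_cell)
    result = ino.identify_internodes(d, ANNOT)
    assert len(result) == 1
    assert result[0].length == pytest.approx(80.0)
    assert result[0].initiation_order == 2
    assert len(result[0].segment_ids) == 3


def test_runs_separated_by_fine_connector_stay_distinct(double_run_cell):
    d = mo.decompose(double_run_cell)
    result = ino.identify_internodes(d, ANNOT)
    assert len(result) == 2
    assert all(i.length == pytest.approx(80.0, abs=0.5) for i in result)


def test_injured_cell_has_no_internodes():
    recon, gt = generate_cell(preset_params("control", seed=3))
    injured, gt2 = apply_injury(
        recon, gt, InjuryParams(seed=0, internode_deletion_probability=1.0,
                                fragment_detach_probability=0.0)
    )
    d = mo.decompose(injured)
    assert ino.identify_internodes(d, InternodeCriteria(mode="auto")) == []
    assert gt2.internode_count == 0


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def test_summary_order_statistics(double_run_cell):
    d = mo.decompose(double_run_cell)
    labels = ino.classify_branches(d, ANNOT)
    result = ino.identify_internodes(d, ANNOT, labels=labels)
    s = ino.internode_summary(d, result, labels)
    assert s.internode_count == 2
    orders = sorted(i.initiation_order for i in result)
    assert (s.min_initiation_order, s.max_initiation_order) == (orders[0], orders[-1])
    assert s.mean_initiation_order == pytest.approx(float(np.mean(orders)))
    assert s.max_internodes_per_arbor == 2


def test_summary_ratio_arithmetic(annotated_cell):
    d = mo.decompose(annotated_cell)
    labels = ino.classify_branches(d, ANNOT)
    result = ino.identify_internodes(d, ANNOT, labels=labels)
    s = ino.internode_summary(d, result, labels)
    n_m = sum(1 for v in labels.values() if v == ino.M_PB)
    assert s.m_pb_over_tb == pytest.approx(n_m / s.total_branches)
    assert s.m_pb_over_tb + s.nm_pb_over_tb == pytest.approx(1.0, abs=1e-9)


def test_summary_with_zero_internodes(three_arbor_cell):
    d = mo.decompose(three_arbor_cell)
    labels = ino.classify_branches(d, CRITERIA)
    s = ino.internode_summary(d, [], labels)
    assert s.internode_count == 0
    assert s.min_initiation_order is None
    assert s.m_pb_over_tb == 0.0
    assert s.nm_pb_over_tb == 1.0


@pytest.mark.parametrize("seed", range(6))
def test_ratios_sum_to_one_on_synthetic_cells(seed):
    recon, _ = generate_cell(preset_params("ttx", seed=seed))
    d = mo.decompose(recon)
    labels = ino.classify_branches(d, ANNOT)
    result = ino.identify_internodes(d, ANNOT, labels=labels)
    s = ino.internode_summary(d, result, labels)
    assert s.m_pb_over_tb + s.nm_pb_over_tb == pytest.approx(1.0, abs=1e-12)


def test_counts_and_lengths_invariant_under_rigid_motion():
    recon, _ = generate_cell(preset_params("control", seed=9))
    d = mo.decompose(recon)
    base = ino.identify_internodes(d, CRITERIA)

    theta = 0.7
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    shift = np.array([17.0, -4.0, 2.5])
    moved = make_recon(
        [
            (
                p.sample_id,
                p.structure_code,
                *(rot @ np.array(p.xyz) + shift),
                p.radius,
                p.parent_id,
            )
            for p in recon.points
        ],
        cell_id="moved",
    )
    d2 = mo.decompose(moved)
    result = ino.identify_internodes(d2, CRITERIA)
    assert len(result) == len(base)
    for a, b in zip(base, result):
        assert b.length == pytest.approx(a.length, abs=1e-6)
        assert b.initiation_order == a.initiation_order


# ---------------------------------------------------------------------------
# spatial envelope
# ---------------------------------------------------------------------------

def _envelope_fixture(points):
    """One 'internode' whose chain is exactly the given points."""
    rows = [(1, 1, *map(float, points[0]), 5.0, -1)]
    parent = 1
    for k, p in enumerate(points[1:], start=2):
        rows.append((k, 7, float(p[0]), float(p[1]), float(p[2]), 1.2, parent))
        parent = k
    recon = make_recon(rows, cell_id="env")
    d = mo.decompose(recon)
    result = ino.identify_internodes(d, ANNOT)
    return d, result


def test_envelope_matches_principal_direction_oracle():
    # expected values frozen from a brute-force axis-angle scan over the
    # XY projection of these four points
    pts = [(0, 0, 0), (10, 2, 1), (20, -3, 2), (30, 0, 0)]
    d, result = _envelope_fixture(pts)
    env = ino.spatial_envelope(result, d)
    assert env.axis[0] == pytest.approx(0.99869318, abs=1e-6)
    assert env.axis[1] == pytest.approx(-0.05110715, abs=1e-6)
    assert env.perpendicular_extent == pytest.approx(4.4823944, abs=1e-5)
    assert env.z_extent == pytest.approx(2.0)


def test_envelope_with_fixed_axis_override():
    pts = [(0, 0, 0), (10, 2, 1), (20, -3, 2), (30, 0, 0)]
    d, result = _envelope_fixture(pts)
    env = ino.spatial_envelope(result, d, axis=(1.0, 0.0))
    assert env.perpendicular_extent == pytest.approx(5.0)
    assert env.z_extent == pytest.approx(2.0)


def test_envelope_degenerate_collinear_points():
    pts = [(0, 0, 0), (10, 0, 0), (20, 0, 0), (30, 0, 0)]
    d, result = _envelope_fixture(pts)
    env = ino.spatial_envelope(result, d)
    assert env.perpendicular_extent == pytest.approx(0.0, abs=1e-9)
    assert env.z_extent == pytest.approx(0.0, abs=1e-9)


def test_envelope_requires_internodes(three_arbor_cell):
    d = mo.decompose(three_arbor_cell)
    with pytest.raises(ValueError, match="no internodes"):
        ino.spatial_envelope([], d)


def test_envelope_recovers_generator_cross_section():
    """Internodes generated inside a 36.5 x 17.3 um cross-section are
    recovered within +-10%."""
    params = preset_params("control", seed=21)
    recon, gt = generate_cell(params)
    assert gt.internode_count >= 2
    d = mo.decompose(recon)
    result = ino.identify_internodes(d, ANNOT)
    env = ino.spatial_envelope(result, d)
    assert env.perpendicular_extent == pytest.approx(
        params.envelope_perpendicular_um, rel=0.10
    )
    assert env.z_extent == pytest.approx(params.envelope_z_um, rel=0.10)
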