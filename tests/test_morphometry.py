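"""Arbor decomposition, branch segments, centrifugal ordering and the
cell-level branch counts."""

import numpy as np
import pytest

from oligotrace import morphometry as mo
from oligotrace import preset_params, generate_cell

from conftest import make_recon


def test_three_unbranched_arbors(three_arbor_cell):
    d = mo.decompose(three_arbor_cell)
    assert len(d.arbors) == 3
    for a in d.arbors:
        assert a.branch_point_count == 0
        assert a.max_order == 1
        assert a.segment_count == 1
    assert mo.total_branches(d, "all_segments") == 3
    assert mo.total_branches(d, "terminal_tips") == 3


def test_single_bifurcation():
    """Soma with one child that bifurcates once: 1 arbor, 3 segments."""
    recon = make_recon(
        [
            (1, 1, 0.0, 0.0, 0.0, 5.0, -1),
            (2, 3, 10.0, 0.0, 0.0, 0.4, 1),
            (3, 3, 20.0, 5.0, 0.0, 0.4, 2),
            (4, 3, 20.0, -5.0, 0.0, 0.4, 2),
        ]
    )
    d = mo.decompose(recon)
    assert len(d.arbors) == 1
    a = d.arbors[0]
    assert a.branch_point_count == 1
    assert a.max_order == 2
    assert a.segment_count == 3
    assert mo.total_branches(d, "all_segments") == 3
    assert mo.total_branches(d, "terminal_tips") == 2


def test_unknown_tb_mode_rejected(three_arbor_cell):
    with pytest.raises(ValueError, match="unknown TB mode"):
        mo.total_branches(mo.decompose(three_arbor_cell), "bogus")


def test_perfect_binary_tree_metrics(binary_tree_cell):
    d = mo.decompose(binary_tree_cell)
    assert len(d.arbors) == 1
    a = d.arbors[0]
    assert mo.arbor_metrics(a) == (pytest.approx(7.0), 3, 3)
    assert a.segment_count == 7
    assert a.tip_count == 4  # strictly bifurcating: tips = branch points + 1
    assert a.longest_path_length == pytest.approx(3.0)


def test_segment_length_examples():
    assert mo.segment_length(np.array([[0, 0, 0], [3, 4, 0]])) == pytest.approx(5.0)
    assert mo.segment_length(
        np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]])
    ) == pytest.approx(3.0)


def test_segment_length_matches_pairwise_oracle():
    rng = np.random.default_rng(42)
    pts = rng.normal(0, 30, (50, 3))
    expected = sum(
        float(np.sqrt(((pts[i + 1] - pts[i]) ** 2).sum())) for i in range(49)
    )
    assert mo.segment_length(pts) == pytest.approx(expected, rel=1e-12)


def test_single_point_segment_warns():
    with pytest.warns(UserWarning, match="single-point"):
        assert mo.segment_length(np.array([[1.0, 2.0, 3.0]])) == 0.0


def test_soma_surrogate_for_unlabelled_cell(caplog):
    """A cell without a structure-code-1 point uses the root of the
    largest component as the soma, with a warning."""
    recon = make_recon(
        [
            (1, 3, 0.0, 0.0, 0.0, 0.5, -1),
            (2, 3, 10.0, 0.0, 0.0, 0.5, 1),
            (3, 3, 20.0, 0.0, 0.0, 0.5, 2),
        ]
    )
    import logging

    with caplog.at_level(logging.WARNING, logger="oligotrace.morphometry"):
        d = mo.decompose(recon)
    assert d.soma_is_surrogate
    assert d.soma_ids == [1]
    assert "soma surrogate" in caplog.text
    assert len(d.arbors) == 1


def test_duplicate_points_merged():
    recon = make_recon(
        [
            (1, 1, 0.0, 0.0, 0.0, 5.0, -1),
            (2, 3, 10.0, 0.0, 0.0, 0.4, 1),
            (3, 3, 10.0, 0.0, 0.0, 0.4, 2),  # zero-length duplicate
            (4, 3, 20.0, 0.0, 0.0, 0.4, 3),
        ]
    )
    d = mo.decompose(recon)
    assert d.merged_duplicates == 1
    assert len(d.arbors) == 1
    assert d.arbors[0].segment_count == 1
    assert d.arbors[0].total_length == pytest.approx(20.0)


def test_unit_scale_applied():
    recon = make_recon(
        [(1, 1, 0.0, 0.0, 0.0, 5.0, -1), (2, 3, 10.0, 0.0, 0.0, 0.4, 1)],
        unit_scale=0.5,
    )
    d = mo.decompose(recon)
    assert d.arbors[0].total_length == pytest.approx(5.0)


def _point_order_oracle(recon, soma_ids):
    """Independent centrifugal-order oracle: the order of a point is one
    plus the number of junction points strictly between it and the soma."""
    children = recon.children_map()
    soma = set(soma_ids)
    orders = {}
    for p in recon.points:
        if p.sample_id in soma:
            continue
        o = 1
        cur = recon.point(p.sample_id)
        while cur.parent_id != -1 and cur.parent_id not in soma:
            parent = recon.point(cur.parent_id)
            if len(children[parent.sample_id]) >= 2:
                o += 1
            cur = parent
        orders[p.sample_id] = o
    return orders


@pytest.mark.parametrize("seed", range(8))
def test_centrifugal_order_matches_point_oracle(seed):
    recon, _ = generate_cell(preset_params("control", seed=seed))
    d = mo.decompose(recon)
    oracle = _point_order_oracle(d.recon, d.soma_ids)
    for seg in d.segments.values():
        for pid in seg.proper_point_ids:
            assert seg.centrifugal_order == oracle[pid], f"point {pid}"


@pytest.mark.parametrize("seed", range(8))
def test_arbors_partition_points_and_tb_identity(seed):
    recon, gt = generate_cell(preset_params("control", seed=seed))
    d = mo.decompose(recon)
    # every non-soma point of the soma component in exactly one arbor
    claimed = []
    for a in d.arbors:
        for sid in a.segment_ids:
            claimed.extend(d.segments[sid].proper_point_ids)
    assert sorted(claimed) == sorted(
        p.sample_id for p in d.recon.points if p.sample_id not in d.soma_ids
    )
    # strictly bifurcating: TB(all_segments) = 2 * branch points + arbor roots
    bp = sum(a.branch_point_count for a in d.arbors)
    assert mo.total_branches(d, "all_segments") == 2 * bp + len(d.arbors)
    assert mo.total_branches(d, "all_segments") == gt.total_branches


@pytest.mark.parametrize("seed", range(4))
def test_arbor_metrics_match_depth_first_oracle(seed):
    """Total length / branch points / max order vs an exhaustive
    depth-first walk over the raw point tree."""
    recon, _ = generate_cell(preset_params("control", seed=seed))
    d = mo.decompose(recon)
    children = d.recon.children_map()
    for a in d.arbors:
        root_pid = d.segments[a.root_segment_id].point_ids[1]
        total = 0.0
        branch_points = 0
        stack = [(root_pid, 1)]
        max_order = 0
        while stack:
            pid, order = stack.pop()
            pt = d.recon.point(pid)
            parent = d.recon.point(pt.parent_id)
            total += float(
                np.sqrt(
                    (pt.x - parent.x) ** 2
                    + (pt.y - parent.y) ** 2
                    + (pt.z - parent.z) ** 2
                )
            )
            kids = children[pid]
            max_order = max(max_order, order)
            if len(kids) >= 2:
                branch_points += 1
                stack.extend((k, order + 1) for k in kids)
            else:
                stack.extend((k, order) for k in kids)
        assert a.total_length == pytest.approx(total, rel=1e-9)
        assert a.branch_point_count == branch_points
        assert a.max_order == max_order
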