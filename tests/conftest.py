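import numpy as np
import pytest

from oligotrace.swc import CellReconstruction, ReconPoint


def make_recon(rows, cell_id="test", **kw):
    """Build a CellReconstruction from (id, code, x, y, z, r, parent) tuples."""
    return CellReconstruction(
        points=[ReconPoint(*row) for row in rows], cell_id=cell_id, **kw
    )


@pytest.fixture
def simple_chain():
    """Soma root plus two child points on a line (minimal valid cell)."""
    return make_recon(
        [
            (1, 1, 0.0, 0.0, 0.0, 5.0, -1),
            (2, 3, 3.0, 0.0, 0.0, 0.5, 1),
            (3, 3, 6.0, 0.0, 0.0, 0.5, 2),
        ]
    )


@pytest.fixture
def binary_tree_cell():
    """Soma with one arbor forming a perfect binary tree of depth 3.

    Every branch segment has unit length, so the arbor metrics are
    (total_length 7, branch points 3, max order 3) with 7 segments.
    """
    rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1), (2, 3, 1.0, 0.0, 0.0, 0.4, 1)]
    nid = 3
    # two children of 2, each with two children of their own
    level2 = []
    for dy in (1.0, -1.0):
        rows.append((nid, 3, 1.0, dy, 0.0, 0.4, 2))
        level2.append(nid)
        nid += 1
    for parent, dy in zip(level2, (1.0, -1.0)):
        py = rows[parent - 1][3]
        for dz in (1.0, -1.0):
            rows.append((nid, 3, 1.0, py, dz, 0.4, parent))
            nid += 1
    return make_recon(rows)


@pytest.fixture
def three_arbor_cell():
    """Soma with three direct unbranched chains (3 arbors, no junctions)."""
    rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
    nid = 2
    for direction in ((1, 0, 0), (0, 1, 0), (-1, 0, 0)):
        parent = 1
        for k in range(1, 4):
            rows.append(
                (nid, 3, 10.0 * k * direction[0], 10.0 * k * direction[1],
                 10.0 * k * direction[2], 0.4, parent)
            )
            parent = nid
            nid += 1
    return make_recon(rows)


def annotated_run_cell(n_runs=1):
    """Soma -> fine branch -> run(s) of 3 contiguous annotated segments.

    Each annotated run totals 80 um (segments of 30 + 20 + 30 um joined
    by side-twig junctions).  With ``n_runs == 2`` the second run hangs
    off the first via a fine connecting branch, so annotation-mode
    merging must yield two distinct internodes.
    """
    rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1), (2, 3, 5.0, 0.0, 0.0, 0.3, 1)]
    nid = 3

    def add(code, x, y, z, r, parent):
        nonlocal nid
        rows.append((nid, code, x, y, z, r, parent))
        nid += 1
        return nid - 1

    def add_run(attach, x0, y0):
        # segment 1: 30 um in one 10+10+10 chain
        a = add(7, x0 + 10, y0, 0.0, 1.2, attach)
        b = add(7, x0 + 20, y0, 0.0, 1.2, a)
        c = add(7, x0 + 30, y0, 0.0, 1.2, b)
        add(3, x0 + 30, y0 + 5, 0.0, 0.3, c)  # twig -> junction
        # segment 2: 20 um
        d = add(7, x0 + 40, y0, 0.0, 1.2, c)
        e = add(7, x0 + 50, y0, 0.0, 1.2, d)
        add(3, x0 + 50, y0 + 5, 0.0, 0.3, e)  # twig -> junction
        # segment 3: 30 um
        f = add(7, x0 + 60, y0, 0.0, 1.2, e)
        g = add(7, x0 + 80, y0, 0.0, 1.2, f)
        return g

    add(3, 5.0, 4.0, 0.0, 0.3, 2)  # twig: the connecting branch ends at a junction
    end = add_run(2, 5.0, 0.0)
    if n_runs == 2:
        # fine connector from the first run's tip, then a second run
        add(3, 85.0, 5.0, 0.0, 0.3, end)  # twig: run 1 tip is a junction
        h = add(3, 90.0, 5.0, 0.0, 0.3, end)
        add(3, 90.0, 10.0, 0.0, 0.3, h)  # twig: connector ends at a junction
        add_run(h, 90.0, 5.0)
    return make_recon(rows, cell_id=f"annotated-{n_runs}")


@pytest.fixture
def annotated_cell():
    return annotated_run_cell(1)


@pytest.fixture
def double_run_cell():
    return annotated_run_cell(2)


def thick_branch_cell(run_length=60.0, radius=1.2):
    """Soma -> fine connecting branch (r 0.3) -> straight thick branch.

    Used for criteria-mode classification: with the default thresholds
    the thick branch is myelinating iff ``run_length`` >= 25 um.
    """
    rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
    nid = 2
    parent = 1
    for k in range(1, 4):  # fine connecting branch, 15 um
        rows.append((nid, 3, 5.0 * k, 0.0, 0.0, 0.3, parent))
        parent = nid
        nid += 1
    attach = parent
    # side twig so the connecting branch ends at a junction
    rows.append((nid, 3, 15.0, 4.0, 0.0, 0.3, attach))
    nid += 1
    # straight thick branch along +x
    n_steps = max(2, int(run_length // 10) + 1)
    step = run_length / n_steps
    parent = attach
    for k in range(1, n_steps + 1):
        rows.append((nid, 3, 15.0 + step * k, 0.0, 0.0, radius, parent))
        parent = nid
        nid += 1
    return make_recon(rows, cell_id="thick-branch")


def random_recon(seed, n_extra_roots=0):
    """A random valid multi-point reconstruction for round-trip tests."""
    rng = np.random.default_rng(seed)
    rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
    nid = 2
    for _ in range(rng.integers(5, 40)):
        parent = int(rng.integers(1, nid))
        xyz = rng.normal(0, 50, 3)
        rows.append(
            (nid, int(rng.integers(0, 8)), float(xyz[0]), float(xyz[1]),
             float(xyz[2]), float(rng.uniform(0.1, 3.0)), parent)
        )
        nid += 1
    for _ in range(n_extra_roots):
        xyz = rng.normal(0, 50, 3)
        rows.append(
            (nid, 3, float(xyz[0]), float(xyz[1]), float(xyz[2]),
             float(rng.uniform(0.1, 3.0)), -1)
        )
        nid += 1
    return make_recon(rows, cell_id=f"random-{seed}")
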