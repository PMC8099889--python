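"""Synthetic oligodendrocyte reconstructions and colocalization images
with known ground truth.

The morphology generator emulates transitional oligodendrocytes in
cerebellar white matter: ~7-8 process arbors per cell, order-dependent
branching, a minority of thick, long, axis-aligned internode branches
reached via fine connecting branches, and internode point clouds confined
to a flattened tube-like envelope around the white-matter axis (taken as
x).  The injury transform emulates complement-mediated damage:
fragmented processes and loss of internodes.  The image generator
produces paired axon (NF200) / myelin (MBP) stacks where the myelin
covers a known fraction of the axon pixels.

Everything is driven by a single seeded ``numpy`` generator, so a given
(params, seed) pair reproduces byte-identical artifacts.

Construction of a cell proceeds in three stages:

1. *Topology*: per arbor, a branching process where a branch at
   centrifugal order *o* bifurcates with probability
   ``p0 * decay**(o-1)`` up to a maximum order.  Every internal node has
   exactly two children, so generator branches correspond one-to-one to
   the branch segments recovered by decomposition.
2. *Internode placement*: a quota of ``round(m_pb_fraction * TB)``
   branches (scaled by the placement probability) is drawn at random
   from the eligible branches -- order >= 2 with a fine parent -- under
   the constraint that internodes are never adjacent, i.e. they are
   always reached from fine connecting branches.  Lengths are lognormal
   (median / IQR parameterised), floored at the shortest detectable
   internode (~29 um).
3. *Geometry*: fine branches grow as persistent random walks; a fine
   branch that feeds internodes is steered so its endpoint lands on the
   internode's assigned transverse position; internodes run along +-x
   with small angular jitter and their transverse coordinates are
   confined to the configured envelope cross-section, whose edges the
   assigned positions cover exactly when at least two connecting
   branches exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .swc import SOMA_CODE, DEFAULT_INTERNODE_CODE, CellReconstruction, ReconPoint
from . import morphometry

FINE_CODE = 3  # structure code for ordinary (non-internode, non-soma) points


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphGenParams:
    """Generator parameters; defaults are the control condition.

    The branching constants (``branch_p0``, ``branch_decay``) are set so
    the expected total branch count per cell matches the observed control
    (~20) and activity-silenced (~25) cells; ``m_pb_fraction`` is the
    target myelinating fraction of branches (M_PB/TB); internode length
    is lognormal with the given median and sigma (log-scale), floored at
    ``internode_min_length_um``.
    """

    seed: int = 0
    arbor_count_mean: float = 7.7
    arbor_count_sd: float = 1.6
    arbor_count_min: int = 3
    branch_p0: float = 0.38
    branch_decay: float = 0.82
    max_order: int = 9
    fine_length_median_um: float = 12.0
    fine_length_sigma: float = 0.5
    fine_radius_um: float = 0.3
    fine_step_um: float = 4.0
    internode_placement_probability: float = 1.0
    m_pb_fraction: float = 0.28
    internode_length_median_um: float = 85.0
    internode_length_sigma: float = 0.293
    internode_min_length_um: float = 29.0
    internode_radius_um: float = 1.2
    internode_step_um: float = 5.0
    internode_jitter_deg: float = 1.5
    envelope_perpendicular_um: float = 36.5
    envelope_z_um: float = 17.3
    annotation_code: int = DEFAULT_INTERNODE_CODE
    soma_radius_um: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.internode_placement_probability <= 1:
            raise ValueError("internode_placement_probability must be in [0, 1]")
        if not 0 <= self.m_pb_fraction <= 1:
            raise ValueError("m_pb_fraction must be in [0, 1]")
        for name in (
            "fine_length_median_um",
            "internode_length_median_um",
            "internode_radius_um",
            "fine_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.arbor_count_min < 1:
            raise ValueError("arbor_count_min must be >= 1")
        if self.arbor_count_mean < self.arbor_count_min:
            raise ValueError("arbor_count_mean below arbor_count_min is infeasible")


@dataclass(frozen=True)
class InjuryParams:
    """Complement-injury transform: detach branches, delete internodes."""

    seed: int = 0
    fragment_detach_probability: float = 0.3
    internode_deletion_probability: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fragment_detach_probability", "internode_deletion_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ImageGenParams:
    """Synthetic NF200/MBP image pair parameters."""

    seed: int = 0
    planes: int = 3
    height: int = 192
    width: int = 192
    n_fibers: int = 14
    fiber_width_px: int = 3
    coverage: float = 0.4
    fiber_intensity: float = 160.0
    background: float = 12.0
    noise_sd: float = 3.0
    pixel_size_um: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")


@dataclass
class InternodeTruth:
    point_ids: list[int]
    length_um: float
    initiation_order: int
    arbor_index: int


@dataclass
class GroundTruth:
    """The generator's record of what it built."""

    cell_id: str
    arbor_count: int
    total_branches: int
    internodes: list[InternodeTruth]
    m_pb_over_tb: float
    fragment_count: int = 0
    envelope_perpendicular_um: float | None = None
    envelope_z_um: float | None = None

    @property
    def internode_count(self) -> int:
        return len(self.internodes)

    @property
    def internode_point_ids(self) -> set[int]:
        return {i for ino in self.internodes for i in ino.point_ids}

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# morphology generation
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    """One generator branch (maps 1:1 onto a decomposed BranchSegment)."""

    node_id: int
    arbor: int
    parent: int | None
    depth: int
    children: list[int] = field(default_factory=list)
    kind: str = "fine"
    target_length: float | None = None
    transverse: tuple[float, float] | None = None
    # geometry, filled during emission
    point_ids: list[int] = field(default_factory=list)
    end_xyz: np.ndarray | None = None
    end_dir: np.ndarray | None = None
    realized_length: float = 0.0


def _build_topology(rng: np.random.Generator, params: MorphGenParams) -> list[_Node]:
    n_arbors = int(
        max(params.arbor_count_min, round(rng.normal(params.arbor_count_mean,
                                                     params.arbor_count_sd)))
    )
    nodes: list[_Node] = []
    for arbor in range(n_arbors):
        root = _Node(node_id=len(nodes), arbor=arbor, parent=None, depth=1)
        nodes.append(root)
        frontier = [root]
        while frontier:
            node = frontier.pop(0)
            o = node.depth
            if o >= params.max_order:
                continue
            p = params.branch_p0 * params.branch_decay ** (o - 1)
            if rng.random() < p:
                for _ in range(2):
                    child = _Node(
                        node_id=len(nodes), arbor=arbor,
                        parent=node.node_id, depth=o + 1,
                    )
                    node.children.append(child.node_id)
                    nodes.append(child)
                    frontier.append(child)
    return nodes


def _truncated_lognormal_mu(median: float, sigma: float, floor: float) -> float:
    """Log-scale location such that a lognormal left-truncated at ``floor``
    has the given median.

    The configured internode length median is the *observed* median of
    detected internodes, which already excludes anything below the
    detection floor, so the underlying distribution is shifted to
    compensate.
    """
    from scipy.stats import norm

    if floor <= 0 or median <= floor:
        return math.log(median)
    target = math.log(median)
    mu = target
    for _ in range(100):
        q_floor = norm.cdf((math.log(floor) - mu) / sigma)
        new_mu = target - sigma * norm.ppf((1 + q_floor) / 2)
        if abs(new_mu - mu) < 1e-10:
            break
        mu = new_mu
    return mu


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, floor: float
) -> float:
    for _ in range(1000):
        v = float(rng.lognormal(mu, sigma))
        if v >= floor:
            return v
    return floor  # pragma: no cover - practically unreachable


def _place_internodes(
    rng: np.random.Generator, nodes: list[_Node], params: MorphGenParams
) -> None:
    tb = len(nodes)
    quota = int(round(params.m_pb_fraction * tb
                      * params.internode_placement_probability))
    eligible = [n for n in nodes if n.depth >= 2]
    if quota > 0 and not eligible:
        # a transitional OL carries at least one internode, which needs a
        # branch reached from a connecting branch: force one bifurcation
        root = nodes[int(rng.integers(len(nodes)))]
        for _ in range(2):
            child = _Node(node_id=len(nodes), arbor=root.arbor,
                          parent=root.node_id, depth=root.depth + 1)
            root.children.append(child.node_id)
            nodes.append(child)
            eligible.append(child)
        tb = len(nodes)
    perm = rng.permutation(len(eligible))
    mu = _truncated_lognormal_mu(
        params.internode_length_median_um,
        params.internode_length_sigma,
        params.internode_min_length_um,
    )
    placed = 0
    for idx in perm:
        if placed >= quota:
            break
        node = eligible[idx]
        parent = nodes[node.parent]
        if parent.kind == "internode":
            continue
        if any(nodes[c].kind == "internode" for c in node.children):
            continue
        node.kind = "internode"
        node.target_length = _truncated_lognormal(
            rng, mu, params.internode_length_sigma,
            params.internode_min_length_um,
        )
        placed += 1

    # assign transverse (y, z) positions inside the envelope cross-section.
    # internodes sharing a connecting branch share its endpoint, hence one
    # position per connecting branch; positions tile the cross-section so
    # its configured extents are realised when >= 2 connectors exist.
    connectors = sorted(
        {n.parent for n in nodes if n.kind == "internode"}
    )
    m = len(connectors)
    py, pz = params.envelope_perpendicular_um / 2, params.envelope_z_um / 2
    if m == 1:
        positions = [(0.0, 0.0)]
    else:
        ys = np.linspace(-py, py, m)
        zs = np.linspace(-pz, pz, m)
        if m > 2:  # jitter interior points, keep the extremes pinned
            ys[1:-1] += rng.uniform(-py / m, py / m, m - 2)
            zs[1:-1] += rng.uniform(-pz / m, pz / m, m - 2)
        positions = list(zip(ys, zs[rng.permutation(m)]))
        rng.shuffle(positions)
    for conn_id, pos in zip(connectors, positions):
        for c in nodes[conn_id].children:
            if nodes[c].kind == "internode":
                nodes[c].transverse = (float(pos[0]), float(pos[1]))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _emit_geometry(
    rng: np.random.Generator, nodes: list[_Node], params: MorphGenParams
) -> list[ReconPoint]:
    """Walk the topology arbor by arbor emitting SWC points."""
    points: list[ReconPoint] = [
        ReconPoint(1, SOMA_CODE, 0.0, 0.0, 0.0, params.soma_radius_um, -1)
    ]
    next_id = 2
    py, pz = params.envelope_perpendicular_um / 2, params.envelope_z_um / 2
    jit = math.tan(math.radians(params.internode_jitter_deg))

    def add_point(xyz: np.ndarray, code: int, radius: float, parent: int) -> int:
        nonlocal next_id
        pid = next_id
        next_id += 1
        points.append(
            ReconPoint(pid, code, round(float(xyz[0]), 4), round(float(xyz[1]), 4),
                       round(float(xyz[2]), 4), radius, parent)
        )
        return pid

    by_id = {n.node_id: n for n in nodes}
    order = sorted(nodes, key=lambda n: (n.arbor, n.depth, n.node_id))
    for node in order:
        if node.parent is None:
            start = np.zeros(3)
            theta = rng.uniform(0, 2 * math.pi)
            direction = _unit(
                np.array([math.cos(theta), math.sin(theta), 0.15 * rng.normal()])
            )
            parent_pid = 1
        else:
            parent_node = by_id[node.parent]
            start = parent_node.end_xyz
            direction = _unit(
                parent_node.end_dir + rng.normal(0.0, 0.6, 3) * [1, 1, 0.4]
            )
            parent_pid = parent_node.point_ids[-1]

        if node.kind == "internode":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            d = _unit(np.array([sign, rng.normal(0, jit), rng.normal(0, jit)]))
            length = node.target_length
            n_steps = max(2, int(math.ceil(length / params.internode_step_um)))
            step = length / n_steps
            xyz = start.copy()
            pids = []
            for _ in range(n_steps):
                xyz = xyz + d * step
                xyz[1] = min(max(xyz[1], -py), py)
                xyz[2] = min(max(xyz[2], -pz), pz)
                pid = add_point(xyz, params.annotation_code,
                                params.internode_radius_um, parent_pid)
                pids.append(pid)
                parent_pid = pid
            node.point_ids = pids
            node.end_xyz = xyz
            node.end_dir = d
            chain = np.vstack([start] + [
                [points[p - 1].x, points[p - 1].y, points[p - 1].z] for p in pids
            ])
            node.realized_length = morphometry.polyline_length(chain)
        else:
            targets = [
                by_id[c].transverse for c in node.children
                if by_id[c].kind == "internode"
            ]
            if targets:
                y_t, z_t = targets[0]
                x_t = start[0] + (1 if rng.random() < 0.5 else -1) * rng.uniform(6, 16)
                end = np.array([x_t, y_t, z_t])
                dist = np.linalg.norm(end - start)
                n_steps = max(2, int(math.ceil(dist / params.fine_step_um)))
                waypoints = [
                    start + (end - start) * (k / n_steps)
                    + np.append(rng.normal(0, 0.5, 2), rng.normal(0, 0.3))
                    for k in range(1, n_steps)
                ] + [end]
            else:
                length = float(rng.lognormal(
                    math.log(params.fine_length_median_um), params.fine_length_sigma
                ))
                n_steps = max(1, int(math.ceil(length / params.fine_step_um)))
                step = length / n_steps
                waypoints = []
                d = direction
                xyz = start.copy()
                for _ in range(n_steps):
                    d = _unit(d + rng.normal(0.0, 0.25, 3) * [1, 1, 0.3])
                    xyz = xyz + d * step
                    waypoints.append(xyz.copy())
                direction = d
            pids = []
            for xyz in waypoints:
                pid = add_point(np.asarray(xyz), FINE_CODE,
                                params.fine_radius_um, parent_pid)
                pids.append(pid)
                parent_pid = pid
            node.point_ids = pids
            last = points[pids[-1] - 1]
            node.end_xyz = np.array([last.x, last.y, last.z])
            node.end_dir = _unit(node.end_xyz - start) if targets else direction
            chain = np.vstack([start] + [
                [points[p - 1].x, points[p - 1].y, points[p - 1].z] for p in pids
            ])
            node.realized_length = morphometry.polyline_length(chain)
    return points


def generate_cell(params: MorphGenParams) -> tuple[CellReconstruction, GroundTruth]:
    """Generate one annotated synthetic cell plus its ground truth.

    The emitted SWC is valid (single soma root, one connected component)
    and internode points carry the annotation structure code and the
    thick radius.  Identical params (including seed) give identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    nodes = _build_topology(rng, params)
    _place_internodes(rng, nodes, params)
    points = _emit_geometry(rng, nodes, params)
    recon = CellReconstruction(
        points=points,
        cell_id=f"synthetic-{params.seed}",
        comments=[f"synthetic transitional oligodendrocyte, seed {params.seed}"],
    )
    internodes = [
        InternodeTruth(
            point_ids=list(n.point_ids),
            length_um=n.realized_length,
            initiation_order=n.depth,
            arbor_index=n.arbor,
        )
        for n in nodes
        if n.kind == "internode"
    ]
    tb = len(nodes)
    ino_pts = np.array(
        [
            [p.y, p.z]
            for p in points
            if p.sample_id in {i for t in internodes for i in t.point_ids}
        ]
    )
    gt = GroundTruth(
        cell_id=recon.cell_id,
        arbor_count=len({n.arbor for n in nodes}),
        total_branches=tb,
        internodes=internodes,
        m_pb_over_tb=len(internodes) / tb if tb else 0.0,
        fragment_count=0,
        envelope_perpendicular_um=(
            float(np.ptp(ino_pts[:, 0])) if len(ino_pts) else None
        ),
        envelope_z_um=float(np.ptp(ino_pts[:, 1])) if len(ino_pts) else None,
    )
    return recon, gt


# ---------------------------------------------------------------------------
# injury
# ---------------------------------------------------------------------------

def apply_injury(
    recon: CellReconstruction, gt: GroundTruth, params: InjuryParams
) -> tuple[CellReconstruction, GroundTruth]:
    """Complement-injury transform.

    Each internode branch (with its distal subtree) is deleted with
    ``internode_deletion_probability``; each remaining branch segment is
    detached from its parent (becoming a new root / fragment) with
    ``fragment_detach_probability``.  The ground truth is updated to the
    surviving internodes and the resulting fragment count.
    """
    rng = np.random.default_rng(params.seed)
    children = recon.children_map()

    deleted: set[int] = set()
    surviving = []
    for ino in gt.internodes:
        if rng.random() < params.internode_deletion_probability:
            stack = [ino.point_ids[0]]
            while stack:
                sid = stack.pop()
                if sid in deleted:
                    continue
                deleted.add(sid)
                stack.extend(children[sid])
        else:
            surviving.append(ino)

    kept = [p for p in recon.points if p.sample_id not in deleted]
    interim = CellReconstruction(
        points=kept, cell_id=recon.cell_id, unit_scale=recon.unit_scale,
        comments=list(recon.comments),
    )

    # detach surviving branch segments with the configured probability
    decomp = morphometry.decompose(interim)
    detach_heads: set[int] = set()
    for sid in sorted(decomp.segments):
        seg = decomp.segments[sid]
        if rng.random() < params.fragment_detach_probability:
            detach_heads.add(seg.proper_point_ids[0])
    final_points = []
    for p in interim.points:
        if p.sample_id in detach_heads:
            p = ReconPoint(p.sample_id, p.structure_code, p.x, p.y, p.z,
                           p.radius, -1)
        final_points.append(p)
    injured = CellReconstruction(
        points=final_points, cell_id=recon.cell_id, unit_scale=recon.unit_scale,
        comments=list(recon.comments) + ["complement injury applied"],
    )
    new_gt = GroundTruth(
        cell_id=gt.cell_id,
        arbor_count=gt.arbor_count,
        total_branches=gt.total_branches,
        internodes=surviving,
        m_pb_over_tb=gt.m_pb_over_tb,
        fragment_count=injured.n_components - 1,
        envelope_perpendicular_um=gt.envelope_perpendicular_um,
        envelope_z_um=gt.envelope_z_um,
    )
    return injured, new_gt


# ---------------------------------------------------------------------------
# presets and cohorts
# ---------------------------------------------------------------------------

#: control condition: long internodes, ~28% of branches myelinating
CONTROL_PRESET = dict(
    internode_length_median_um=85.0,
    internode_length_sigma=0.293,
    m_pb_fraction=0.28,
    branch_p0=0.38,
    branch_decay=0.82,
)

#: chronic activity blockade: shorter internodes, fewer myelinating
#: branches, ~20% more branches overall
TTX_PRESET = dict(
    internode_length_median_um=54.0,
    internode_length_sigma=0.542,
    m_pb_fraction=0.20,
    branch_p0=0.46,
    branch_decay=0.80,
)

PRESETS = {"control": CONTROL_PRESET, "ttx": TTX_PRESET, "injury": CONTROL_PRESET}


def preset_params(name: str, seed: int = 0, **overrides) -> MorphGenParams:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return MorphGenParams(seed=seed, **kw)


def generate_cohort(
    preset: str, n: int, seed: int = 0, **overrides
) -> list[tuple[CellReconstruction, GroundTruth]]:
    """Generate ``n`` cells of a preset condition.

    Per-cell seeds are drawn from a generator seeded with ``seed`` so the
    cohort is reproducible as a whole.  The ``injury`` preset generates
    control-like cells and applies the injury transform to each.
    """
    rng = np.random.default_rng(seed)
    cell_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for s in cell_seeds:
        recon, gt = generate_cell(preset_params(preset, seed=int(s), **overrides))
        if preset == "injury":
            recon, gt = apply_injury(recon, gt, InjuryParams(seed=int(s)))
        out.append((recon, gt))
    return out


# ---------------------------------------------------------------------------
# colocalization images
# ---------------------------------------------------------------------------

@dataclass
class ImageTruth:
    nf_mask: np.ndarray  # true fiber pixels (2-D bool)
    covered_mask: np.ndarray  # true myelin-covered fiber pixels
    coverage: float  # |covered| / |fiber|


def generate_coloc_image(
    params: ImageGenParams,
) -> tuple[np.ndarray, np.ndarray, ImageTruth]:
    """Generate an (NF200 stack, MBP stack, truth) triple.

    Fibers are near-horizontal thick lines spanning the field; the MBP
    signal covers a contiguous fraction ``coverage`` of each fiber's
    pixels.  Both stacks share fiber geometry across planes with
    plane-wise intensity variation, so a maximum projection recovers the
    full fiber set.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    nf_mask = np.zeros((h, w), dtype=bool)
    covered_mask = np.zeros((h, w), dtype=bool)
    for _ in range(params.n_fibers):
        r0 = rng.integers(2, h - 2 - params.fiber_width_px)
        slope = math.tan(math.radians(rng.uniform(-10, 10)))
        cols = np.arange(w)
        rows = np.clip(np.round(r0 + slope * cols).astype(int), 0,
                       h - params.fiber_width_px)
        fiber = np.zeros((h, w), dtype=bool)
        for off in range(params.fiber_width_px):
            fiber[rows + off, cols] = True
        fiber &= ~nf_mask  # crossings belong to the first-drawn fiber
        nf_mask |= fiber
        # contiguous covered run of the configured fraction of columns
        n_cov = int(round(params.coverage * w))
        if n_cov > 0:
            start = int(rng.integers(0, w - n_cov + 1))
            cov_cols = np.zeros(w, dtype=bool)
            cov_cols[start:start + n_cov] = True
            cov = fiber & cov_cols[None, :]
            covered_mask |= cov
    n_fiber_px = int(nf_mask.sum())
    coverage_true = float(covered_mask.sum() / n_fiber_px) if n_fiber_px else 0.0

    def stack_from(mask: np.ndarray) -> np.ndarray:
        planes = []
        for _ in range(params.planes):
            factor = rng.uniform(0.75, 1.0)
            img = np.full((h, w), params.background, dtype=float)
            img[mask] = params.fiber_intensity * factor
            if params.noise_sd > 0:
                img = img + rng.normal(0, params.noise_sd, (h, w))
            planes.append(np.clip(img, 0, None))
        return np.stack(planes)

    return stack_from(nf_mask), stack_from(covered_mask), ImageTruth(
        nf_mask=nf_mask, covered_mask=covered_mask, coverage=coverage_true
    )
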