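"""Identification of putative internodes on decomposed cells.

A putative internode is a thickened, longitudinal (nearly straight) run
of branch segments reached from a fine connecting branch.  Two
classification modes are supported:

``annotation``
    Internode membership is read from SWC structure codes: a segment is
    myelinating (``M_PB``) iff more than half of its proper points carry
    the annotation code (default 7).  Used when the tracing already
    delimits internodes.

``criteria``
    Internodes are reconstructed from geometry.  A candidate run starts
    at a segment whose median radius is at least ``radius_ratio`` times
    that of its parent (the fine connecting branch), and extends through
    child segments of comparable thickness.  The run is accepted as an
    internode when its total path length reaches ``min_length_um`` and
    its main path is sufficiently straight (end-to-end distance / path
    length >= ``min_straightness``).

Contiguous myelinating segments merge into a single internode; fine
branches sprouting from an internode are classified independently and do
not split it.  ``M_PB/TB`` and ``NM_PB/TB`` are the per-cell maturation
ratios (myelinating / non-myelinating branches over total branches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import BranchSegment, DecomposedCell, total_branches
from .swc import DEFAULT_INTERNODE_CODE

M_PB = "M_PB"
NM_PB = "NM_PB"


class NoAnnotationsError(ValueError):
    """Annotation-mode classification requested on a cell with no
    annotated points (would otherwise silently report zero internodes)."""


@dataclass(frozen=True)
class InternodeCriteria:
    """Thresholds governing internode classification.

    mode
        ``"annotation"``, ``"criteria"``, or ``"auto"`` (annotation when
        annotated points are present, criteria otherwise).
    annotation_code
        SWC structure code marking internode points.
    min_length_um
        Minimum path length of a candidate run.  The default (25 um)
        sits just below the shortest putative internode observed in
        cerebellar slice cultures (~29 um).
    radius_ratio
        Minimum ratio of a run's median radius to its parent connecting
        branch's median radius ("thickened" vs "fine").
    min_straightness
        Minimum end-to-end / path-length ratio of the run's main path
        ("longitudinal" segments).
    """

    mode: str = "auto"
    annotation_code: int = DEFAULT_INTERNODE_CODE
    min_length_um: float = 25.0
    radius_ratio: float = 2.0
    min_straightness: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in ("annotation", "criteria", "auto"):
            raise ValueError(f"unknown classification mode {self.mode!r}")
        if self.min_length_um <= 0:
            raise ValueError("min_length_um must be positive")
        if self.radius_ratio < 1:
            raise ValueError("radius_ratio must be >= 1")
        if not 0 < self.min_straightness <= 1:
            raise ValueError("min_straightness must be in (0, 1]")

    def resolve_mode(self, decomp: DecomposedCell) -> str:
        if self.mode != "auto":
            return self.mode
        has_codes = any(
            p.structure_code == self.annotation_code for p in decomp.recon.points
        )
        return "annotation" if has_codes else "criteria"


@dataclass
class Internode:
    """A classified myelinating run: one putative myelin sheath."""

    internode_id: int
    segment_ids: tuple[int, ...]
    length: float
    initiation_order: int
    arbor_id: int


@dataclass
class InternodeSummary:
    cell_id: str
    internode_count: int
    lengths: list[float]
    min_initiation_order: int | None
    max_initiation_order: int | None
    mean_initiation_order: float | None
    max_internodes_per_arbor: int
    m_pb_over_tb: float
    nm_pb_over_tb: float
    total_branches: int
    tb_mode: str


@dataclass
class SpatialEnvelope:
    """Spatial extent of the internode point cloud.

    ``axis`` is the first principal direction of the internode points
    projected to the XY plane (a proxy for the white-matter path);
    ``perpendicular_extent`` is the range along the in-plane orthogonal
    direction and ``z_extent`` the range along Z, both in micrometres.
    """

    axis: tuple[float, float]
    perpendicular_extent: float
    z_extent: float


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _annotation_labels(
    decomp: DecomposedCell, criteria: InternodeCriteria
) -> dict[int, str]:
    code = criteria.annotation_code
    annotated = {
        p.sample_id for p in decomp.recon.points if p.structure_code == code
    }
    if not annotated:
        raise NoAnnotationsError(
            f"{decomp.cell_id}: annotation mode requested but no point carries "
            f"structure code {code}"
        )
    labels = {}
    for sid, seg in decomp.segments.items():
        proper = seg.proper_point_ids
        n_ann = sum(1 for i in proper if i in annotated)
        labels[sid] = M_PB if proper and n_ann * 2 > len(proper) else NM_PB
    return labels


def _run_main_path(
    decomp: DecomposedCell, run: list[BranchSegment]
) -> tuple[float, float]:
    """(end-to-end distance, path length) of the run's longest root-to-tip
    path, where "root" is the run's most proximal segment."""
    run_ids = {s.segment_id for s in run}
    root = min(run, key=lambda s: s.centrifugal_order)

    best = (0.0, root)

    def walk(seg: BranchSegment, acc: float) -> None:
        nonlocal best
        acc += seg.length
        kids = [
            decomp.segments[c] for c in seg.child_segment_ids if c in run_ids
        ]
        if not kids:
            if acc > best[0]:
                best = (acc, seg)
            return
        for k in kids:
            walk(k, acc)

    walk(root, 0.0)
    path_len, end_seg = best
    start = decomp.segment_points(root)[0]
    end = decomp.segment_points(end_seg)[-1]
    return float(np.linalg.norm(end - start)), path_len


def _criteria_runs(
    decomp: DecomposedCell, criteria: InternodeCriteria
) -> list[list[BranchSegment]]:
    """Maximal candidate runs of thick segments, before threshold checks."""
    runs: list[list[BranchSegment]] = []
    in_run: set[int] = set()
    # proximal-first traversal so a run is grown before its descendants are
    # considered as fresh run starts
    order = sorted(
        decomp.segments.values(),
        key=lambda s: (s.centrifugal_order, s.segment_id),
    )
    for seg in order:
        if seg.segment_id in in_run or seg.parent_segment_id is None:
            continue
        parent = decomp.segments[seg.parent_segment_id]
        if parent.segment_id in in_run:
            continue
        if seg.median_radius < criteria.radius_ratio * parent.median_radius:
            continue
        # grow the run distally through children of comparable thickness
        ref = seg.median_radius
        run = []
        stack = [seg]
        while stack:
            s = stack.pop()
            run.append(s)
            in_run.add(s.segment_id)
            for cid in s.child_segment_ids:
                child = decomp.segments[cid]
                if child.median_radius * criteria.radius_ratio >= ref:
                    stack.append(child)
        runs.append(run)
    return runs


def classify_branches(
    decomp: DecomposedCell, criteria: InternodeCriteria | None = None
) -> dict[int, str]:
    """Label every branch segment ``M_PB`` or ``NM_PB``."""
    criteria = criteria or InternodeCriteria()
    mode = criteria.resolve_mode(decomp)
    if mode == "annotation":
        return _annotation_labels(decomp, criteria)
    labels = {sid: NM_PB for sid in decomp.segments}
    for run in _criteria_runs(decomp, criteria):
        total_len = sum(s.length for s in run)
        if total_len < criteria.min_length_um:
            continue
        chord, path_len = _run_main_path(decomp, run)
        if path_len > 0 and chord / path_len < criteria.min_straightness:
            continue
        for s in run:
            labels[s.segment_id] = M_PB
    return labels


# ---------------------------------------------------------------------------
# internode assembly and summaries
# ---------------------------------------------------------------------------

def identify_internodes(
    decomp: DecomposedCell,
    criteria: InternodeCriteria | None = None,
    labels: dict[int, str] | None = None,
) -> list[Internode]:
    """Merge contiguous myelinating segments into internodes.

    Adjacent (parent-child) ``M_PB`` segments belong to the same
    internode; runs separated by a non-myelinating connecting branch are
    distinct internodes.  An empty list is a valid outcome (the injury
    phenotype).  Ordering is deterministic: by arbor, then by the minimum
    segment id of the member run.
    """
    if labels is None:
        labels = classify_branches(decomp, criteria)
    m_ids = {sid for sid, lab in labels.items() if lab == M_PB}
    seen: set[int] = set()
    groups: list[list[int]] = []
    for sid in sorted(m_ids):
        if sid in seen:
            continue
        group = []
        stack = [sid]
        while stack:
            s = stack.pop()
            if s in seen:
                continue
            seen.add(s)
            group.append(s)
            seg = decomp.segments[s]
            neighbours = list(seg.child_segment_ids)
            if seg.parent_segment_id is not None:
                neighbours.append(seg.parent_segment_id)
            stack.extend(n for n in neighbours if n in m_ids and n not in seen)
        groups.append(sorted(group))
    groups.sort(key=lambda g: (decomp.segments[g[0]].arbor_id, g[0]))
    internodes = []
    for k, group in enumerate(groups):
        segs = [decomp.segments[s] for s in group]
        internodes.append(
            Internode(
                internode_id=k,
                segment_ids=tuple(group),
                length=float(sum(s.length for s in segs)),
                initiation_order=min(s.centrifugal_order for s in segs),
                arbor_id=segs[0].arbor_id,
            )
        )
    return internodes


def internode_summary(
    decomp: DecomposedCell,
    internodes: list[Internode],
    labels: dict[int, str],
    tb_mode: str = "all_segments",
) -> InternodeSummary:
    """Per-cell internode statistics and branch-class ratios.

    ``m_pb_over_tb`` uses the number of M_PB segments over TB (same
    denominator as ``nm_pb_over_tb``; the two sum to 1 exactly).  With
    zero internodes the order statistics are absent but the ratios remain
    defined.
    """
    tb = total_branches(decomp, tb_mode)
    n_m = sum(1 for lab in labels.values() if lab == M_PB)
    if tb_mode == "terminal_tips":
        n_m = sum(
            1
            for sid, lab in labels.items()
            if lab == M_PB and decomp.segments[sid].is_tip
        )
    m_ratio = n_m / tb if tb else 0.0
    orders = [i.initiation_order for i in internodes]
    per_arbor: dict[int, int] = {}
    for i in internodes:
        per_arbor[i.arbor_id] = per_arbor.get(i.arbor_id, 0) + 1
    return InternodeSummary(
        cell_id=decomp.cell_id,
        internode_count=len(internodes),
        lengths=[i.length for i in internodes],
        min_initiation_order=min(orders) if orders else None,
        max_initiation_order=max(orders) if orders else None,
        mean_initiation_order=float(np.mean(orders)) if orders else None,
        max_internodes_per_arbor=max(per_arbor.values(), default=0),
        m_pb_over_tb=m_ratio,
        nm_pb_over_tb=1.0 - m_ratio,
        total_branches=tb,
        tb_mode=tb_mode,
    )


def internode_points(
    decomp: DecomposedCell, internodes: list[Internode]
) -> np.ndarray:
    """(n, 3) array of all member-segment chain points of the internodes."""
    coords = []
    for ino in internodes:
        for sid in ino.segment_ids:
            coords.append(decomp.segment_points(decomp.segments[sid]))
    return np.concatenate(coords, axis=0)


def spatial_envelope(
    internodes: list[Internode],
    decomp: DecomposedCell,
    axis: tuple[float, float] | None = None,
) -> SpatialEnvelope:
    """Spatial envelope of the internode point cloud.

    The in-plane axis is the first principal direction of the XY
    projection (sign-normalised to positive x), unless a fixed ``axis``
    override is given.  Extents are max - min of the projections.
    """
    if not internodes:
        raise ValueError("no internodes: spatial envelope undefined")
    pts = internode_points(decomp, internodes)
    xy = pts[:, :2]
    if axis is None:
        centred = xy - xy.mean(axis=0)
        cov = centred.T @ centred
        eigvals, eigvecs = np.linalg.eigh(cov)
        a = eigvecs[:, int(np.argmax(eigvals))]
        if a[0] < 0 or (a[0] == 0 and a[1] < 0):
            a = -a
    else:
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
    perp = np.array([-a[1], a[0]])
    proj = xy @ perp
    return SpatialEnvelope(
        axis=(float(a[0]), float(a[1])),
        perpendicular_extent=float(proj.max() - proj.min()),
        z_extent=float(pts[:, 2].max() - pts[:, 2].min()),
    )
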