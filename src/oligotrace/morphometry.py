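"""Topological decomposition of a reconstruction into process arbors and
inter-junction branch segments, plus the arbor-level metrics.

Terminology
-----------
A *process arbor* is the tree of branches emanating from a single soma
attachment point.  A *branch segment* is the chain of points running from
a topological node (the soma attachment, or a junction with >= 2
children) to the next junction or terminal tip; the chain includes the
starting node, which is shared with the parent segment, so that segment
lengths tile the path length of the arbor exactly.

Branch ordering is *centrifugal*: the soma-attached segment has order 1
and the order increases by one at every junction moving outward.  This is
not Strahler ordering.

Total branches (TB) per cell is reported under one of two modes:
``all_segments`` (every branch segment counts; the default) or
``terminal_tips`` (only tip-terminated segments count).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .swc import SOMA_CODE, CellReconstruction, ReconPoint

logger = logging.getLogger(__name__)

#: tolerance (um) below which consecutive duplicate points are merged
DUPLICATE_TOL = 1e-6

TB_MODES = ("all_segments", "terminal_tips")


@dataclass
class BranchSegment:
    """An inter-junction chain of points.

    ``point_ids[0]`` is the attachment node (soma point or junction)
    shared with the parent segment; the remaining ids are the segment's
    *proper* points, owned by this segment alone.
    """

    segment_id: int
    arbor_id: int
    point_ids: tuple[int, ...]
    centrifugal_order: int
    parent_segment_id: int | None
    length: float
    median_radius: float
    is_tip: bool
    child_segment_ids: list[int] = field(default_factory=list)

    @property
    def proper_point_ids(self) -> tuple[int, ...]:
        return self.point_ids[1:]


@dataclass
class ProcessArbor:
    """All branch segments descending from one soma attachment."""

    arbor_id: int
    root_segment_id: int
    segment_ids: list[int]
    total_length: float
    branch_point_count: int
    max_order: int
    segment_count: int
    tip_count: int
    longest_path_length: float


@dataclass
class DecomposedCell:
    """A reconstruction decomposed into arbors and segments.

    Fragments (connected components that do not contain the soma) are not
    decomposed into arbors; their count is reported as
    ``fragment_count``.
    """

    recon: CellReconstruction
    soma_ids: list[int]
    soma_is_surrogate: bool
    arbors: list[ProcessArbor]
    segments: dict[int, BranchSegment]
    fragment_count: int
    merged_duplicates: int

    @property
    def cell_id(self) -> str:
        return self.recon.cell_id

    def arbor_segments(self, arbor: ProcessArbor) -> list[BranchSegment]:
        return [self.segments[s] for s in arbor.segment_ids]

    def segment_points(self, seg: BranchSegment) -> np.ndarray:
        """(n, 3) coordinate array for a segment's chain (in um)."""
        pts = [self.recon.point(i).xyz for i in seg.point_ids]
        return np.asarray(pts, dtype=float) * self.recon.unit_scale


def polyline_length(coords: np.ndarray) -> float:
    """Sum of consecutive 3-D Euclidean distances along a polyline."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(coords, axis=0), axis=1)))


def segment_length(
    seg: BranchSegment | np.ndarray, decomp: DecomposedCell | None = None
) -> float:
    """Path length of a segment (or raw polyline) in micrometres.

    A single-point chain has length 0 and triggers a warning.
    """
    if isinstance(seg, BranchSegment):
        if decomp is None:
            raise ValueError("segment_length(BranchSegment) needs the DecomposedCell")
        coords = decomp.segment_points(seg)
    else:
        coords = np.asarray(seg, dtype=float)
    if len(coords) < 2:
        warnings.warn("single-point segment has zero length", stacklevel=2)
        return 0.0
    return polyline_length(coords)


def _merge_duplicates(
    recon: CellReconstruction, tol: float = DUPLICATE_TOL
) -> tuple[CellReconstruction, int]:
    """Drop points lying within ``tol`` um of their parent, reattaching
    children to the parent.  Returns (clean recon, number merged)."""
    index = {p.sample_id: p for p in recon.points}
    drop: dict[int, int] = {}  # dropped id -> surviving ancestor id
    for p in recon.points:
        if p.parent_id == -1:
            continue
        parent = index[p.parent_id]
        d = math.dist(p.xyz, parent.xyz) * recon.unit_scale
        if d < tol and p.structure_code != SOMA_CODE:
            drop[p.sample_id] = p.parent_id
    if not drop:
        return recon, 0

    def survivor(sid: int) -> int:
        while sid in drop:
            sid = drop[sid]
        return sid

    pts = []
    for p in recon.points:
        if p.sample_id in drop:
            continue
        parent = p.parent_id if p.parent_id == -1 else survivor(p.parent_id)
        if parent != p.parent_id:
            p = ReconPoint(
                p.sample_id, p.structure_code, p.x, p.y, p.z, p.radius, parent
            )
        pts.append(p)
    clean = CellReconstruction(
        points=pts,
        cell_id=recon.cell_id,
        unit_scale=recon.unit_scale,
        comments=list(recon.comments),
    )
    return clean, len(drop)


def _resolve_soma(recon: CellReconstruction) -> tuple[list[int], bool]:
    """Soma sample ids, falling back to the root of the largest component
    when no structure-code-1 point exists (with a logged warning)."""
    soma = recon.soma_ids
    if soma:
        return soma, False
    comps = recon.component_ids()
    largest = max(comps, key=len)
    roots = [i for i in largest if recon.point(i).parent_id == -1]
    surrogate = min(roots)
    logger.warning(
        "%s: no soma point (code 1); using root sample %d of the largest "
        "component as soma surrogate",
        recon.cell_id,
        surrogate,
    )
    return [surrogate], True


def decompose(recon: CellReconstruction) -> DecomposedCell:
    """Decompose a cell into soma-rooted arbors and branch segments.

    Zero-length duplicate points are merged first.  One arbor is created
    per neurite point whose parent is a soma point; arbors are ordered by
    ascending minimum sample id of their root point.  Every non-soma
    point of the soma's component belongs to exactly one arbor.
    """
    recon, merged = _merge_duplicates(recon)
    soma_ids, surrogate = _resolve_soma(recon)
    soma_set = set(soma_ids)
    children = recon.children_map()

    arbor_roots = []
    for sid in soma_ids:
        for child in children[sid]:
            if child not in soma_set:
                arbor_roots.append((child, sid))
    arbor_roots.sort()

    segments: dict[int, BranchSegment] = {}
    arbors: list[ProcessArbor] = []
    seg_counter = 0

    for arbor_id, (root_pt, soma_pt) in enumerate(arbor_roots):
        arbor_seg_ids: list[int] = []
        # stack entries: (first proper point, attachment point, order, parent seg)
        stack: list[tuple[int, int, int, int | None]] = [
            (root_pt, soma_pt, 1, None)
        ]
        root_seg_id = seg_counter
        # path length from the arbor attachment to each segment end
        path_to_end: dict[int, float] = {}
        while stack:
            first, attach, order, parent_seg = stack.pop()
            chain = [attach, first]
            cur = first
            while len(children[cur]) == 1:
                cur = children[cur][0]
                chain.append(cur)
            sid = seg_counter
            seg_counter += 1
            coords = (
                np.asarray([recon.point(i).xyz for i in chain], dtype=float)
                * recon.unit_scale
            )
            radii = [recon.point(i).radius * recon.unit_scale for i in chain[1:]]
            kids = children[cur]
            seg = BranchSegment(
                segment_id=sid,
                arbor_id=arbor_id,
                point_ids=tuple(chain),
                centrifugal_order=order,
                parent_segment_id=parent_seg,
                length=polyline_length(coords),
                median_radius=float(np.median(radii)),
                is_tip=not kids,
            )
            segments[sid] = seg
            arbor_seg_ids.append(sid)
            if parent_seg is not None:
                segments[parent_seg].child_segment_ids.append(sid)
                path_to_end[sid] = path_to_end[parent_seg] + seg.length
            else:
                path_to_end[sid] = seg.length
            # LIFO stack: push children in reverse file order so traversal
            # (and segment ids) follow ascending child order deterministically
            for child in reversed(kids):
                stack.append((child, cur, order + 1, sid))

        segs = [segments[s] for s in arbor_seg_ids]
        tips = [s for s in segs if s.is_tip]
        arbors.append(
            ProcessArbor(
                arbor_id=arbor_id,
                root_segment_id=root_seg_id,
                segment_ids=arbor_seg_ids,
                total_length=float(sum(s.length for s in segs)),
                branch_point_count=sum(1 for s in segs if len(s.child_segment_ids) >= 2),
                max_order=max(s.centrifugal_order for s in segs),
                segment_count=len(segs),
                tip_count=len(tips),
                longest_path_length=max(path_to_end[s.segment_id] for s in tips),
            )
        )

    # fragments: components not containing the soma
    comps = recon.component_ids()
    fragment_count = sum(1 for c in comps if not soma_set.intersection(c))

    return DecomposedCell(
        recon=recon,
        soma_ids=soma_ids,
        soma_is_surrogate=surrogate,
        arbors=arbors,
        segments=segments,
        fragment_count=fragment_count,
        merged_duplicates=merged,
    )


def arbor_metrics(arbor: ProcessArbor) -> tuple[float, int, int]:
    """(total_length_um, branch_point_count, max_order) for one arbor."""
    return (arbor.total_length, arbor.branch_point_count, arbor.max_order)


def total_branches(decomp: DecomposedCell, mode: str = "all_segments") -> int:
    """Total branches (TB) per cell under the configured counting mode."""
    if mode not in TB_MODES:
        raise ValueError(f"unknown TB mode {mode!r}; expected one of {TB_MODES}")
    if mode == "all_segments":
        return sum(a.segment_count for a in decomp.arbors)
    return sum(a.tip_count for a in decomp.arbors)
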