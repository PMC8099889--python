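"""Reading, validating and writing SWC neurite reconstructions.

The SWC dialect accepted here is the one produced by NeuronStudio and
FIJI's Simple Neurite Tracer: seven whitespace-separated columns
(``sample_id structure_code x y z radius parent_id``), ``#`` comment
lines, blank lines ignored.  Sample ids need not be consecutive or
sorted.  A file may contain several points with ``parent_id == -1``
(several roots); such a file describes a cell with multiple connected
components, which is how fragmented (injured) cells are represented.

Coordinates are treated as micrometres unless a ``unit_scale`` is
supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

SOMA_CODE = 1
#: structure code conventionally used to annotate internode membership
DEFAULT_INTERNODE_CODE = 7


class SWCParseError(ValueError):
    """A line of the file could not be parsed (column count / numerics)."""


class SWCStructureError(ValueError):
    """The parsed points violate the structural invariants of an SWC forest."""


@dataclass(frozen=True)
class ReconPoint:
    """One traced sample point.

    ``parent_id == -1`` marks a root.  ``radius`` and the coordinates are
    in the file's native units (micrometres by convention).
    """

    sample_id: int
    structure_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class CellReconstruction:
    """A traced cell: a forest of :class:`ReconPoint`.

    Invariants (checked at construction):

    * sample ids unique, radii positive, coordinates finite;
    * every ``parent_id`` is -1 or an existing sample id;
    * the parent graph is acyclic with at least one root.

    Connected components are enumerated deterministically by ascending
    minimum sample id.
    """

    points: list[ReconPoint]
    cell_id: str = "cell"
    unit_scale: float = 1.0
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        if not self.points:
            raise SWCStructureError(f"{self.cell_id}: reconstruction has no points")
        if self.unit_scale <= 0:
            raise SWCStructureError(f"{self.cell_id}: unit_scale must be positive")
        index: dict[int, ReconPoint] = {}
        for p in self.points:
            if p.sample_id in index:
                raise SWCStructureError(
                    f"{self.cell_id}: duplicate sample_id {p.sample_id}"
                )
            if p.sample_id <= 0:
                raise SWCStructureError(
                    f"{self.cell_id}: sample_id must be positive, got {p.sample_id}"
                )
            if p.radius <= 0:
                raise SWCStructureError(
                    f"{self.cell_id}: sample {p.sample_id} has non-positive radius"
                )
            if not all(math.isfinite(v) for v in (p.x, p.y, p.z, p.radius)):
                raise SWCStructureError(
                    f"{self.cell_id}: sample {p.sample_id} has non-finite values"
                )
            index[p.sample_id] = p
        roots = []
        for p in self.points:
            if p.parent_id == -1:
                roots.append(p.sample_id)
            elif p.parent_id not in index:
                raise SWCStructureError(
                    f"{self.cell_id}: sample {p.sample_id} references missing "
                    f"parent {p.parent_id}"
                )
            elif p.parent_id == p.sample_id:
                raise SWCStructureError(
                    f"{self.cell_id}: sample {p.sample_id} is its own parent"
                )
        if not roots:
            raise SWCStructureError(f"{self.cell_id}: no root point (parent_id -1)")
        self._index = index
        # cycle check: every point must reach a root through parent links
        root_of: dict[int, int] = {}
        for p in self.points:
            chain = []
            sid = p.sample_id
            while sid not in root_of:
                chain.append(sid)
                parent = index[sid].parent_id
                if parent == -1:
                    root_of[sid] = sid
                    break
                if parent in chain:
                    raise SWCStructureError(
                        f"{self.cell_id}: cycle involving samples {sorted(chain)}"
                    )
                sid = parent
            root = root_of[sid] if sid in root_of else root_of[chain[-1]]
            for c in chain:
                root_of[c] = root
        self._root_of = root_of

    # -- basic accessors ----------------------------------------------
    def __len__(self) -> int:
        return len(self.points)

    def point(self, sample_id: int) -> ReconPoint:
        return self._index[sample_id]

    def __contains__(self, sample_id: int) -> bool:
        return sample_id in self._index

    @property
    def sample_ids(self) -> list[int]:
        return [p.sample_id for p in self.points]

    @property
    def soma_ids(self) -> list[int]:
        return [p.sample_id for p in self.points if p.structure_code == SOMA_CODE]

    @property
    def root_ids(self) -> list[int]:
        return [p.sample_id for p in self.points if p.parent_id == -1]

    def children_map(self) -> dict[int, list[int]]:
        """Map sample id -> child sample ids, in file order."""
        children: dict[int, list[int]] = {p.sample_id: [] for p in self.points}
        for p in self.points:
            if p.parent_id != -1:
                children[p.parent_id].append(p.sample_id)
        return children

    # -- components ---------------------------------------------------
    def component_ids(self) -> list[list[int]]:
        """Connected components as lists of sample ids.

        Components are ordered by ascending minimum sample id; ids inside a
        component keep file order.
        """
        groups: dict[int, list[int]] = {}
        for p in self.points:
            groups.setdefault(self._root_of[p.sample_id], []).append(p.sample_id)
        return sorted(groups.values(), key=min)

    @property
    def n_components(self) -> int:
        return len(set(self._root_of.values()))


def _parse_line(line: str, lineno: int, path: str) -> ReconPoint:
    cols = line.split()
    if len(cols) != 7:
        raise SWCParseError(
            f"{path}:{lineno}: expected 7 columns, got {len(cols)}"
        )
    try:
        return ReconPoint(
            sample_id=int(cols[0]),
            structure_code=int(cols[1]),
            x=float(cols[2]),
            y=float(cols[3]),
            z=float(cols[4]),
            radius=float(cols[5]),
            parent_id=int(cols[6]),
        )
    except ValueError as exc:
        raise SWCParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None


def read_swc(
    path: str | Path,
    cell_id: str | None = None,
    unit_scale: float = 1.0,
) -> CellReconstruction:
    """Read an SWC file into a validated :class:`CellReconstruction`.

    Comment lines (``#``) are preserved in ``comments``.  Raises
    :class:`SWCParseError` for malformed lines (with line number) and
    :class:`SWCStructureError` for dangling parents, duplicate ids or
    cycles.
    """
    path = Path(path)
    points: list[ReconPoint] = []
    comments: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line.lstrip("#").strip())
                continue
            points.append(_parse_line(line, lineno, str(path)))
    return CellReconstruction(
        points=points,
        cell_id=cell_id if cell_id is not None else path.stem,
        unit_scale=unit_scale,
        comments=comments,
    )


def write_swc(recon: CellReconstruction, path: str | Path) -> None:
    """Write a reconstruction back to SWC.

    Floats are written with shortest round-trip representation, so
    ``read_swc(write_swc(r))`` reproduces the points exactly.
    """
    if not recon.points:  # pragma: no cover - unconstructible, defensive
        raise SWCStructureError("cannot write an empty reconstruction")
    path = Path(path)
    lines = [f"# {c}" for c in recon.comments]
    for p in recon.points:
        lines.append(
            f"{p.sample_id} {p.structure_code} {p.x!r} {p.y!r} {p.z!r} "
            f"{p.radius!r} {p.parent_id}"
        )
    path.write_text("\n".join(lines) + "\n")


def split_components(recon: CellReconstruction) -> list[CellReconstruction]:
    """Split a (possibly fragmented) cell into its connected components.

    Returns one :class:`CellReconstruction` per component, ordered by
    ascending minimum sample id.  Sample ids are preserved.
    """
    comps = recon.component_ids()
    out = []
    for k, ids in enumerate(comps):
        idset = set(ids)
        pts = [p for p in recon.points if p.sample_id in idset]
        out.append(
            CellReconstruction(
                points=pts,
                cell_id=f"{recon.cell_id}#{k}",
                unit_scale=recon.unit_scale,
                comments=list(recon.comments),
            )
        )
    return out
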