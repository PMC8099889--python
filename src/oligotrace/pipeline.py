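"""Batch analysis: SWC files in, per-cell / per-arbor / per-internode
metric tables out.

The per-cell table deliberately emits both aggregations wherever the
field's reporting conventions are ambiguous: branch points are given per
cell and as a per-arbor mean, arbor length as total path length and as
longest root-to-tip path, and internode length as mean and median.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import internodes as ino
from . import morphometry as morpho
from . import swc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-wide configuration (YAML-loadable).

    ``unit_scale`` converts file coordinates to micrometres; ``tb_mode``
    selects the total-branch counting convention; the remaining keys
    parameterise internode classification (see
    :class:`~oligotrace.internodes.InternodeCriteria`).
    """

    unit_scale: float = 1.0
    tb_mode: str = "all_segments"
    mode: str = "auto"
    internode_annotation_code: int = swc.DEFAULT_INTERNODE_CODE
    min_length_um: float = 25.0
    radius_ratio: float = 2.0
    min_straightness: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def criteria(self) -> ino.InternodeCriteria:
        return ino.InternodeCriteria(
            mode=self.mode,
            annotation_code=self.internode_annotation_code,
            min_length_um=self.min_length_um,
            radius_ratio=self.radius_ratio,
            min_straightness=self.min_straightness,
        )

    def provenance(self) -> dict:
        return asdict(self)


@dataclass
class CellAnalysis:
    row: dict
    arbor_rows: list[dict]
    internode_rows: list[dict]


def analyze_cell(
    recon: swc.CellReconstruction, config: AnalysisConfig | None = None
) -> CellAnalysis:
    """Run the full morphometry pipeline on one reconstruction."""
    config = config or AnalysisConfig()
    criteria = config.criteria()
    decomp = morpho.decompose(recon)
    mode = criteria.resolve_mode(decomp)
    labels = ino.classify_branches(decomp, criteria)
    internodes = ino.identify_internodes(decomp, criteria, labels=labels)
    summary = ino.internode_summary(decomp, internodes, labels, config.tb_mode)

    arbors = decomp.arbors
    lengths = summary.lengths
    if internodes:
        env = ino.spatial_envelope(internodes, decomp)
        env_perp, env_z = env.perpendicular_extent, env.z_extent
    else:
        env_perp = env_z = None
    row = {
        "cell_id": decomp.cell_id,
        "n_points": len(decomp.recon.points),
        "fragment_count": decomp.fragment_count,
        "arbor_count": len(arbors),
        "total_branches": summary.total_branches,
        "tb_mode": summary.tb_mode,
        "mean_arbor_length_um": float(np.mean([a.total_length for a in arbors]))
        if arbors else 0.0,
        "mean_arbor_longest_path_um": float(
            np.mean([a.longest_path_length for a in arbors])
        ) if arbors else 0.0,
        "branch_points_per_cell": sum(a.branch_point_count for a in arbors),
        "mean_branch_points_per_arbor": float(
            np.mean([a.branch_point_count for a in arbors])
        ) if arbors else 0.0,
        "max_branch_order": max((a.max_order for a in arbors), default=0),
        "internode_count": summary.internode_count,
        "mean_internode_length_um": float(np.mean(lengths)) if lengths else None,
        "median_internode_length_um": float(np.median(lengths)) if lengths else None,
        "internode_min_order": summary.min_initiation_order,
        "internode_max_order": summary.max_initiation_order,
        "internode_mean_order": summary.mean_initiation_order,
        "max_internodes_per_arbor": summary.max_internodes_per_arbor,
        "m_pb_over_tb": summary.m_pb_over_tb,
        "nm_pb_over_tb": summary.nm_pb_over_tb,
        "envelope_perpendicular_um": env_perp,
        "envelope_z_um": env_z,
        "classification_mode": mode,
        "soma_is_surrogate": decomp.soma_is_surrogate,
    }
    arbor_rows = [
        {
            "cell_id": decomp.cell_id,
            "arbor_id": a.arbor_id,
            "total_length_um": a.total_length,
            "longest_path_um": a.longest_path_length,
            "branch_point_count": a.branch_point_count,
            "max_order": a.max_order,
            "segment_count": a.segment_count,
            "tip_count": a.tip_count,
        }
        for a in arbors
    ]
    internode_rows = [
        {
            "cell_id": decomp.cell_id,
            "internode_id": i.internode_id,
            "length_um": i.length,
            "initiation_order": i.initiation_order,
            "arbor_id": i.arbor_id,
        }
        for i in internodes
    ]
    return CellAnalysis(row=row, arbor_rows=arbor_rows, internode_rows=internode_rows)


def analyze_cells(
    recons: list[swc.CellReconstruction], config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(cells, arbors, internodes) tables for a list of reconstructions."""
    config = config or AnalysisConfig()
    rows, arbor_rows, ino_rows = [], [], []
    for recon in recons:
        res = analyze_cell(recon, config)
        rows.append(res.row)
        arbor_rows.extend(res.arbor_rows)
        ino_rows.extend(res.internode_rows)
    ino_cols = ["cell_id", "internode_id", "length_um", "initiation_order", "arbor_id"]
    return (
        pd.DataFrame(rows),
        pd.DataFrame(arbor_rows),
        pd.DataFrame(ino_rows, columns=ino_cols),
    )


def analyze_directory(
    swc_dir: str | Path, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Analyze every ``*.swc`` file in a directory (sorted by name)."""
    config = config or AnalysisConfig()
    paths = sorted(Path(swc_dir).glob("*.swc"))
    if not paths:
        raise FileNotFoundError(f"no .swc files in {swc_dir}")
    recons = [swc.read_swc(p, unit_scale=config.unit_scale) for p in paths]
    return analyze_cells(recons, config)


def write_outputs(
    out_csv: str | Path,
    cells: pd.DataFrame,
    arbors: pd.DataFrame | None = None,
    internode_table: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> None:
    """Write the per-cell CSV plus companions and a criteria sidecar."""
    out_csv = Path(out_csv)
    cells.to_csv(out_csv, index=False)
    if arbors is not None:
        arbors.to_csv(out_csv.with_name(out_csv.stem + "_arbors.csv"), index=False)
    if internode_table is not None:
        internode_table.to_csv(
            out_csv.with_name(out_csv.stem + "_internodes.csv"), index=False
        )
    if config is not None:
        sidecar = out_csv.with_name(out_csv.stem + "_criteria.json")
        sidecar.write_text(json.dumps(config.provenance(), indent=2) + "\n")
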