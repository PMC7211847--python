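"""Whole-lifetime cell traits and inclusion/exclusion rules.

A cell enters the heritability analysis only if its full cell cycle was
observed, cytokinesis to cytokinesis: it must have a tracked mother (so its
birth was seen) and must itself have divided on screen.  Originally plated
founders, cells that moved off-screen, cells that died, and cells still
undivided when the recording ended are excluded — but their rows are kept,
flagged, because partial-lifetime speeds of off-screen cells feed the
off-screen sampling-bias check.

Traits:

* ``generation_time`` — (last frame − first frame) × frame interval, hours.
* ``speed`` — curvilinear speed: total Euclidean polyline length of the
  recorded path in microns, divided by the generation time, µm h⁻¹.

Division anchoring: a daughter's first frame equals her mother's last frame,
so mother and daughter lifespans partition time with no overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import CellTrack, LineageForest, TrackSet

EXCLUSION_REASONS = ("founder", "off_screen", "died", "censored_at_end", "none")

#: Column order of the serialized trait table.
TRAIT_COLUMNS = [
    "cell_id",
    "family_id",
    "well_id",
    "field_id",
    "generation",
    "generation_time",
    "speed",
    "path_length",
    "net_displacement",
    "complete",
    "exclusion_reason",
]


@dataclass
class CellTraits:
    cell_id: str
    family_id: str
    well_id: str
    field_id: str
    generation: int
    generation_time: float  # hours; NaN when the full cycle was not observed
    speed: float  # µm/h; partial-lifetime value for incomplete cells
    path_length: float  # µm over the recorded points
    net_displacement: float  # µm, start to end of the recorded track
    complete: bool
    exclusion_reason: str


@dataclass
class TraitTable:
    """Per-cell traits, one row per tracked cell, excluded cells flagged."""

    rows: list[CellTraits]
    frame_interval: float
    scale: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        return df[TRAIT_COLUMNS] if len(df) else pd.DataFrame(columns=TRAIT_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval=float("nan"), scale=float("nan")) -> "TraitTable":
        df = pd.read_csv(path, dtype={c: str for c in ("cell_id", "family_id", "well_id", "field_id")})
        names = [f.name for f in dc_fields(CellTraits)]
        rows = [CellTraits(**{k: rec[k] for k in names}) for rec in df.to_dict("records")]
        for r in rows:
            r.complete = bool(r.complete)
            r.generation = int(r.generation)
        return cls(rows=rows, frame_interval=frame_interval, scale=scale)

    def complete_rows(self) -> list[CellTraits]:
        return [r for r in self.rows if r.complete]

    def by_cell(self) -> dict[str, CellTraits]:
        return {r.cell_id: r for r in self.rows}


def _observed_birth(cell: CellTrack, ts: TrackSet) -> bool:
    if cell.mother_id is None:
        return False
    mother = ts.cells[cell.mother_id]
    return mother.last_frame == cell.first_frame


def _exclusion_reason(cell: CellTrack, ts: TrackSet) -> str:
    if cell.mother_id is None:
        return "founder"
    if cell.fate == "divided":
        return "none"
    return cell.fate  # off_screen | died | censored_at_end


def generation_time(cell: CellTrack, ts: TrackSet) -> float:
    """Full cell-cycle duration in hours, cytokinesis to cytokinesis.

    Requires an observed birth (the mother's track ends at this cell's first
    frame) and an observed division (``fate == "divided"``).
    """
    reason = _exclusion_reason(cell, ts)
    if reason != "none" or not _observed_birth(cell, ts):
        raise ContractError(
            f"cell {cell.cell_id!r} was not observed for a complete cycle "
            f"(exclusion_reason={reason!r})"
        )
    hours = (cell.last_frame - cell.first_frame) * ts.frame_interval / 60.0
    if hours <= 0:
        raise ContractError(f"cell {cell.cell_id!r}: non-positive lifetime")
    return hours


def _polyline_length_um(cell: CellTrack, scale: float) -> float:
    xy = cell.xy()
    if len(xy) < 2:
        return 0.0
    steps = np.diff(xy, axis=0)
    return float(scale * np.hypot(steps[:, 0], steps[:, 1]).sum())


def _net_displacement_um(cell: CellTrack, scale: float) -> float:
    xy = cell.xy()
    return float(scale * math.hypot(xy[-1, 0] - xy[0, 0], xy[-1, 1] - xy[0, 1]))


def curvilinear_speed(cell: CellTrack, ts: TrackSet) -> float:
    """Whole-lifetime curvilinear speed in µm h⁻¹.

    Total Euclidean distance along the recorded polyline (microns) divided by
    the generation time (hours).  A missing frame contributes one straight
    segment across the gap, so the path length is a lower bound there.
    """
    return _polyline_length_um(cell, ts.scale) / generation_time(cell, ts)


def compute_traits(forest: LineageForest, ts: TrackSet) -> TraitTable:
    """One trait row per cell; exclusions are recorded, never raised.

    Complete cells get whole-lifetime traits.  Incomplete cells get the speed
    over their observed interval (NaN generation time); this partial speed is
    used only by the off-screen comparison test.
    """
    rows: list[CellTraits] = []
    for family_id, node in forest.iter_cells():
        cell = ts.cells[node.cell_id]
        reason = _exclusion_reason(cell, ts)
        if reason == "none" and not _observed_birth(cell, ts):
            # Birth not actually observed (anchor mismatch): excluded like a
            # plated cell, whose cycle start is equally unseen.
            reason = "founder"
        complete = reason == "none"
        path = _polyline_length_um(cell, ts.scale)
        net = _net_displacement_um(cell, ts.scale)
        if complete:
            gt = generation_time(cell, ts)
            speed = path / gt
        else:
            gt = float("nan")
            observed_h = (cell.last_frame - cell.first_frame) * ts.frame_interval / 60.0
            speed = path / observed_h if observed_h > 0 else float("nan")
        rows.append(
            CellTraits(
                cell_id=cell.cell_id,
                family_id=family_id,
                well_id=cell.well_id,
                field_id=cell.field_id,
                generation=node.generation,
                generation_time=gt,
                speed=speed,
                path_length=path,
                net_displacement=net,
                complete=complete,
                exclusion_reason=reason,
            )
        )
    rows.sort(key=lambda r: (r.family_id, r.generation, r.cell_id))
    return TraitTable(rows=rows, frame_interval=ts.frame_interval, scale=ts.scale)


@dataclass
class FamilyCensus:
    """Counts describing how much of the tracked data is usable."""

    n_cells_tracked: int
    n_complete_cells: int
    n_families: int
    n_eligible_families: int  # families with at least one comparable cousin pair
    n_cousin_eligible_cells: int  # complete cells having >=1 complete cousin
    n_usable_cells: int  # complete cells belonging to eligible families
    usable_fraction: float
    excluded_by_reason: dict[str, int]

    def to_dict(self) -> dict:
        return dict(vars(self))


def family_census(tt: TraitTable, forest: LineageForest) -> FamilyCensus:
    """Count eligible families (>=1 pair of complete cousins) and usable cells."""
    complete = {r.cell_id for r in tt.rows if r.complete}
    excluded: dict[str, int] = {}
    for r in tt.rows:
        if not r.complete:
            excluded[r.exclusion_reason] = excluded.get(r.exclusion_reason, 0) + 1

    n_eligible = 0
    n_cousin_cells = 0
    n_usable = 0
    for root in forest.families:
        family_cells = [n.cell_id for n in root.walk()]
        eligible = False
        for grandma in root.walk():
            if len(grandma.children) != 2:
                continue
            branch_a = [c.cell_id for c in grandma.children[0].children if c.cell_id in complete]
            branch_b = [c.cell_id for c in grandma.children[1].children if c.cell_id in complete]
            if branch_a and branch_b:
                eligible = True
                n_cousin_cells += len(branch_a) + len(branch_b)
        if eligible:
            n_eligible += 1
            n_usable += sum(1 for cid in family_cells if cid in complete)

    n_tracked = len(tt.rows)
    return FamilyCensus(
        n_cells_tracked=n_tracked,
        n_complete_cells=len(complete),
        n_families=len(forest.families),
        n_eligible_families=n_eligible,
        n_cousin_eligible_cells=n_cousin_cells,
        n_usable_cells=n_usable,
        usable_fraction=n_usable / n_tracked if n_tracked else 0.0,
        excluded_by_reason=excluded,
    )
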