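"""Tracking-data IO and lineage-forest construction.

Two on-disk dialects are supported:

* **Tracking CSV** — a tracks table ``(cell_id, frame, x, y)`` plus a lineage
  sidecar ``(cell_id, mother_id, fate, well_id, field_id)``.  An empty
  ``mother_id`` marks an originally plated founder.
* **MTrackJ ``.mdf``** — the text format written by the MTrackJ plugin for
  ImageJ (header line, then Assembly/Cluster/Track/Point records).  MDF
  carries positions only, so lineage always comes from the same CSV sidecar.

Coordinates follow the image convention (origin top-left, y down) and stay in
pixels here; conversion to microns happens in :mod:`clonalherit.traits` via
the ``scale`` attribute.  Frames are 0-based and frame ``k`` occurs at time
``k * frame_interval`` minutes.  MTrackJ numbers timepoints from 1, so the
reader/writer shift by one on the ``t`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, PedigreeError, ValidationError

#: Allowed cell-fate tokens.
FATES = ("divided", "off_screen", "died", "censored_at_end")

#: Default sampling design: one frame every 20 min for 72 h -> 217 frames.
DEFAULT_FRAME_INTERVAL_MIN = 20.0
DEFAULT_N_FRAMES = 217

TRACK_COLUMNS = ["cell_id", "frame", "x", "y"]
LINEAGE_COLUMNS = ["cell_id", "mother_id", "fate", "well_id", "field_id"]


@dataclass(frozen=True)
class TrackPoint:
    """One recorded position: 0-based frame index and pixel coordinates."""

    frame: int
    x: float
    y: float


@dataclass
class CellTrack:
    """A single cell's observed path plus its declared pedigree link and fate."""

    cell_id: str
    points: list[TrackPoint]
    mother_id: Optional[str] = None
    fate: str = "censored_at_end"
    well_id: str = "W1"
    field_id: str = "P1"

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError(f"cell {self.cell_id!r}: empty track")
        if self.fate not in FATES:
            raise ValidationError(
                f"cell {self.cell_id!r}: unknown fate {self.fate!r}; "
                f"allowed tokens: {', '.join(FATES)}"
            )
        frames = [p.frame for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError(
                f"cell {self.cell_id!r}: frame indices must be strictly increasing"
            )
        for p in self.points:
            if not (np.isfinite(p.x) and np.isfinite(p.y)):
                raise ValidationError(f"cell {self.cell_id!r}: non-finite coordinate")

    @property
    def first_frame(self) -> int:
        return self.points[0].frame

    @property
    def last_frame(self) -> int:
        return self.points[-1].frame

    def xy(self) -> np.ndarray:
        """Positions as an (n, 2) float array, in pixels."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)


@dataclass
class TrackSet:
    """All tracks of one recording plus the acquisition metadata.

    Parameters
    ----------
    cells : dict
        ``cell_id -> CellTrack``.
    frame_interval : float
        Minutes between consecutive frames.
    scale : float
        Microns per pixel.
    n_frames : int
        Total frames in the recording (frame indices run 0..n_frames-1).
    """

    cells: dict[str, CellTrack]
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN
    scale: float = 1.0
    n_frames: int = DEFAULT_N_FRAMES

    def __post_init__(self) -> None:
        self.validate_links()

    def validate_links(self) -> None:
        """Check that every mother reference resolves and the link graph is acyclic."""
        for cid, cell in self.cells.items():
            if cell.mother_id is not None and cell.mother_id not in self.cells:
                raise IntegrityError(
                    f"cell {cid!r} references unknown mother {cell.mother_id!r}"
                )
        # Cycle check by walking to the root from every cell.
        for cid in self.cells:
            seen = set()
            cur: Optional[str] = cid
            while cur is not None:
                if cur in seen:
                    raise IntegrityError(f"cyclic lineage links involving cell {cur!r}")
                seen.add(cur)
                cur = self.cells[cur].mother_id

    def daughters_of(self, cell_id: str) -> list[str]:
        return sorted(c.cell_id for c in self.cells.values() if c.mother_id == cell_id)


@dataclass
class LineageNode:
    """Node of a family tree: a cell, its generation (founder = 0), its children."""

    cell_id: str
    generation: int
    children: list["LineageNode"] = field(default_factory=list)

    def walk(self) -> Iterator["LineageNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class LineageForest:
    """Families of binary-division pedigrees, each rooted at a plated founder."""

    families: list[LineageNode]

    def iter_cells(self) -> Iterator[tuple[str, LineageNode]]:
        """Yield ``(family_id, node)`` for every cell; family_id is the founder id."""
        for root in self.families:
            for node in root.walk():
                yield root.cell_id, node

    def family_ids(self) -> list[str]:
        return [root.cell_id for root in self.families]


# ---------------------------------------------------------------------------
# CSV dialect


def _read_lineage_table(lineage_path) -> pd.DataFrame:
    lineage = pd.read_csv(lineage_path, dtype=str, keep_default_na=False)
    missing = [c for c in LINEAGE_COLUMNS if c not in lineage.columns]
    if missing:
        raise FormatError(f"lineage file missing columns: {missing}")
    bad = sorted(set(lineage["fate"]) - set(FATES))
    if bad:
        raise ValidationError(
            f"unknown fate token(s) {bad}; allowed tokens: {', '.join(FATES)}"
        )
    if lineage["cell_id"].duplicated().any():
        dup = lineage.loc[lineage["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise IntegrityError(f"duplicate cell_id {dup!r} in lineage file")
    return lineage


def _assemble_trackset(
    points_by_cell: dict[str, list[TrackPoint]],
    lineage: pd.DataFrame,
    frame_interval_min: float,
    microns_per_pixel: float,
    n_frames: int,
) -> TrackSet:
    cells: dict[str, CellTrack] = {}
    lineage_ids = set(lineage["cell_id"])
    for cid in lineage_ids:
        if cid not in points_by_cell:
            raise IntegrityError(f"cell {cid!r} present in lineage but has no track")
    for cid in points_by_cell:
        if cid not in lineage_ids:
            raise IntegrityError(f"track {cid!r} has no lineage record")
    for row in lineage.itertuples(index=False):
        pts = sorted(points_by_cell[row.cell_id], key=lambda p: p.frame)
        fate = row.fate
        # Non-divided cells still present at the final frame are censored by
        # the end of the recording, whatever the sidecar says.
        if fate != "divided" and pts[-1].frame == n_frames - 1:
            fate = "censored_at_end"
        cells[row.cell_id] = CellTrack(
            cell_id=row.cell_id,
            points=pts,
            mother_id=row.mother_id or None,
            fate=fate,
            well_id=row.well_id,
            field_id=row.field_id,
        )
    return TrackSet(
        cells=cells,
        frame_interval=frame_interval_min,
        scale=microns_per_pixel,
        n_frames=n_frames,
    )


def read_track_csv(
    tracks_path,
    lineage_path,
    *,
    microns_per_pixel: float,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    n_frames: int = DEFAULT_N_FRAMES,
) -> TrackSet:
    """Read the tracking-CSV dialect (tracks table + lineage sidecar)."""
    tracks = pd.read_csv(tracks_path, dtype={"cell_id": str},
                         float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise FormatError(f"tracks file missing columns: {missing}")
    lineage = _read_lineage_table(lineage_path)
    points_by_cell: dict[str, list[TrackPoint]] = {}
    for row in tracks.itertuples(index=False):
        points_by_cell.setdefault(str(row.cell_id), []).append(
            TrackPoint(frame=int(row.frame), x=float(row.x), y=float(row.y))
        )
    return _assemble_trackset(
        points_by_cell, lineage, frame_interval_min, microns_per_pixel, n_frames
    )


def write_track_csv(ts: TrackSet, tracks_path, lineage_path) -> None:
    """Write a TrackSet in the tracking-CSV dialect (deterministic row order)."""
    track_rows = []
    lineage_rows = []
    for cid in sorted(ts.cells):
        cell = ts.cells[cid]
        for p in cell.points:
            track_rows.append((cid, p.frame, repr(p.x), repr(p.y)))
        lineage_rows.append(
            (cid, cell.mother_id or "", cell.fate, cell.well_id, cell.field_id)
        )
    pd.DataFrame(track_rows, columns=TRACK_COLUMNS).to_csv(tracks_path, index=False)
    pd.DataFrame(lineage_rows, columns=LINEAGE_COLUMNS).to_csv(lineage_path, index=False)


# ---------------------------------------------------------------------------
# MTrackJ .mdf dialect

_MDF_HEADER_PREFIX = "MTrackJ"
_MDF_FOOTER = "End of MTrackJ Data File"


def read_mdf(
    path,
    lineage_path,
    *,
    microns_per_pixel: float,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
    n_frames: int = DEFAULT_N_FRAMES,
) -> TrackSet:
    """Read an MTrackJ data file plus the lineage CSV sidecar.

    Track ids become cell ids (as decimal strings).  The ``z`` coordinate of
    point records is read and discarded; ``t`` is MTrackJ's 1-based timepoint
    and is converted to the 0-based frame index.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(_MDF_HEADER_PREFIX):
        got = lines[0] if lines else "<empty file>"
        raise FormatError(f"not an MTrackJ data file; first line: {got!r}")
    points_by_cell: dict[str, list[TrackPoint]] = {}
    current: Optional[str] = None
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line == _MDF_FOOTER:
            continue
        tokens = line.split()
        kind = tokens[0]
        if kind in ("Assembly", "Cluster"):
            continue
        if kind == "Track":
            current = tokens[1]
            if current in points_by_cell:
                raise IntegrityError(f"duplicate track id {current!r} (line {lineno})")
            points_by_cell[current] = []
        elif kind == "Point":
            if current is None:
                raise FormatError(
                    f"line {lineno}: Point record before any Track record: {line!r}"
                )
            try:
                _pid, x, y, _z, t = tokens[1], tokens[2], tokens[3], tokens[4], tokens[5]
                frame = int(round(float(t))) - 1
                points_by_cell[current].append(
                    TrackPoint(frame=frame, x=float(x), y=float(y))
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"line {lineno}: bad Point record: {line!r}") from exc
        else:
            raise FormatError(f"line {lineno}: unrecognised record {kind!r}")
    lineage = _read_lineage_table(lineage_path)
    return _assemble_trackset(
        points_by_cell, lineage, frame_interval_min, microns_per_pixel, n_frames
    )


def write_mdf(ts: TrackSet, path, lineage_path=None) -> None:
    """Write tracks as an MTrackJ data file (one Assembly/Cluster, one Track per cell).

    Cell ids must be decimal integers for the MDF dialect; the optional
    lineage sidecar is written in the lineage-CSV dialect.
    """
    out = ["MTrackJ 1.5.1 Data File", "Assembly 1", "Cluster 1"]
    for cid in sorted(ts.cells, key=lambda c: int(c)):
        out.append(f"Track {int(cid)}")
        for i, p in enumerate(ts.cells[cid].points, start=1):
            out.append(f"Point {i} {p.x:.4f} {p.y:.4f} 1.0 {p.frame + 1}.0 1")
    out.append(_MDF_FOOTER)
    Path(path).write_text("\n".join(out) + "\n")
    if lineage_path is not None:
        rows = [
            (cid, c.mother_id or "", c.fate, c.well_id, c.field_id)
            for cid, c in sorted(ts.cells.items(), key=lambda kv: int(kv[0]))
        ]
        pd.DataFrame(rows, columns=LINEAGE_COLUMNS).to_csv(lineage_path, index=False)


# ---------------------------------------------------------------------------
# Forest construction


def build_forest(ts: TrackSet) -> LineageForest:
    """Partition cells into families rooted at founders, assigning generations.

    Rejects mothers with more than two declared daughters (divisions are
    binary); a mother with a single tracked daughter is kept — the other
    daughter simply was not tracked.
    """
    ts.validate_links()
    children: dict[str, list[str]] = {cid: [] for cid in ts.cells}
    for cid, cell in ts.cells.items():
        if cell.mother_id is not None:
            children[cell.mother_id].append(cid)
    for mid, kids in children.items():
        if len(kids) > 2:
            raise PedigreeError(
                f"mother {mid!r} has {len(kids)} declared daughters; divisions are binary"
            )

    def grow(cid: str, generation: int) -> LineageNode:
        return LineageNode(
            cell_id=cid,
            generation=generation,
            children=[grow(k, generation + 1) for k in sorted(children[cid])],
        )

    founders = sorted(cid for cid, c in ts.cells.items() if c.mother_id is None)
    return LineageForest(families=[grow(f, 0) for f in founders])


def forest_from_lineage_csv(lineage_path) -> LineageForest:
    """Build a forest from a lineage sidecar alone (no positions needed)."""
    lineage = _read_lineage_table(lineage_path)
    ids = set(lineage["cell_id"])
    children: dict[str, list[str]] = {cid: [] for cid in ids}
    mothers: dict[str, Optional[str]] = {}
    for row in lineage.itertuples(index=False):
        mid = row.mother_id or None
        mothers[row.cell_id] = mid
        if mid is not None:
            if mid not in ids:
                raise IntegrityError(
                    f"cell {row.cell_id!r} references unknown mother {mid!r}"
                )
            children[mid].append(row.cell_id)
    for cid in ids:
        seen = set()
        cur: Optional[str] = cid
        while cur is not None:
            if cur in seen:
                raise IntegrityError(f"cyclic lineage links involving cell {cur!r}")
            seen.add(cur)
            cur = mothers[cur]
    for mid, kids in children.items():
        if len(kids) > 2:
            raise PedigreeError(
                f"mother {mid!r} has {len(kids)} declared daughters; divisions are binary"
            )

    def grow(cid: str, generation: int) -> LineageNode:
        return LineageNode(
            cell_id=cid,
            generation=generation,
            children=[grow(k, generation + 1) for k in sorted(children[cid])],
        )

    founders = sorted(cid for cid in ids if mothers[cid] is None)
    return LineageForest(families=[grow(f, 0) for f in founders])
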