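"""Shared fixtures: hand-built tracksets with known pedigrees and fates."""

from __future__ import annotations

import pytest

from clonalherit.io import CellTrack, TrackPoint, TrackSet


def make_cell(cid, first, last, mother=None, fate="divided",
              well="W1", field="P1", step=(1.0, 0.0), start=(0.0, 0.0)):
    """A cell moving in a straight line, one point per frame."""
    pts = [
        TrackPoint(frame=f, x=start[0] + (f - first) * step[0],
                   y=start[1] + (f - first) * step[1])
        for f in range(first, last + 1)
    ]
    return CellTrack(cell_id=cid, points=pts, mother_id=mother, fate=fate,
                     well_id=well, field_id=field)


@pytest.fixture
def three_family_ts():
    """Three families exercising every fate, with hand-enumerated expectations.

    Family A: complete 3-generation core with one off-screen and one dead
    granddaughter; family B: one censored daughter, one complete branch;
    family C: a founder that never divided.
    """
    cells = [
        # family A
        make_cell("a0", 0, 30, fate="divided"),
        make_cell("a1", 30, 60, mother="a0", fate="divided"),
        make_cell("a2", 30, 66, mother="a0", fate="divided", step=(0.0, 1.0)),
        make_cell("a11", 60, 100, mother="a1", fate="divided"),
        make_cell("a12", 60, 80, mother="a1", fate="off_screen"),
        make_cell("a21", 66, 110, mother="a2", fate="divided"),
        make_cell("a22", 66, 85, mother="a2", fate="died"),
        # family B
        make_cell("b0", 0, 40, fate="divided", well="W2"),
        make_cell("b1", 40, 216, mother="b0", fate="censored_at_end", well="W2"),
        make_cell("b2", 40, 90, mother="b0", fate="divided", well="W2"),
        make_cell("b21", 90, 150, mother="b2", fate="divided", well="W2"),
        make_cell("b22", 90, 216, mother="b2", fate="censored_at_end", well="W2"),
        # family C
        make_cell("c0", 0, 216, fate="censored_at_end", well="W3"),
    ]
    ts = TrackSet(cells={c.cell_id: c for c in cells},
                  frame_interval=20.0, scale=1.0, n_frames=217)
    expected = {
        "n_cells": 13,
        "complete": {"a1", "a2", "a11", "a21", "b2", "b21"},
        "by_reason": {"founder": 3, "off_screen": 1, "died": 1, "censored_at_end": 2},
        "n_families": 3,
        "n_eligible_families": 1,  # only A has complete cousins in both branches
        "n_cousin_eligible_cells": 2,  # a11 and a21
        "n_usable_cells": 4,  # complete members of family A
    }
    return ts, expected


@pytest.fixture
def straight_line_ts():
    """Mother 0→10, daughter 10→82 moving 3 px per 20-min frame: speed 9 µm/h."""
    mother = make_cell("m", 0, 10, fate="divided")
    daughter = make_cell("d", 10, 82, mother="m", fate="divided", step=(3.0, 0.0))
    return TrackSet(cells={"m": mother, "d": daughter},
                    frame_interval=20.0, scale=1.0, n_frames=217)
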