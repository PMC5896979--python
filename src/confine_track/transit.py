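"""Constriction-transit detection.

For every track and every constriction row a three-state machine classifies
each frame from the nucleus bounding box:

* ``attempting`` — the leading bbox edge has crossed the row's entry
  boundary while the trailing edge has not yet cleared the exit boundary,
* ``passed`` — the trailing edge has fully cleared the exit boundary,
* ``outside`` — the nucleus is still on the entry side.

An attempt that reaches ``passed`` is a success; one that falls back to
``outside`` is a failure; attempts lasting exactly one frame are discarded
as grazes (a nucleus sliding along the pillar row can momentarily poke over
the boundary without attempting to pass). With the default migration
direction ``"up"``, cells move toward decreasing y: the entry boundary is
the row's lower boundary and the exit boundary its upper one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .registration import ConstrictionRow, DeviceGeometry
from .segmentation import NucleusObservation
from .tracking import Track

State = Literal["outside_below", "attempting", "passed_above"]
MigrationDirection = Literal["up", "down"]


@dataclass(frozen=True)
class TransitEvent:
    """One interaction of one track with one constriction row."""

    track_id: int
    row_index: int
    entry_frame: int
    exit_frame: int
    outcome: Literal["success", "failure", "ongoing"]
    transit_time_min: float
    #: True when this event starts on the frame right after another event of
    #: the same track/row ended (back-and-forth struggles; a manual analyst
    #: might merge the two).
    adjacent_to_previous: bool = False

    def __post_init__(self):
        if self.entry_frame > self.exit_frame:
            raise ValueError("entry_frame must not exceed exit_frame")


def constriction_state(
    obs: NucleusObservation,
    row: ConstrictionRow,
    migration_direction: MigrationDirection = "up",
) -> State:
    """Classify one observation against one row's boundary band."""
    _, y0, _, y1 = obs.bbox  # min_y, max_y (half-open)
    if migration_direction == "up":
        leading, trailing = y0, y1
        if trailing <= row.upper_boundary_y:
            return "passed_above"
        if leading < row.lower_boundary_y and trailing > row.upper_boundary_y:
            return "attempting"
        return "outside_below"
    # mirrored: migration toward increasing y
    leading, trailing = y1, y0
    if trailing >= row.lower_boundary_y:
        return "passed_above"
    if leading > row.upper_boundary_y and trailing < row.lower_boundary_y:
        return "attempting"
    return "outside_below"


def detect_transits(
    track: Track,
    geometry: DeviceGeometry,
    frame_interval_min: float,
    migration_direction: MigrationDirection = "up",
) -> list[TransitEvent]:
    """Run the transit state machine for one track against every row.

    Entry is the first attempting frame; a success ends at the first frame
    fully past the exit boundary (transit time = (exit - entry) x frame
    interval); a failure ends at the last attempting frame before the
    nucleus falls back outside. Single-frame attempts are discarded. A track
    ending mid-attempt yields an ``ongoing`` event, excluded from
    transit-time statistics downstream.
    """
    events: list[TransitEvent] = []
    for row_index, row in enumerate(geometry.rows):
        events.extend(
            _detect_row(track, row, row_index, frame_interval_min, migration_direction)
        )
    events.sort(key=lambda e: (e.entry_frame, e.row_index))
    return events


def _detect_row(
    track: Track,
    row: ConstrictionRow,
    row_index: int,
    frame_interval_min: float,
    migration_direction: MigrationDirection,
) -> list[TransitEvent]:
    frames = track.frames
    events: list[TransitEvent] = []
    entry: int | None = None
    attempt_frames: list[int] = []
    last_event_end: int | None = None

    def close(outcome: str, exit_frame: int) -> None:
        nonlocal entry, attempt_frames, last_event_end
        if entry is not None and len(attempt_frames) > 1:
            # a failure needs one outside frame before re-entry, so "immediately
            # re-entered" means at most one frame between end and next entry
            adjacent = last_event_end is not None and entry - last_event_end <= 2
            events.append(
                TransitEvent(
                    track_id=track.track_id,
                    row_index=row_index,
                    entry_frame=entry,
                    exit_frame=exit_frame,
                    outcome=outcome,  # type: ignore[arg-type]
                    transit_time_min=(exit_frame - entry) * frame_interval_min,
                    adjacent_to_previous=adjacent,
                )
            )
            last_event_end = exit_frame
        entry = None
        attempt_frames = []

    for f in frames:
        state = constriction_state(track.observations[f], row, migration_direction)
        if state == "attempting":
            if entry is None:
                entry = f
            attempt_frames.append(f)
        elif state == "passed_above":
            if entry is not None:
                close("success", f)
        else:  # outside_below
            if entry is not None:
                close("failure", attempt_frames[-1])
    if entry is not None and len(attempt_frames) > 1:
        close("ongoing", attempt_frames[-1])
    return events


def transits_to_frame(events: list[TransitEvent]) -> pd.DataFrame:
    columns = [
        "track_id",
        "row",
        "entry_frame",
        "exit_frame",
        "outcome",
        "transit_time_min",
        "adjacent_to_previous",
    ]
    rows = [
        {
            "track_id": e.track_id,
            "row": e.row_index,
            "entry_frame": e.entry_frame,
            "exit_frame": e.exit_frame,
            "outcome": e.outcome,
            "transit_time_min": e.transit_time_min,
            "adjacent_to_previous": e.adjacent_to_previous,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=columns)
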