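"""Frame-to-frame nucleus linking and track assembly.

Every candidate pairing of a nucleus in one frame with a nucleus in the next
is scored with the error function

    E = distance^2 + 2 * |delta mean chromatin-marker intensity| + 2 * |delta area|

(distance in px, intensity in raw counts, area in px^2 — the units are mixed
by design; the weights are configurable). Pairs are accepted greedily in
ascending E, each accepted object becoming unavailable for further pairings,
and only pairs whose centroids lie within a physical gate (40 µm by default,
the distance a cell can plausibly travel in one frame interval) are
considered at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import NucleusObservation

DEFAULT_MAX_DISTANCE_UM = 40.0
DEFAULT_INTENSITY_WEIGHT = 2.0
DEFAULT_AREA_WEIGHT = 2.0


@dataclass(frozen=True)
class PairingCost:
    """The linking error E and its components, kept for auditability."""

    value: float
    distance_sq: float
    delta_intensity: float
    delta_area: float


@dataclass
class Track:
    """Time-ordered observations of one nucleus."""

    track_id: int
    observations: dict[int, NucleusObservation] = field(default_factory=dict)
    parent_id: int | None = None
    daughter_ids: list[int] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return min(self.observations)

    @property
    def end_frame(self) -> int:
        return max(self.observations)

    @property
    def frames(self) -> list[int]:
        return sorted(self.observations)

    def add(self, obs: NucleusObservation) -> None:
        if obs.frame_index in self.observations:
            raise ValueError(f"track {self.track_id} already has frame {obs.frame_index}")
        self.observations[obs.frame_index] = obs

    def __len__(self) -> int:
        return len(self.observations)


def pairing_cost(
    a: NucleusObservation,
    b: NucleusObservation,
    intensity_weight: float = DEFAULT_INTENSITY_WEIGHT,
    area_weight: float = DEFAULT_AREA_WEIGHT,
) -> PairingCost:
    """Linking error between two observations from consecutive frames."""
    d2 = (a.centroid_x - b.centroid_x) ** 2 + (a.centroid_y - b.centroid_y) ** 2
    di = abs(a.mean_nuclear_marker - b.mean_nuclear_marker)
    da = abs(a.area - b.area)
    return PairingCost(
        value=d2 + intensity_weight * di + area_weight * da,
        distance_sq=d2,
        delta_intensity=di,
        delta_area=da,
    )


def link_frames(
    prev: list[NucleusObservation],
    curr: list[NucleusObservation],
    max_distance_um: float = DEFAULT_MAX_DISTANCE_UM,
    pixel_size_um: float = 1.0,
    intensity_weight: float = DEFAULT_INTENSITY_WEIGHT,
    area_weight: float = DEFAULT_AREA_WEIGHT,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy mutual-best pairing between two consecutive frames.

    Candidate pairs are restricted to centroid distance at most
    ``max_distance_um / pixel_size_um`` pixels. Pairs are accepted in
    ascending error E (ties broken by (prev_index, curr_index)); each
    accepted object is removed from further consideration, until no
    admissible pair remains.

    Returns
    -------
    pairs, unmatched_prev, unmatched_curr
        Index pairs into (prev, curr), plus the indices left unmatched
        (ended tracks and new-track candidates respectively).
    """
    gate_px = max_distance_um / pixel_size_um
    gate_sq = gate_px**2
    candidates = []
    for i, a in enumerate(prev):
        for j, b in enumerate(curr):
            cost = pairing_cost(a, b, intensity_weight, area_weight)
            if cost.distance_sq <= gate_sq:
                candidates.append((cost.value, i, j))
    candidates.sort()
    used_prev: set[int] = set()
    used_curr: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_prev or j in used_curr:
            continue
        pairs.append((i, j))
        used_prev.add(i)
        used_curr.add(j)
    unmatched_prev = [i for i in range(len(prev)) if i not in used_prev]
    unmatched_curr = [j for j in range(len(curr)) if j not in used_curr]
    return pairs, unmatched_prev, unmatched_curr


def build_tracks(
    per_frame_observations: list[list[NucleusObservation]],
    max_distance_um: float = DEFAULT_MAX_DISTANCE_UM,
    pixel_size_um: float = 1.0,
    intensity_weight: float = DEFAULT_INTENSITY_WEIGHT,
    area_weight: float = DEFAULT_AREA_WEIGHT,
) -> list[Track]:
    """Assemble tracks by chaining greedy frame-to-frame links.

    Linking is strictly consecutive (no gap closing): a nucleus unmatched in
    frame t ends its track, and every unmatched observation starts a new one.
    Track ids are assigned in order of creation and are stable for a given
    input.
    """
    tracks: list[Track] = []
    active: dict[int, Track] = {}  # index within current frame -> track
    next_id = 0
    prev_obs: list[NucleusObservation] = []
    for t, curr_obs in enumerate(per_frame_observations):
        if t == 0:
            new_active: dict[int, Track] = {}
            for j, obs in enumerate(curr_obs):
                tr = Track(track_id=next_id)
                next_id += 1
                tr.add(obs)
                tracks.append(tr)
                new_active[j] = tr
            active = new_active
            prev_obs = curr_obs
            continue
        pairs, _, unmatched_curr = link_frames(
            prev_obs,
            curr_obs,
            max_distance_um=max_distance_um,
            pixel_size_um=pixel_size_um,
            intensity_weight=intensity_weight,
            area_weight=area_weight,
        )
        new_active = {}
        for i, j in pairs:
            if i in active:
                active[i].add(curr_obs[j])
                new_active[j] = active[i]
        for j in unmatched_curr:
            tr = Track(track_id=next_id)
            next_id += 1
            tr.add(curr_obs[j])
            tracks.append(tr)
            new_active[j] = tr
        active = new_active
        prev_obs = curr_obs
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into a tidy table (one row per track per frame)."""
    rows = []
    for tr in sorted(tracks, key=lambda t: t.track_id):
        for f in tr.frames:
            o = tr.observations[f]
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": f,
                    "x": o.centroid_x,
                    "y": o.centroid_y,
                    "area": o.area,
                    "mean_nuclear_marker": o.mean_nuclear_marker,
                    "mean_reporter": o.mean_reporter,
                    "in_constriction": o.in_constriction,
                }
            )
    columns = [
        "track_id",
        "frame",
        "x",
        "y",
        "area",
        "mean_nuclear_marker",
        "mean_reporter",
        "in_constriction",
    ]
    return pd.DataFrame(rows, columns=columns)
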