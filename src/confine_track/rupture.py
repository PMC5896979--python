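"""Nuclear envelope rupture detection and mitosis reclassification.

Rupture is read off the per-track ratio r_t of mean chromatin-marker
intensity to mean nucleoplasmic-reporter intensity. The reporter leaks into
the cytoplasm on rupture, so r jumps up, then relaxes back as the envelope
is repaired and the reporter is re-imported. Because both channels bleach
together, the ratio is insensitive to photobleaching.

A rupture starts when the frame-to-frame ratio change exceeds a fraction
(default 20%) of the previous frame's ratio, or when the ratio rises over at
least ``rise_len`` (default 5) consecutive time points. It ends when the
ratio has returned close to its pre-rupture baseline and the ratio change
has settled back to zero. Mitosis also disperses the reporter; a candidate
rupture is reclassified as a division whenever a new track appears in the
nucleus' vicinity in the following frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Track

DEFAULT_JUMP_FRAC = 0.20
DEFAULT_RISE_LEN = 5
DEFAULT_MIN_RISE_FRAC = 0.01
DEFAULT_BASELINE_TOL_FRAC = 0.10
DEFAULT_DELTA_ZERO_TOL = 0.05
DEFAULT_VICINITY_UM = 40.0
DEFAULT_MITOSIS_WINDOW = 1


@dataclass
class RatioSeries:
    """Per-frame marker/reporter ratio of one track."""

    track_id: int
    frames: list[int]
    ratio: np.ndarray  # r_t, aligned with frames
    delta: np.ndarray  # r_t - r_{t-1}; first element 0

    def __post_init__(self):
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RuptureEvent:
    track_id: int
    start_frame: int
    end_frame: int | None
    duration_min: float | None
    baseline_ratio: float
    trigger: str  # "jump" or "sustained_rise"


@dataclass
class MitosisEvent:
    parent_track_id: int
    daughter_track_ids: list[int]
    division_frame: int


def compute_ratio_series(track: Track) -> RatioSeries:
    """r_t = mean chromatin marker / mean reporter, per observed frame.

    Frames where the reporter mean is zero have no defined ratio and are
    skipped with a warning.
    """
    frames, ratios = [], []
    for f in track.frames:
        obs = track.observations[f]
        if obs.mean_reporter <= 0:
            warnings.warn(
                f"track {track.track_id} frame {f}: zero reporter mean, ratio skipped",
                stacklevel=2,
            )
            continue
        frames.append(f)
        ratios.append(obs.mean_nuclear_marker / obs.mean_reporter)
    ratio = np.asarray(ratios, dtype=float)
    delta = np.zeros_like(ratio)
    if len(ratio) > 1:
        delta[1:] = np.diff(ratio)
    return RatioSeries(track_id=track.track_id, frames=frames, ratio=ratio, delta=delta)


def detect_rupture_start(
    series: RatioSeries,
    jump_frac: float = DEFAULT_JUMP_FRAC,
    rise_len: int = DEFAULT_RISE_LEN,
    min_rise_frac: float = DEFAULT_MIN_RISE_FRAC,
) -> list[tuple[int, str]]:
    """Candidate rupture starts: (frame, trigger) pairs, earliest first.

    Two triggers fire:

    * ``jump`` at frame t when r_t - r_{t-1} > jump_frac * r_{t-1};
    * ``sustained_rise`` when r rises over ``rise_len`` consecutive time
      points, each step by more than ``min_rise_frac`` of the running value
      (the noise floor that keeps chance monotone runs in a flat trace from
      triggering); the start is the first frame of the run.

    A sustained-rise run containing a jump is reported once, at the earlier
    frame with the jump trigger taking precedence. Merging of starts that
    fall inside an already open event happens in :func:`detect_ruptures`.
    """
    n = len(series)
    starts: list[tuple[int, str]] = []
    run = 0  # number of consecutive qualifying rises ending at i
    for i in range(1, n):
        prev = series.ratio[i - 1]
        if series.delta[i] > jump_frac * prev:
            starts.append((series.frames[i], "jump"))
        if series.delta[i] > min_rise_frac * prev:
            run += 1
        else:
            run = 0
        # run+1 time points are rising; trigger once, when the run reaches length
        if run + 1 == rise_len:
            starts.append((series.frames[i - run], "sustained_rise"))
    starts.sort(key=lambda s: (s[0], s[1] != "jump"))
    merged: list[tuple[int, str]] = []
    for f, trig in starts:
        if not merged or f > merged[-1][0]:
            merged.append((f, trig))
    return merged


def detect_rupture_end(
    series: RatioSeries,
    start_frame: int,
    baseline_tol_frac: float = DEFAULT_BASELINE_TOL_FRAC,
    delta_zero_tol: float = DEFAULT_DELTA_ZERO_TOL,
) -> int | None:
    """First frame after the peak at which the ratio has recovered.

    Recovery means r_t <= (1 + baseline_tol_frac) * baseline and
    |r_t - r_{t-1}| <= delta_zero_tol * baseline, where the baseline is the
    ratio at the last pre-rupture frame. Returns None when the trace never
    recovers (the event stays open).
    """
    baseline = baseline_ratio(series, start_frame)
    idx_start = series.frames.index(start_frame)
    peak_val = series.ratio[idx_start]
    for i in range(idx_start + 1, len(series)):
        if series.ratio[i] >= peak_val:
            peak_val = series.ratio[i]  # still rising: not past the peak yet
            continue
        if (
            series.ratio[i] <= (1 + baseline_tol_frac) * baseline
            and abs(series.delta[i]) <= delta_zero_tol * baseline
        ):
            return series.frames[i]
    return None


def baseline_ratio(series: RatioSeries, start_frame: int) -> float:
    """Ratio at the last frame before the rupture start (or at the start
    itself when the rupture opens the track)."""
    idx = series.frames.index(start_frame)
    return float(series.ratio[max(idx - 1, 0)])


def detect_ruptures(
    track: Track,
    frame_interval_min: float,
    jump_frac: float = DEFAULT_JUMP_FRAC,
    rise_len: int = DEFAULT_RISE_LEN,
    min_rise_frac: float = DEFAULT_MIN_RISE_FRAC,
    baseline_tol_frac: float = DEFAULT_BASELINE_TOL_FRAC,
    delta_zero_tol: float = DEFAULT_DELTA_ZERO_TOL,
) -> list[RuptureEvent]:
    """Full rupture detection for one track: starts, ends, durations.

    Starts that fall inside an open event (before its detected end) are
    merged into it; a track has at most one open rupture at a time.
    """
    if len(track) < 2:
        return []
    series = compute_ratio_series(track)
    if len(series) < 2:
        return []
    events: list[RuptureEvent] = []
    open_until = -np.inf
    for frame, trigger in detect_rupture_start(series, jump_frac, rise_len, min_rise_frac):
        if frame <= open_until:
            continue
        end = detect_rupture_end(series, frame, baseline_tol_frac, delta_zero_tol)
        events.append(
            RuptureEvent(
                track_id=track.track_id,
                start_frame=frame,
                end_frame=end,
                duration_min=None if end is None else (end - frame) * frame_interval_min,
                baseline_ratio=baseline_ratio(series, frame),
                trigger=trigger,
            )
        )
        open_until = np.inf if end is None else end
    return events


def reclassify_mitosis(
    tracks: list[Track],
    candidate_ruptures: list[RuptureEvent],
    vicinity_um: float = DEFAULT_VICINITY_UM,
    pixel_size_um: float = 1.0,
    mitosis_window: int = DEFAULT_MITOSIS_WINDOW,
) -> tuple[list[RuptureEvent], list[MitosisEvent]]:
    """Separate true ruptures from divisions.

    Mitosis begins like a rupture (the reporter disperses on envelope
    breakdown) but produces a second nucleus: when a new track starts within
    ``mitosis_window`` frames of a candidate rupture start and within
    ``vicinity_um`` of the candidate's nucleus, the candidate becomes a
    :class:`MitosisEvent` linking parent and daughter(s), and parent/daughter
    links are recorded on the tracks.
    """
    by_id = {t.track_id: t for t in tracks}
    vicinity_px = vicinity_um / pixel_size_um
    ruptures: list[RuptureEvent] = []
    mitoses: list[MitosisEvent] = []
    for cand in candidate_ruptures:
        parent = by_id[cand.track_id]
        daughters = []
        for other in tracks:
            if other.track_id == cand.track_id:
                continue
            s = other.start_frame
            if not cand.start_frame <= s <= cand.start_frame + mitosis_window:
                continue
            ref_frame = max(f for f in parent.frames if f <= s) if any(
                f <= s for f in parent.frames
            ) else parent.start_frame
            p = parent.observations[ref_frame]
            d = other.observations[s]
            dist = np.hypot(p.centroid_x - d.centroid_x, p.centroid_y - d.centroid_y)
            if dist <= vicinity_px:
                daughters.append(other.track_id)
        if daughters:
            division_frame = min(by_id[d].start_frame for d in daughters) - 1
            mitoses.append(
                MitosisEvent(
                    parent_track_id=cand.track_id,
                    daughter_track_ids=sorted(daughters),
                    division_frame=division_frame,
                )
            )
            parent.daughter_ids = sorted(set(parent.daughter_ids) | set(daughters))
            for d in daughters:
                by_id[d].parent_id = cand.track_id
        else:
            ruptures.append(cand)
    return ruptures, mitoses


def normalize_rupture_trace(series: RatioSeries, event: RuptureEvent) -> np.ndarray:
    """Event trace re-expressed relative to its pre-rupture value and scaled
    so the peak equals 1 (the form used to average repair dynamics across
    nuclei). Values lie in [0, 1]."""
    i0 = series.frames.index(event.start_frame)
    i1 = (
        series.frames.index(event.end_frame) + 1
        if event.end_frame is not None
        else len(series)
    )
    rel = series.ratio[max(i0 - 1, 0) : i1] / event.baseline_ratio
    return rel / rel.max()


def ruptures_to_frame(events: list[RuptureEvent]) -> pd.DataFrame:
    columns = ["track_id", "start_frame", "end_frame", "duration_min", "trigger", "baseline_ratio"]
    rows = [
        {
            "track_id": e.track_id,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "duration_min": e.duration_min,
            "trigger": e.trigger,
            "baseline_ratio": e.baseline_ratio,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=columns)


def mitoses_to_frame(events: list[MitosisEvent]) -> pd.DataFrame:
    columns = ["parent_track_id", "daughter_track_ids", "division_frame"]
    rows = [
        {
            "parent_track_id": e.parent_track_id,
            "daughter_track_ids": ";".join(str(d) for d in e.daughter_track_ids),
            "division_frame": e.division_frame,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=columns)
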