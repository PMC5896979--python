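"""Benchmarking helpers: match pipeline output against generator ground truth."""

from __future__ import annotations

import numpy as np

from .rupture import MitosisEvent, RuptureEvent
from .synth import GroundTruth
from .tracking import Track
from .transit import TransitEvent

MATCH_TOL_PX = 5.0


def match_observations(
    gt: GroundTruth, tracks: list[Track], tol_px: float = MATCH_TOL_PX
) -> dict[tuple[int, int], tuple[int, int]]:
    """Greedy nearest-centroid matching of detections to scripted nuclei.

    Returns a map (frame, nucleus_id) -> (track_id, frame) for every ground
    truth observation with a detection within ``tol_px``.
    """
    det_by_frame: dict[int, list[tuple[int, float, float]]] = {}
    for tr in tracks:
        for f, obs in tr.observations.items():
            det_by_frame.setdefault(f, []).append((tr.track_id, obs.centroid_x, obs.centroid_y))
    matches: dict[tuple[int, int], tuple[int, int]] = {}
    for nid, per_frame in gt.tracks.items():
        for f, gobs in per_frame.items():
            cands = det_by_frame.get(f, [])
            if not cands:
                continue
            dists = [np.hypot(x - gobs.x, y - gobs.y) for _, x, y in cands]
            i = int(np.argmin(dists))
            if dists[i] <= tol_px:
                matches[(f, nid)] = (cands[i][0], f)
    return matches


def detection_precision_recall(
    gt: GroundTruth, tracks: list[Track], tol_px: float = MATCH_TOL_PX
) -> tuple[float, float]:
    """Per-observation detection precision and recall over all frames."""
    matches = match_observations(gt, tracks, tol_px)
    n_gt = sum(len(v) for v in gt.tracks.values())
    n_det = sum(len(tr) for tr in tracks)
    tp = len(matches)
    recall = tp / n_gt if n_gt else 1.0
    precision = tp / n_det if n_det else 1.0
    return precision, recall


def link_accuracy(gt: GroundTruth, tracks: list[Track], tol_px: float = MATCH_TOL_PX) -> float:
    """Fraction of scripted consecutive-frame identity links the tracker kept."""
    matches = match_observations(gt, tracks, tol_px)
    total = correct = 0
    for nid, per_frame in gt.tracks.items():
        frames = sorted(per_frame)
        for f0, f1 in zip(frames, frames[1:]):
            if f1 != f0 + 1:
                continue
            total += 1
            m0, m1 = matches.get((f0, nid)), matches.get((f1, nid))
            if m0 is not None and m1 is not None and m0[0] == m1[0]:
                correct += 1
    return correct / total if total else 1.0


def _track_to_nucleus(gt: GroundTruth, tracks: list[Track]) -> dict[int, int]:
    """Majority-vote assignment of each track to a scripted nucleus."""
    matches = match_observations(gt, tracks)
    votes: dict[int, dict[int, int]] = {}
    for (f, nid), (tid, _) in matches.items():
        votes.setdefault(tid, {}).setdefault(nid, 0)
        votes[tid][nid] += 1
    return {tid: max(v, key=v.get) for tid, v in votes.items()}


def transit_metrics(
    gt: GroundTruth,
    tracks: list[Track],
    events: list[TransitEvent],
    frame_tol: int = 1,
) -> dict[str, float]:
    """Event-level precision/recall and worst-case timing error (frames).

    A detected event matches a scripted one when it is on the same nucleus
    and row, has the same outcome, and both entry and exit frames agree
    within ``frame_tol``.
    """
    t2n = _track_to_nucleus(gt, tracks)
    gt_events = list(gt.transits)
    used: set[int] = set()
    tp = 0
    max_err = 0.0
    for ev in events:
        nid = t2n.get(ev.track_id)
        best = None
        for i, g in enumerate(gt_events):
            if i in used or g.nucleus_id != nid or g.row_index != ev.row_index:
                continue
            if g.outcome != ev.outcome:
                continue
            err = max(abs(g.entry_frame - ev.entry_frame), abs(g.exit_frame - ev.exit_frame))
            if err <= frame_tol and (best is None or err < best[1]):
                best = (i, err)
        if best is not None:
            used.add(best[0])
            tp += 1
            max_err = max(max_err, best[1])
    recall = tp / len(gt_events) if gt_events else 1.0
    precision = tp / len(events) if events else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_gt": len(gt_events),
        "n_detected": len(events),
        "max_frame_error": max_err,
    }


def rupture_metrics(
    gt: GroundTruth,
    tracks: list[Track],
    ruptures: list[RuptureEvent],
    mitoses: list[MitosisEvent],
    jump_threshold: float = 0.20,
    frame_tol: int = 1,
) -> dict[str, float]:
    """Rupture recall (detectable events), false positives, division handling.

    Detectable scripted events are jump ruptures above ``jump_threshold``
    plus all sustained rises. A detection matches when on the same nucleus
    with the start within ``frame_tol``; duration errors are reported for
    matched, closed events.
    """
    t2n = _track_to_nucleus(gt, tracks)
    detectable = [
        g
        for g in gt.ruptures
        if g.trigger == "sustained_rise" or g.jump_frac > jump_threshold
    ]
    scripted_nuclei = {g.nucleus_id for g in gt.ruptures}
    matched: set[int] = set()
    false_pos = 0
    max_dur_err = 0.0
    for ev in ruptures:
        nid = t2n.get(ev.track_id)
        hit = None
        for i, g in enumerate(gt.ruptures):
            if g.nucleus_id == nid and abs(g.start_frame - ev.start_frame) <= frame_tol:
                hit = i
                break
        if hit is None:
            false_pos += 1
        else:
            matched.add(hit)
            g = gt.ruptures[hit]
            if g.end_frame is not None and ev.end_frame is not None:
                max_dur_err = max(
                    max_dur_err,
                    abs((g.end_frame - g.start_frame) - (ev.end_frame - ev.start_frame)),
                )
    detectable_matched = sum(
        1
        for i, g in enumerate(gt.ruptures)
        if i in matched and (g.trigger == "sustained_rise" or g.jump_frac > jump_threshold)
    )
    recall = detectable_matched / len(detectable) if detectable else 1.0

    # divisions: every scripted division must surface as a mitosis on the
    # parent nucleus' track, and never as a rupture. The parent track is the
    # detection matched to the parent nucleus at its last scripted frame
    # (majority votes would misattribute it: after division the track
    # continues as one of the daughters).
    matches = match_observations(gt, tracks)
    div_ok = 0
    div_rupture_fp = 0
    for d in gt.divisions:
        last_frame = max(gt.tracks[d.parent_id])
        hit = matches.get((last_frame, d.parent_id))
        parent_tracks = {hit[0]} if hit is not None else set()
        if any(
            m.parent_track_id in parent_tracks
            and abs(m.division_frame - d.division_frame) <= frame_tol
            for m in mitoses
        ):
            div_ok += 1
        if any(ev.track_id in parent_tracks for ev in ruptures):
            div_rupture_fp += 1
    return {
        "recall": recall,
        "n_detectable": len(detectable),
        "false_positives": false_pos,
        "divisions_total": len(gt.divisions),
        "divisions_reclassified": div_ok,
        "division_rupture_false_positives": div_rupture_fp,
        "max_duration_error_frames": max_dur_err,
        "n_scripted_nuclei": len(scripted_nuclei),
    }
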