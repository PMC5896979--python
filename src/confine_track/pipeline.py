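"""End-to-end orchestration: register, stabilize, segment, track, detect events."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .preprocess import DriftTrace, estimate_drift, smooth_fluorescence, stabilize
from .registration import DeviceGeometry, detect_pillars, estimate_rotation, rotate_sequence, build_geometry
from .rupture import MitosisEvent, RuptureEvent, detect_ruptures, reclassify_mitosis
from .segmentation import NucleusObservation, segment_frame
from .sequence import ImageSequence, read_sequence
from .tracking import Track, build_tracks
from .transit import TransitEvent, detect_transits

logger = logging.getLogger(__name__)


@dataclass
class ResultsBundle:
    """Everything one analysis run produces, stage by stage."""

    geometry: DeviceGeometry
    drift: DriftTrace
    sequence: ImageSequence  # rotated + stabilized
    observations: list[list[NucleusObservation]]
    tracks: list[Track]
    transits: list[TransitEvent]
    ruptures: list[RuptureEvent]
    mitoses: list[MitosisEvent]
    stage_log: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    config: AnalysisConfig,
    sequence: ImageSequence | None = None,
) -> ResultsBundle:
    """Run the full analysis in pipeline order.

    Stages: device registration from frame 1 → whole-stack rotation → drift
    estimation and stabilization → per-frame segmentation → frame-to-frame
    tracking → constriction-transit detection → rupture detection → mitosis
    reclassification. The input comes from ``config.input_path`` unless an
    in-memory sequence is given.
    """
    if sequence is None:
        if config.input_path is None:
            raise ValueError("no input: set config.input_path or pass a sequence")
        sequence = read_sequence(
            config.input_path,
            channel_map=config.channel_map,
            pixel_size_um=config.pixel_size_um,
            frame_interval_min=config.frame_interval_min,
        )

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # registration (frame 1 defines the rotation for the whole sequence)
    pillars = _stage("register")(
        lambda: detect_pillars(
            sequence.frame(0, "transmitted"),
            config.hough_radius_range_px,
            config.hough_sensitivity,
        )
    )
    angle = estimate_rotation(pillars)
    rotated = _stage("rotate")(lambda: rotate_sequence(sequence, angle))
    pillars_rot = detect_pillars(
        rotated.frame(0, "transmitted"), config.hough_radius_range_px, config.hough_sensitivity
    )
    geometry = build_geometry(
        pillars_rot,
        boundary_offset_um=config.boundary_offset_um,
        pixel_size_um=sequence.pixel_size_um,
        rotation_deg=angle,
    )
    logger.info("registration: %d pillars, %d rows, rotation %.2f deg",
                len(pillars_rot), len(geometry.rows), angle)

    # stabilization
    drift = _stage("stabilize")(lambda: estimate_drift(rotated, max_drift_px=config.max_drift_px))
    stable = stabilize(rotated, drift)

    # segmentation
    def _segment():
        marker = stable.channel("nuclear_marker")
        reporter = stable.channel("reporter")
        per_frame = []
        for t in range(stable.n_frames):
            smoothed = smooth_fluorescence(marker[t], sigma=config.gaussian_sigma_px)
            _, obs = segment_frame(
                smoothed,
                marker[t],
                reporter[t],
                frame_index=t,
                pixel_size_um=stable.pixel_size_um,
                geometry=geometry,
                window_px=config.threshold_window_px,
                offset_frac=config.threshold_offset_frac,
                h_depth=config.h_depth,
                min_area_um2=config.min_area_um2,
                max_area_um2=config.max_area_um2,
                min_circularity=config.min_circularity,
            )
            per_frame.append(obs)
        return per_frame

    observations = _stage("segment")(_segment)
    logger.info("segmentation: %d objects over %d frames",
                sum(len(o) for o in observations), len(observations))

    # tracking
    tracks = _stage("track")(
        lambda: build_tracks(
            observations,
            max_distance_um=config.max_distance_um,
            pixel_size_um=stable.pixel_size_um,
            intensity_weight=config.intensity_weight,
            area_weight=config.area_weight,
        )
    )

    # transit events
    def _transits():
        events = []
        for tr in tracks:
            if len(tr) < 2:
                continue
            events.extend(
                detect_transits(
                    tr,
                    geometry,
                    stable.frame_interval_min,
                    migration_direction=config.migration_direction,  # type: ignore[arg-type]
                )
            )
        return events

    transits = _stage("transit")(_transits)

    # rupture events + mitosis reclassification
    def _ruptures():
        candidates = []
        for tr in tracks:
            candidates.extend(
                detect_ruptures(
                    tr,
                    stable.frame_interval_min,
                    jump_frac=config.jump_frac,
                    rise_len=config.rise_len,
                    min_rise_frac=config.min_rise_frac,
                    baseline_tol_frac=config.baseline_tol_frac,
                    delta_zero_tol=config.delta_zero_tol,
                )
            )
        return reclassify_mitosis(
            tracks,
            candidates,
            vicinity_um=config.vicinity_um,
            pixel_size_um=stable.pixel_size_um,
            mitosis_window=config.mitosis_window,
        )

    ruptures, mitoses = _stage("rupture")(_ruptures)

    stage_log = {
        "pillars": len(pillars_rot),
        "rows": len(geometry.rows),
        "objects": int(sum(len(o) for o in observations)),
        "tracks": len(tracks),
        "transits": len(transits),
        "ruptures": len(ruptures),
        "mitoses": len(mitoses),
    }
    return ResultsBundle(
        geometry=geometry,
        drift=drift,
        sequence=stable,
        observations=observations,
        tracks=tracks,
        transits=transits,
        ruptures=ruptures,
        mitoses=mitoses,
        stage_log=stage_log,
    )
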