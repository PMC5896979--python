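"""Analysis configuration: every tunable in one serializable place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class AnalysisConfig:
    """All pipeline tunables with their documented defaults.

    Round-trips losslessly through YAML via :meth:`to_yaml` / :meth:`from_yaml`.
    """

    # input
    input_path: str | None = None
    channel_map: dict | None = None
    pixel_size_um: float | None = None
    frame_interval_min: float | None = None

    # device registration
    boundary_offset_um: float = 7.0
    hough_radius_range_px: tuple[int, int] = (6, 14)
    hough_sensitivity: float = 0.6

    # preprocessing
    gaussian_sigma_px: float = 2.5
    max_drift_px: int = 20

    # segmentation
    threshold_window_px: int = 51
    threshold_offset_frac: float = 0.02
    h_depth: float = 1.0
    min_area_um2: float = 30.0
    max_area_um2: float = 600.0
    min_circularity: float = 0.3

    # tracking
    max_distance_um: float = 40.0
    intensity_weight: float = 2.0
    area_weight: float = 2.0

    # transit detection
    migration_direction: str = "up"

    # rupture detection
    jump_frac: float = 0.20
    rise_len: int = 5
    min_rise_frac: float = 0.01
    baseline_tol_frac: float = 0.10
    delta_zero_tol: float = 0.05
    vicinity_um: float = 40.0
    mitosis_window: int = 1

    # overlay rendering
    trail_window_min: float = 360.0  # draw at most the last six hours of track trail

    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hough_radius_range_px"] = list(self.hough_radius_range_px)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hough_radius_range_px" in d:
            d["hough_radius_range_px"] = tuple(d["hough_radius_range_px"])
        return cls(**d)
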