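"""Synthetic time-lapse generator with full ground truth.

Renders multi-channel stacks that emulate the real experiment: a pillared
PDMS device forming three horizontal rows of constrictions imaged in
transmitted light, elliptical nuclei carrying a chromatin marker and a
nucleoplasmic reporter, dumbbell deformation while squeezing through a pore,
stage drift, photobleaching, envelope-rupture reporter transients and cell
divisions. Every scenario is scripted, so the generator emits machine-
readable ground truth (tracks, transit events, ruptures, divisions, drift,
pillar centers) that is consistent with the rendered images by construction.

Scenarios are deterministic: the same scenario and seed give bit-identical
stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import ImageSequence

# rendering levels (arbitrary camera counts)
TRANSMITTED_BG = 1000.0
PILLAR_LEVEL = 300.0
FLUOR_BG = 100.0

DEFAULT_PIXEL_SIZE_UM = 1.0
DEFAULT_FRAME_INTERVAL_MIN = 10.0


# -- scenario schema -----------------------------------------------------------


@dataclass
class DeviceSpec:
    """Pillar grid: ``n_rows`` horizontal rows of round pillars."""

    n_rows: int = 3
    pillars_per_row: int = 6
    pitch_px: float = 24.0
    radius_px: float = 8.0
    row_spacing_px: float = 55.0
    first_row_y: float = 40.0
    first_pillar_x: float = 38.0
    rotation_deg: float = 0.0

    def level_centers(self) -> np.ndarray:
        """Pillar centers before the device rotation, shape (n, 2) as (x, y)."""
        pts = [
            (self.first_pillar_x + j * self.pitch_px, self.first_row_y + i * self.row_spacing_px)
            for i in range(self.n_rows)
            for j in range(self.pillars_per_row)
        ]
        return np.asarray(pts, dtype=float)

    def row_ys(self) -> list[float]:
        return [self.first_row_y + i * self.row_spacing_px for i in range(self.n_rows)]

    def pore_xs(self) -> list[float]:
        return [
            self.first_pillar_x + (j + 0.5) * self.pitch_px
            for j in range(self.pillars_per_row - 1)
        ]


@dataclass
class NucleusScript:
    """One scripted nucleus: per-frame center, shape and channel levels.

    ``centers``, ``reporter_levels`` are aligned with ``frames`` (the
    contiguous frame indices during which the nucleus exists). The rendered
    shape is an ellipse with semi-axes (a, b), switching to a dumbbell (two
    lobes bridged through the pore, same total y extent) whenever the center
    is within b of a pillar-row centerline and ``allow_dumbbell`` is set.
    """

    nucleus_id: int
    frames: list[int]
    centers: np.ndarray  # (n, 2) level coordinates (x, y)
    semi_axis_a: float = 12.0
    semi_axis_b: float = 8.0
    marker_level: float = 600.0
    reporter_levels: np.ndarray | None = None  # default: constant 500
    allow_dumbbell: bool = True
    halo_frames: set[int] = field(default_factory=set)  # frames with a cytoplasmic halo

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if len(self.centers) != len(self.frames):
            raise ValueError("centers must align with frames")
        if self.reporter_levels is None:
            self.reporter_levels = np.full(len(self.frames), 500.0)
        self.reporter_levels = np.asarray(self.reporter_levels, dtype=float)
        if len(self.reporter_levels) != len(self.frames):
            raise ValueError("reporter_levels must align with frames")


@dataclass
class ScriptedTransit:
    nucleus_id: int
    row_index: int
    entry_frame: int
    exit_frame: int
    outcome: str  # success / failure / ongoing


@dataclass
class ScriptedRupture:
    nucleus_id: int
    start_frame: int
    end_frame: int | None
    jump_frac: float  # fractional ratio jump at onset (0 for sustained rises)
    trigger: str  # jump / sustained_rise


@dataclass
class ScriptedDivision:
    parent_id: int
    daughter_ids: list[int]
    division_frame: int


@dataclass
class Scenario:
    name: str
    shape: tuple[int, int] = (220, 200)  # (H, W)
    n_frames: int = 40
    device: DeviceSpec = field(default_factory=DeviceSpec)
    nuclei: list[NucleusScript] = field(default_factory=list)
    drift: np.ndarray | None = None  # (T, 2) int offsets, frame 1 = (0, 0)
    photobleach: np.ndarray | None = None  # (T,) multiplicative factor
    noise_sigma: float = 10.0
    seed: int = 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    transits: list[ScriptedTransit] = field(default_factory=list)
    ruptures: list[ScriptedRupture] = field(default_factory=list)
    divisions: list[ScriptedDivision] = field(default_factory=list)

    def __post_init__(self):
        if self.drift is None:
            self.drift = np.zeros((self.n_frames, 2), dtype=int)
        self.drift = np.asarray(self.drift, dtype=int)
        if self.photobleach is None:
            self.photobleach = np.ones(self.n_frames)
        self.photobleach = np.asarray(self.photobleach, dtype=float)


@dataclass
class GTObservation:
    x: float
    y: float
    bbox: tuple[int, int, int, int]  # half-open (min_x, min_y, max_x, max_y)
    area: float


@dataclass
class GroundTruth:
    tracks: dict[int, dict[int, GTObservation]]  # nucleus_id -> frame -> obs
    transits: list[ScriptedTransit]
    ruptures: list[ScriptedRupture]
    divisions: list[ScriptedDivision]
    drift: np.ndarray
    pillar_centers_level: np.ndarray
    pillar_centers_rendered: np.ndarray  # frame-1 image coordinates
    rotation_deg: float
    row_centerlines_y: list[float]


# -- rendering -----------------------------------------------------------------


def _rotate_pts(pts: np.ndarray, angle_deg: float, center: tuple[float, float]) -> np.ndarray:
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = center
    dx, dy = pts[..., 0] - cx, pts[..., 1] - cy
    return np.stack([cx + dx * c - dy * s, cy + dx * s + dy * c], axis=-1)


def _paint_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    h, w = img.shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1][((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2] = value


def _ellipse_mask(shape, cx, cy, a, b) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    x0, x1 = max(int(cx - a) - 1, 0), min(int(cx + a) + 2, w)
    y0, y1 = max(int(cy - b) - 1, 0), min(int(cy + b) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return mask


def _nucleus_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    dumbbell_row_y: float | None,
    pore_half_width: float,
) -> np.ndarray:
    """Binary mask of one nucleus; dumbbell when squeezing through a row.

    The dumbbell keeps the same total y extent (center +- b) as the ellipse
    so bounding-box-based transit logic sees a consistent object.
    """
    cx, cy = center
    if dumbbell_row_y is None:
        return _ellipse_mask(shape, cx, cy, a, b)
    lobe_a, lobe_b = 0.7 * a, 0.5 * b
    mask = _ellipse_mask(shape, cx, cy - 0.5 * b, lobe_a, lobe_b)
    mask |= _ellipse_mask(shape, cx, cy + 0.5 * b, lobe_a, lobe_b)
    half_w = max(min(0.8 * pore_half_width, 0.35 * a), 1.0)
    h, w = shape
    y0 = max(int(np.floor(cy - 0.5 * b)), 0)
    y1 = min(int(np.ceil(cy + 0.5 * b)) + 1, h)
    x0 = max(int(np.floor(cx - half_w)), 0)
    x1 = min(int(np.ceil(cx + half_w)) + 1, w)
    if y0 < y1 and x0 < x1:
        mask[y0:y1, x0:x1] = True
    return mask


def render_scenario(scenario: Scenario) -> tuple[ImageSequence, GroundTruth]:
    """Rasterize a scenario and derive its ground truth.

    The device rotation and the per-frame drift are applied analytically to
    all scripted positions before painting, so the ground truth is exact for
    the rendered images. Ground-truth track observations (centroid, bbox,
    area) are measured on each nucleus' noise-free mask.
    """
    h, w = scenario.shape
    T = scenario.n_frames
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    dev = scenario.device
    rng = np.random.default_rng(scenario.seed)

    pillars_level = dev.level_centers()
    pillars_rot = _rotate_pts(pillars_level, dev.rotation_deg, center)

    by_frame: dict[int, list[tuple[NucleusScript, int]]] = {t: [] for t in range(T)}
    for script in scenario.nuclei:
        for k, t in enumerate(script.frames):
            if not 0 <= t < T:
                raise ValueError(
                    f"nucleus {script.nucleus_id} scripted at frame {t} outside sequence"
                )
            by_frame[t].append((script, k))

    row_ys = dev.row_ys()
    pore_half = max((dev.pitch_px - 2 * dev.radius_px) / 2.0, 1.0)

    frames = np.empty((T, 3, h, w), dtype=float)
    gt_tracks: dict[int, dict[int, GTObservation]] = {s.nucleus_id: {} for s in scenario.nuclei}

    for t in range(T):
        dx, dy = (int(v) for v in scenario.drift[t])
        bleach = float(scenario.photobleach[t])

        trans = np.full((h, w), TRANSMITTED_BG)
        for px, py in pillars_rot:
            _paint_disk(trans, px + dx, py + dy, dev.radius_px, PILLAR_LEVEL)

        marker = np.full((h, w), FLUOR_BG)
        reporter = np.full((h, w), FLUOR_BG)

        for script, k in by_frame[t]:
            cx_l, cy_l = script.centers[k]
            if not (0 <= cx_l < w and 0 <= cy_l < h):
                raise ValueError(
                    f"nucleus {script.nucleus_id} scripted outside the frame at t={t}"
                )
            dumb_row = None
            if script.allow_dumbbell:
                for ry in row_ys:
                    if abs(cy_l - ry) < script.semi_axis_b:
                        dumb_row = ry
                        break
            # rotate the center with the device, then drift
            cx_r, cy_r = _rotate_pts(
                np.array([[cx_l, cy_l]]), dev.rotation_deg, center
            )[0]
            cx_i, cy_i = cx_r + dx, cy_r + dy
            mask = _nucleus_mask(
                (h, w), (cx_i, cy_i), script.semi_axis_a, script.semi_axis_b,
                None if dumb_row is None else dumb_row, pore_half,
            )
            if not mask.any():
                raise ValueError(
                    f"nucleus {script.nucleus_id} fell fully outside the frame at t={t}"
                )
            rep_level = float(script.reporter_levels[k])
            marker[mask] = script.marker_level
            reporter[mask] = rep_level
            if t in script.halo_frames:
                # diffuse cytoplasmic reporter around a ruptured nucleus
                halo = _ellipse_mask(
                    (h, w), cx_i, cy_i, 2 * script.semi_axis_a, 2 * script.semi_axis_a
                ) & ~mask
                base = np.max(script.reporter_levels)
                reporter[halo] = np.maximum(
                    reporter[halo], FLUOR_BG + 0.3 * max(base - rep_level, 0.0)
                )

            ys, xs = np.nonzero(mask)
            bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
            gt_tracks[script.nucleus_id][t] = GTObservation(
                x=float(xs.mean()), y=float(ys.mean()), bbox=bbox, area=float(mask.sum())
            )

        marker = FLUOR_BG + (marker - FLUOR_BG) * bleach
        reporter = FLUOR_BG + (reporter - FLUOR_BG) * bleach

        if scenario.noise_sigma > 0:
            trans = trans + rng.normal(0, scenario.noise_sigma, (h, w))
            marker = marker + rng.normal(0, scenario.noise_sigma, (h, w))
            reporter = reporter + rng.normal(0, scenario.noise_sigma, (h, w))

        frames[t, 0] = trans
        frames[t, 1] = marker
        frames[t, 2] = reporter

    sequence = ImageSequence(
        frames,
        pixel_size_um=scenario.pixel_size_um,
        frame_interval_min=scenario.frame_interval_min,
    )
    gt = GroundTruth(
        tracks=gt_tracks,
        transits=list(scenario.transits),
        ruptures=list(scenario.ruptures),
        divisions=list(scenario.divisions),
        drift=scenario.drift.copy(),
        pillar_centers_level=pillars_level,
        pillar_centers_rendered=pillars_rot + scenario.drift[0],
        rotation_deg=dev.rotation_deg,
        row_centerlines_y=row_ys,
    )
    return sequence, gt


# -- trajectory builders -------------------------------------------------------


def transit_trajectory(
    nucleus_id: int,
    device: DeviceSpec,
    row_index: int,
    pore_index: int,
    n_frames: int,
    kind: str,
    entry_frame: int,
    attempt_len: int,
    boundary_offset_px: float = 7.0,
    b: float = 8.0,
    marker_level: float = 600.0,
) -> tuple[NucleusScript, ScriptedTransit | None]:
    """Script one constriction interaction with exactly known event frames.

    Positions keep a 5-px margin to every boundary crossing so that small
    segmentation bbox errors cannot shift the crossing frame. ``kind`` is one
    of ``success``, ``failure``, ``graze`` or ``ongoing``; for a success the
    nucleus first clears the exit boundary at ``entry_frame + attempt_len``.
    """
    ry = device.row_ys()[row_index]
    px = device.pore_xs()[pore_index]
    y_out = ry + boundary_offset_px + b + 5.0  # comfortably outside
    # leading-edge margin at entry: min_y = cy - b = ry + off - 5  =>  cy = ry + off - 5 + b
    y_first = ry + boundary_offset_px - 5.0 + b
    # trailing-edge margin before exit: max_y = cy + b = ry - off + 5  =>  cy = ry - off + 5 - b
    y_last = ry - boundary_offset_px + 5.0 - b
    y_passed = ry - boundary_offset_px - b - 5.0

    ys = np.full(n_frames, y_out)
    transit: ScriptedTransit | None = None
    if kind == "graze":
        ys[entry_frame] = y_first
    elif kind == "success":
        exit_frame = entry_frame + attempt_len
        steps = np.linspace(y_first, y_last, attempt_len)
        ys[entry_frame : entry_frame + attempt_len] = steps
        ys[exit_frame:] = y_passed
        transit = ScriptedTransit(nucleus_id, row_index, entry_frame, exit_frame, "success")
    elif kind == "failure":
        half = max(attempt_len // 2, 1)
        deepest = ry + 1.0  # straddles the centerline but never nears the exit margin
        down = np.linspace(y_first, deepest, half + 1)
        up = np.linspace(deepest, y_first, attempt_len - half)
        steps = np.concatenate([down[:-1], up]) if attempt_len > 1 else np.array([y_first])
        ys[entry_frame : entry_frame + attempt_len] = steps[:attempt_len]
        last = entry_frame + attempt_len - 1
        transit = ScriptedTransit(nucleus_id, row_index, entry_frame, last, "failure")
    elif kind == "ongoing":
        steps = np.linspace(y_first, ry + 1.0, n_frames - entry_frame)
        ys[entry_frame:] = steps
        transit = ScriptedTransit(nucleus_id, row_index, entry_frame, n_frames - 1, "ongoing")
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")

    centers = np.stack([np.full(n_frames, px), ys], axis=1)
    script = NucleusScript(
        nucleus_id=nucleus_id,
        frames=list(range(n_frames)),
        centers=centers,
        marker_level=marker_level,
    )
    return script, transit


def rupture_ratio_trace(
    n_frames: int,
    start: int,
    duration: int,
    jump_frac: float = 0.0,
    rise_per_frame: float = 0.0,
    rise_len: int = 0,
) -> tuple[np.ndarray, int | None]:
    """Ratio multiplier trace for a rupture event, plus its true end frame.

    A jump rupture multiplies the ratio by (1 + jump_frac) at ``start``; a
    sustained-rise rupture climbs by ``rise_per_frame`` per frame for
    ``rise_len`` frames beginning after ``start``. Recovery decays toward
    baseline and finishes with steps (… -> 1.2 -> 1.02 -> 1.0) engineered so
    the rule-based end lands exactly on the scripted end frame.
    """
    rho = np.ones(n_frames)
    if jump_frac > 0:
        peak = 1.0 + jump_frac
        peak_frame = start
    else:
        peak = (1.0 + rise_per_frame) ** rise_len
        peak_frame = start + rise_len
        for k in range(1, rise_len + 1):
            if start + k < n_frames:
                rho[start + k] = (1.0 + rise_per_frame) ** k
    end = start + duration
    if end >= n_frames - 1:
        # never recovers within the sequence: plateau at the peak
        rho[peak_frame:] = peak
        return rho, None
    rho[peak_frame] = peak
    tail = [min(1.2, peak), 1.02, 1.0]
    decay_frames = np.arange(peak_frame + 1, end - 1)
    if len(decay_frames):
        rho[decay_frames] = np.linspace(peak, min(1.2, peak), len(decay_frames) + 2)[1:-1]
    rho[end - 2] = tail[0] if end - 2 > peak_frame else rho[end - 2]
    rho[end - 1] = tail[1]
    rho[end:] = tail[2]
    return rho, end


def stationary_nucleus(
    nucleus_id: int,
    position: tuple[float, float],
    n_frames: int,
    marker_level: float = 600.0,
    reporter_base: float = 500.0,
    ratio_multiplier: np.ndarray | None = None,
    halo_frames: set[int] | None = None,
    jitter: np.ndarray | None = None,
) -> NucleusScript:
    """A non-migrating nucleus whose ratio trace is scripted via the reporter."""
    if ratio_multiplier is None:
        ratio_multiplier = np.ones(n_frames)
    centers = np.tile(np.asarray(position, dtype=float), (n_frames, 1))
    if jitter is not None:
        centers = centers + jitter
    return NucleusScript(
        nucleus_id=nucleus_id,
        frames=list(range(n_frames)),
        centers=centers,
        marker_level=marker_level,
        reporter_levels=reporter_base / np.asarray(ratio_multiplier, dtype=float),
        allow_dumbbell=False,
        halo_frames=halo_frames or set(),
    )


# -- fixed suites --------------------------------------------------------------


def registration_suite() -> list[Scenario]:
    """Devices at rotations -5..+5 degrees with 12-24 pillars, no cells."""
    scenarios = []
    for i, (rot, per_row) in enumerate(
        [(-5.0, 6), (-2.5, 8), (0.0, 4), (2.5, 5), (5.0, 7)]
    ):
        # keep wide grids inside the frame
        x0 = 38.0 if per_row <= 6 else 16.0
        dev = DeviceSpec(pillars_per_row=per_row, rotation_deg=rot, first_pillar_x=x0)
        scenarios.append(
            Scenario(
                name=f"registration_{i}",
                n_frames=2,
                device=dev,
                noise_sigma=5.0,
                seed=100 + i,
            )
        )
    return scenarios


def tracking_suite() -> list[Scenario]:
    """The standard scene: 12 migrating nuclei over 50 frames, two touching
    pairs, sawtooth drift and mild photobleaching, no constriction overlap."""
    T = 50
    dev = DeviceSpec()
    rng = np.random.default_rng(42)
    nuclei = []
    # two movers per horizontal lane, one confined to each lateral half of
    # the field so they never meet; lanes keep clear of the constriction
    # bands (rows at y 40/95/150, boundaries +-7 px, semi-minor axis 8)
    lanes = [22.0, 67.0, 170.0, 192.0]
    half_ranges = [(15.0, 85.0), (115.0, 185.0)]
    nid = 0
    for y0 in lanes:
        for (lo, hi) in half_ranges:
            x0 = rng.uniform(lo + 10, hi - 10)
            vx = rng.uniform(2.0, 4.0) * rng.choice([-1.0, 1.0])
            xs = x0 + vx * np.arange(T)
            span = hi - lo
            xs = lo + np.abs((xs - lo + span) % (2 * span) - span)
            ys = np.full(T, y0) + 1.0 * np.sin(2 * np.pi * np.arange(T) / 25.0 + nid)
            nuclei.append(
                NucleusScript(
                    nucleus_id=nid,
                    frames=list(range(T)),
                    centers=np.stack([xs, ys], axis=1),
                    marker_level=500.0 + 30.0 * nid,
                    allow_dumbbell=False,
                )
            )
            nid += 1
    # two touching pairs (overlapping ellipses), drifting slowly together
    for pid, (x0, y0) in enumerate([(55.0, 122.0), (155.0, 122.0)]):
        for k in range(2):
            xs = x0 + 10.5 * (2 * k - 1) * np.ones(T) + 1.0 * np.sin(
                2 * np.pi * np.arange(T) / 40.0
            )
            ys = np.full(T, y0) + 0.5 * np.arange(T) / 10.0
            nuclei.append(
                NucleusScript(
                    nucleus_id=nid,
                    frames=list(range(T)),
                    centers=np.stack([xs, ys], axis=1),
                    semi_axis_a=12.0,
                    semi_axis_b=9.0,
                    marker_level=850.0 + 60.0 * (2 * pid + k),
                    allow_dumbbell=False,
                )
            )
            nid += 1
    drift = np.zeros((T, 2), dtype=int)
    drift[:, 0] = np.abs((np.arange(T) + 4) % 8 - 4) - 2  # sawtooth in x, +-2 px
    drift[:, 1] = (np.arange(T) // 10) % 3 - 1
    drift -= drift[0]
    bleach = 0.998 ** np.arange(T)
    return [
        Scenario(
            name="tracking_standard",
            n_frames=T,
            device=dev,
            nuclei=nuclei,
            drift=drift,
            photobleach=bleach,
            noise_sigma=10.0,
            seed=7,
        )
    ]


def transit_suite() -> list[Scenario]:
    """20 scripted constriction interactions: successes, failures, one-frame
    grazes and ongoing attempts, with exactly known event frames."""
    # (kind, row, pore, entry, attempt_len); within a scenario, trajectories
    # sharing a row sit at pores >= 2 apart so they can never touch
    specs = [
        ("success", 0, 0, 8, 4),
        ("success", 1, 2, 10, 6),
        ("failure", 2, 4, 6, 3),
        ("graze", 1, 4, 12, 1),
        ("success", 2, 1, 14, 8),
        ("failure", 0, 2, 9, 5),
        ("success", 0, 4, 5, 3),
        ("graze", 2, 0, 20, 1),
        ("success", 1, 3, 7, 10),
        ("failure", 1, 1, 16, 4),
        ("success", 2, 2, 11, 5),
        ("ongoing", 0, 1, 30, 0),
        ("failure", 2, 0, 8, 7),
        ("success", 0, 3, 18, 4),
        ("graze", 1, 4, 9, 1),
        ("failure", 0, 0, 22, 2),
        ("success", 1, 1, 13, 7),
        ("ongoing", 2, 3, 32, 0),
        ("failure", 1, 3, 25, 6),
        ("graze", 0, 2, 28, 1),
    ]
    T = 45
    dev = DeviceSpec()
    scenarios = []
    for s_idx in range(4):
        nuclei, transits = [], []
        for k in range(5):
            kind, row, pore, entry, alen = specs[s_idx * 5 + k]
            nid = s_idx * 5 + k
            script, transit = transit_trajectory(
                nucleus_id=nid,
                device=dev,
                row_index=row,
                pore_index=pore,
                n_frames=T,
                kind=kind,
                entry_frame=entry,
                attempt_len=alen,
                marker_level=550.0 + 70.0 * k,
            )
            nuclei.append(script)
            if transit is not None:
                transits.append(transit)
        scenarios.append(
            Scenario(
                name=f"transit_{s_idx}",
                n_frames=T,
                device=dev,
                nuclei=nuclei,
                transits=transits,
                noise_sigma=8.0,
                seed=200 + s_idx,
            )
        )
    return scenarios


def rupture_suite() -> list[Scenario]:
    """30 rupture traces (ratio jumps 10-60% and sustained rises), 10
    divisions and 10 flat controls, grouped five nuclei per scenario."""
    T = 40
    dev = DeviceSpec()
    positions = [(30.0, 65.0), (100.0, 65.0), (170.0, 65.0), (55.0, 122.0), (145.0, 122.0)]
    starts = [6, 11, 16, 21, 26]

    jump_specs = []  # (jump_frac, duration) — 24 jump ruptures
    for i, j in enumerate([0.10, 0.15, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60]):
        jump_specs.append((j, 3 + (i % 6)))
    for i, j in enumerate([0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60]):
        jump_specs.append((j, 6 + (i % 8)))
    for i, j in enumerate([0.22, 0.28, 0.33, 0.38, 0.48, 0.58]):
        jump_specs.append((j, 10 + 2 * (i % 5)))
    rise_specs = [(0.05, 5), (0.06, 6), (0.05, 6), (0.07, 5), (0.06, 5), (0.05, 7)]

    scenarios: list[Scenario] = []
    nid = 0

    def new_scenario(idx, nuclei, ruptures, divisions):
        return Scenario(
            name=f"rupture_{idx}",
            n_frames=T,
            device=dev,
            nuclei=nuclei,
            ruptures=ruptures,
            divisions=divisions,
            noise_sigma=6.0,
            seed=300 + idx,
        )

    # five scenarios of jump ruptures (24 traces)
    for s_idx in range(5):
        nuclei, ruptures = [], []
        for k in range(5):
            if s_idx * 5 + k >= len(jump_specs):
                break
            jump, dur = jump_specs[s_idx * 5 + k]
            start = starts[k]
            rho, end = rupture_ratio_trace(T, start, dur, jump_frac=jump)
            halo = set(range(start, (end if end is not None else T)))
            nuclei.append(
                stationary_nucleus(
                    nid, positions[k], T, marker_level=550.0 + 40.0 * k,
                    ratio_multiplier=rho, halo_frames=halo,
                )
            )
            ruptures.append(ScriptedRupture(nid, start, end, jump, "jump"))
            nid += 1
        scenarios.append(new_scenario(s_idx, nuclei, ruptures, []))

    # sustained-rise ruptures (6) — ratio climbs a few percent per frame
    nuclei, ruptures = [], []
    for k, (rate, rl) in enumerate(rise_specs[:5]):
        start = starts[k]
        rho, end = rupture_ratio_trace(T, start, 10 + rl, rise_per_frame=rate, rise_len=rl)
        nuclei.append(
            stationary_nucleus(
                nid, positions[k], T, marker_level=550.0 + 40.0 * k, ratio_multiplier=rho
            )
        )
        ruptures.append(ScriptedRupture(nid, start, end, 0.0, "sustained_rise"))
        nid += 1
    scenarios.append(new_scenario(5, nuclei, ruptures, []))
    rate, rl = rise_specs[5]
    rho, end = rupture_ratio_trace(T, 8, 12, rise_per_frame=rate, rise_len=rl)
    nuclei = [stationary_nucleus(nid, positions[0], T, ratio_multiplier=rho)]
    ruptures = [ScriptedRupture(nid, 8, end, 0.0, "sustained_rise")]
    nid += 1
    scenarios.append(new_scenario(6, nuclei, ruptures, []))

    # flat controls (10)
    for s_idx in range(2):
        nuclei = []
        for k in range(5):
            nuclei.append(
                stationary_nucleus(nid, positions[k], T, marker_level=520.0 + 45.0 * k)
            )
            nid += 1
        scenarios.append(new_scenario(7 + s_idx, nuclei, [], []))

    # divisions (10), two scenarios of five
    for s_idx in range(2):
        nuclei, divisions = [], []
        for k in range(5):
            div_frame = starts[k]
            parent_id = nid
            d1_id, d2_id = nid + 1, nid + 2
            nid += 3
            x0, y0 = positions[k]
            pf = list(range(0, div_frame + 1))
            # reporter halves on envelope breakdown at the division frame
            rho = np.ones(len(pf))
            rho[-1] = 2.0
            nuclei.append(
                NucleusScript(
                    nucleus_id=parent_id,
                    frames=pf,
                    centers=np.tile((x0, y0), (len(pf), 1)),
                    marker_level=600.0,
                    reporter_levels=500.0 / rho,
                    allow_dumbbell=False,
                )
            )
            for d_id, off in ((d1_id, -11.0), (d2_id, +11.0)):
                df = list(range(div_frame + 1, T))
                n_d = len(df)
                rec = np.linspace(2.0, 1.0, min(6, n_d))
                rho_d = np.concatenate([rec, np.ones(max(n_d - len(rec), 0))])
                nuclei.append(
                    NucleusScript(
                        nucleus_id=d_id,
                        frames=df,
                        centers=np.tile((x0 + off, y0), (n_d, 1)),
                        semi_axis_a=7.0,
                        semi_axis_b=5.0,
                        marker_level=600.0,
                        reporter_levels=500.0 / rho_d,
                        allow_dumbbell=False,
                    )
                )
            divisions.append(ScriptedDivision(parent_id, [d1_id, d2_id], div_frame))
        scenarios.append(new_scenario(9 + s_idx, nuclei, [], divisions))
    return scenarios


def touching_pair_mask(
    sep_px: float = 21.0,
    angle_deg: float = 0.0,
    shape: tuple[int, int] = (72, 72),
    a: float = 12.0,
    b: float = 9.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask of two overlapping ellipses plus their true centers.

    The pair axis is rotated by ``angle_deg``; ``sep_px`` below the summed
    extents produces a necked union that a distance-transform watershed
    should cut along the bisector.
    """
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    th = np.radians(angle_deg)
    off = np.array([np.cos(th), np.sin(th)]) * sep_px / 2.0
    c1 = np.array([cx, cy]) - off
    c2 = np.array([cx, cy]) + off
    mask = _ellipse_mask(shape, c1[0], c1[1], a, b) | _ellipse_mask(shape, c2[0], c2[1], a, b)
    return mask, np.stack([c1, c2])


def touching_pair_scenarios() -> list[Scenario]:
    """20 rendered scenes of one overlapping nucleus pair each.

    Pair axes sweep 0-171 degrees; the separation is 1.75x the ellipse
    radius along the pair axis, which leaves a pronounced neck between the
    lobes. Used to benchmark watershed splitting of touching nuclei.
    """
    a, b, f = 12.0, 9.0, 1.75
    scenarios = []
    for k in range(20):
        angle = 9.0 * k
        th = np.radians(angle)
        u = np.array([np.cos(th), np.sin(th)])
        r = np.hypot(a * np.cos(th), b * np.sin(th))
        c = np.array([100.0, 122.0])  # mid-corridor, away from the bands
        nuclei = [
            NucleusScript(
                nucleus_id=i,
                frames=[0],
                centers=np.array([c + (2 * i - 1) * f * r / 2 * u]),
                semi_axis_a=a,
                semi_axis_b=b,
                marker_level=850.0,
                allow_dumbbell=False,
            )
            for i in range(2)
        ]
        scenarios.append(
            Scenario(
                name=f"pair_{k}",
                n_frames=1,
                nuclei=nuclei,
                noise_sigma=10.0,
                seed=700 + k,
            )
        )
    return scenarios


def dumbbell_fixture_scenarios() -> list[Scenario]:
    """20 single-nucleus scenes with the nucleus mid-pore (dumbbell shape),
    for checking that in-band objects are never split."""
    dev = DeviceSpec()
    scenarios = []
    offsets = [-4.0, -2.0, 0.0, 2.0]
    k = 0
    for row in range(3):
        for pore in range(5):
            if k >= 20:
                break
            ry = dev.row_ys()[row]
            px = dev.pore_xs()[pore]
            dy = offsets[k % len(offsets)]
            script = NucleusScript(
                nucleus_id=0,
                frames=[0, 1],
                centers=np.array([[px, ry + dy], [px, ry + dy]]),
                marker_level=650.0,
            )
            scenarios.append(
                Scenario(
                    name=f"dumbbell_{k}",
                    n_frames=2,
                    device=dev,
                    nuclei=[script],
                    noise_sigma=6.0,
                    seed=500 + k,
                )
            )
            k += 1
    # a few extra with the second offset cycle to reach 20
    while len(scenarios) < 20:
        k = len(scenarios)
        ry = dev.row_ys()[k % 3]
        px = dev.pore_xs()[(k + 2) % 5]
        script = NucleusScript(
            nucleus_id=0,
            frames=[0, 1],
            centers=np.array([[px, ry + 3.0], [px, ry + 3.0]]),
            marker_level=650.0,
        )
        scenarios.append(
            Scenario(
                name=f"dumbbell_{k}",
                n_frames=2,
                device=dev,
                nuclei=[script],
                noise_sigma=6.0,
                seed=500 + k,
            )
        )
    return scenarios


def standard_suites() -> dict[str, list[Scenario]]:
    """The fixed, seeded scenario suites used for benchmarking and acceptance."""
    return {
        "registration_suite": registration_suite(),
        "tracking_suite": tracking_suite(),
        "transit_suite": transit_suite(),
        "rupture_suite": rupture_suite(),
    }
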