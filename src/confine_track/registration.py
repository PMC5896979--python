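"""Device registration: pillar detection, rotation and virtual boundaries.

The microfluidic migration device is formed by rows of round PDMS pillars;
the gaps between adjacent pillars in a row are the constrictions cells must
squeeze through. Registration proceeds in three steps:

1. detect the pillars in a transmitted-light frame with a circular Hough
   transform,
2. estimate the in-plane rotation that makes the pillar rows horizontal and
   rotate the whole sequence by it,
3. define, for every pillar row, a horizontal centerline plus virtual entry
   and exit boundary lines a fixed physical distance above and below it.

All coordinates are 0-based pixels with y increasing downward; successful
passage is movement toward decreasing y unless ``migration_direction`` is
flipped downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks, rotate as _sk_rotate

from .sequence import ImageSequence

DEFAULT_BOUNDARY_OFFSET_UM = 7.0  # boundary lines 7 µm above/below each centerline
DEFAULT_RADIUS_RANGE_PX = (6, 14)


class RegistrationError(RuntimeError):
    """Raised when the device geometry cannot be registered."""


@dataclass(frozen=True)
class PillarCircle:
    """One detected pillar: center (px) and radius (px)."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("pillar radius must be positive")


@dataclass(frozen=True)
class ConstrictionRow:
    """One row of constrictions after rotation.

    ``upper_boundary_y < centerline_y < lower_boundary_y`` (y grows downward);
    both boundaries sit exactly ``boundary_offset`` pixels from the centerline.
    ``constriction_x_centers`` are the x midpoints of the gaps between
    adjacent pillars.
    """

    centerline_y: float
    upper_boundary_y: float
    lower_boundary_y: float
    constriction_x_centers: tuple[float, ...] = ()

    def __post_init__(self):
        if not (self.upper_boundary_y < self.centerline_y < self.lower_boundary_y):
            raise ValueError("boundaries must straddle the centerline")


@dataclass
class DeviceGeometry:
    """Registered device: pillars, rotation and constriction rows."""

    pillars: list[PillarCircle]
    rotation_deg: float
    rows: list[ConstrictionRow]
    boundary_offset_um: float
    pixel_size_um: float

    def __post_init__(self):
        if self.boundary_offset_um <= 0:
            raise ValueError("boundary_offset_um must be positive")
        if not -45 < self.rotation_deg <= 45:
            raise ValueError("rotation_deg must lie in (-45, 45]")
        self.rows = sorted(self.rows, key=lambda r: r.centerline_y)

    # -- serialization ---------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "pillars": [asdict(p) for p in self.pillars],
            "rotation_deg": self.rotation_deg,
            "rows": [
                {
                    "centerline_y": r.centerline_y,
                    "upper_boundary_y": r.upper_boundary_y,
                    "lower_boundary_y": r.lower_boundary_y,
                    "constriction_x_centers": list(r.constriction_x_centers),
                }
                for r in self.rows
            ],
            "boundary_offset_um": self.boundary_offset_um,
            "pixel_size_um": self.pixel_size_um,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DeviceGeometry":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            pillars=[PillarCircle(**p) for p in d["pillars"]],
            rotation_deg=d["rotation_deg"],
            rows=[
                ConstrictionRow(
                    centerline_y=r["centerline_y"],
                    upper_boundary_y=r["upper_boundary_y"],
                    lower_boundary_y=r["lower_boundary_y"],
                    constriction_x_centers=tuple(r["constriction_x_centers"]),
                )
                for r in d["rows"]
            ],
            boundary_offset_um=d["boundary_offset_um"],
            pixel_size_um=d["pixel_size_um"],
        )


# -- pillar detection ----------------------------------------------------------


def detect_pillars(
    transmitted_frame: np.ndarray,
    radius_range_px: tuple[int, int] = DEFAULT_RADIUS_RANGE_PX,
    sensitivity: float = 0.6,
) -> list[PillarCircle]:
    """Detect round pillars in a transmitted-light frame via a circular Hough transform.

    Circles are accepted at accumulator peaks at least ``sensitivity`` times
    the strongest peak; duplicate detections closer than one radius are
    suppressed, keeping the stronger peak. Result is sorted by
    (center_y, center_x).

    Raises
    ------
    RegistrationError
        If fewer than two circles are found (a row needs at least a gap).
    """
    frame = np.asarray(transmitted_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("transmitted frame must be 2-D")
    lo, hi = int(radius_range_px[0]), int(radius_range_px[1])
    if hi < lo or lo < 1:
        raise ValueError("radius range must be a nonempty positive interval")

    span = frame.max() - frame.min()
    if span == 0:
        raise RegistrationError(
            f"registration failure: no circles with radius in [{lo}, {hi}] px "
            "(blank frame)"
        )
    norm = (frame - frame.min()) / span
    edges = canny(norm, sigma=2.0)
    radii = np.arange(lo, hi + 1)
    accum = hough_circle(edges, radii)
    # generous cap on peak count; weak peaks are cut by the sensitivity threshold
    peaks = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=lo,
        min_ydistance=lo,
        total_num_peaks=400,
    )
    strengths, cxs, cys, rads = (np.asarray(a) for a in peaks)
    keep_strength = strengths >= sensitivity * (strengths[0] if len(strengths) else 1.0)
    strengths, cxs, cys, rads = (
        a[keep_strength] for a in (strengths, cxs, cys, rads)
    )

    # greedy non-maximum suppression: drop a circle whose center lies within
    # the radius of an already accepted, stronger circle
    accepted: list[tuple[float, float, float, float]] = []
    for s, x, y, r in sorted(zip(strengths, cxs, cys, rads), key=lambda t: -t[0]):
        if any((x - ax) ** 2 + (y - ay) ** 2 < max(r, ar) ** 2 for _, ax, ay, ar in accepted):
            continue
        accepted.append((s, float(x), float(y), float(r)))

    h, w = frame.shape
    circles = []
    for _, x, y, r in accepted:
        if not (0 <= x < w and 0 <= y < h):
            continue
        x, y = _refine_center(norm, x, y, r)
        circles.append(PillarCircle(center_x=x, center_y=y, radius=r))
    if len(circles) < 2:
        raise RegistrationError(
            f"registration failure: found {len(circles)} circle(s) with radius in "
            f"[{lo}, {hi}] px; at least 2 pillars are required"
        )
    return sorted(circles, key=lambda c: (c.center_y, c.center_x))


def _refine_center(norm: np.ndarray, x: float, y: float, r: float) -> tuple[float, float]:
    """Subpixel refinement: darkness-weighted centroid inside the circle.

    Pillars are dark on a bright background; the accumulator peak is
    integer-quantized, so refine against the image itself. Falls back to the
    Hough center when the window is degenerate.
    """
    h, w = norm.shape
    rr = int(np.ceil(r)) + 1
    x0, x1 = max(int(x) - rr, 0), min(int(x) + rr + 1, w)
    y0, y1 = max(int(y) - rr, 0), min(int(y) + rr + 1, h)
    win = norm[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
    weight = np.where(inside, np.clip(win.max() - win, 0, None), 0.0)
    total = weight.sum()
    if total <= 0:
        return float(x), float(y)
    return float((weight * xx).sum() / total), float((weight * yy).sum() / total)


# -- rotation ------------------------------------------------------------------


def cluster_rows(pillars: list[PillarCircle]) -> list[list[PillarCircle]]:
    """Group pillars into rows: a y-gap larger than 2x the median radius starts a new row."""
    if not pillars:
        return []
    med_r = float(np.median([p.radius for p in pillars]))
    gap = 2.0 * med_r
    rows: list[list[PillarCircle]] = []
    for p in sorted(pillars, key=lambda c: c.center_y):
        if rows and p.center_y - rows[-1][-1].center_y <= gap:
            rows[-1].append(p)
        else:
            rows.append([p])
    return rows


def estimate_rotation(pillars: list[PillarCircle]) -> float:
    """Correcting rotation (degrees) that makes the pillar rows horizontal.

    Pillars are clustered into rows; a straight line is fit through each row's
    centers and the per-row slopes are averaged (weighted by row size). The
    returned angle, applied with :func:`rotate_sequence`, levels the rows.
    Result lies in (-45, 45].
    """
    if len(pillars) < 2:
        raise ValueError("need at least 2 pillars to estimate rotation")
    xs = np.array([p.center_x for p in pillars])
    ys = np.array([p.center_y for p in pillars])
    if np.ptp(xs) == 0 and np.ptp(ys) == 0:
        raise ValueError("degenerate pillar configuration: all centers coincide")

    angles, weights = [], []
    for row in cluster_rows(pillars):
        if len(row) < 2:
            continue
        rx = np.array([p.center_x for p in row])
        ry = np.array([p.center_y for p in row])
        if np.ptp(rx) == 0:
            continue
        slope = np.polyfit(rx, ry, 1)[0]
        angles.append(np.degrees(np.arctan(slope)))
        weights.append(len(row))
    if not angles:
        # single column of pillars or rows of one: fall back to the overall pair
        dx, dy = xs.max() - xs.min(), ys[np.argmax(xs)] - ys[np.argmin(xs)]
        if dx == 0:
            raise ValueError("cannot estimate rotation from a vertical pillar column")
        angles, weights = [np.degrees(np.arctan2(dy, dx))], [1.0]
    theta = float(np.average(angles, weights=weights))
    correction = -theta
    while correction <= -45:
        correction += 90
    while correction > 45:
        correction -= 90
    return correction


def rotate_points(points: np.ndarray, angle_deg: float, center: tuple[float, float]) -> np.ndarray:
    """Rotate (x, y) points by ``angle_deg`` about ``center``.

    Uses the same convention as :func:`rotate_sequence`: positive angles move
    content the way the image rotation does (y-down coordinates).
    """
    pts = np.asarray(points, dtype=float)
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = center
    dx, dy = pts[..., 0] - cx, pts[..., 1] - cy
    return np.stack([cx + dx * c - dy * s, cy + dx * s + dy * c], axis=-1)


def rotate_frame(frame: np.ndarray, angle_deg: float, cval: float | None = None) -> np.ndarray:
    """Rotate one frame about its center with bilinear interpolation.

    Out-of-frame regions are filled with ``cval`` (default: the frame median).
    """
    if cval is None:
        cval = float(np.median(frame))
    # skimage's rotate(angle) maps content points by R(-angle) in y-down
    # coordinates; negate so our angle matches rotate_points
    return _sk_rotate(
        np.asarray(frame, dtype=float), -angle_deg, order=1, cval=cval, preserve_range=True
    )


def rotate_sequence(sequence: ImageSequence, angle_deg: float) -> ImageSequence:
    """Rotate every channel of every frame by the same angle about the image center."""
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if angle_deg == 0:
        return sequence.with_frames(sequence.frames.copy())
    out = np.empty_like(sequence.frames, dtype=float)
    for c in range(sequence.frames.shape[1]):
        cval = float(np.median(sequence.frames[:, c]))
        for t in range(sequence.n_frames):
            out[t, c] = rotate_frame(sequence.frames[t, c], angle_deg, cval=cval)
    return sequence.with_frames(out)


# -- geometry ------------------------------------------------------------------


def build_geometry(
    pillars: list[PillarCircle],
    boundary_offset_um: float = DEFAULT_BOUNDARY_OFFSET_UM,
    pixel_size_um: float = 1.0,
    rotation_deg: float = 0.0,
) -> DeviceGeometry:
    """Build constriction rows from pillars already in rotated coordinates.

    Each pillar row yields one :class:`ConstrictionRow` whose centerline is
    the mean pillar-center y and whose entry/exit boundaries sit exactly
    ``boundary_offset_um / pixel_size_um`` pixels above and below it.
    Constriction x centers are midpoints between adjacent pillars in the row.
    """
    if boundary_offset_um <= 0:
        raise ValueError("boundary_offset_um must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    offset_px = boundary_offset_um / pixel_size_um
    rows = []
    for row_pillars in cluster_rows(pillars):
        cy = float(np.mean([p.center_y for p in row_pillars]))
        xs = sorted(p.center_x for p in row_pillars)
        centers = tuple((a + b) / 2.0 for a, b in zip(xs, xs[1:]))
        rows.append(
            ConstrictionRow(
                centerline_y=cy,
                upper_boundary_y=cy - offset_px,
                lower_boundary_y=cy + offset_px,
                constriction_x_centers=centers,
            )
        )
    if len(rows) != 3:
        warnings.warn(
            f"expected 3 constriction rows, found {len(rows)}; continuing "
            "(device designs vary)",
            stacklevel=2,
        )
    return DeviceGeometry(
        pillars=list(pillars),
        rotation_deg=rotation_deg,
        rows=rows,
        boundary_offset_um=boundary_offset_um,
        pixel_size_um=pixel_size_um,
    )


def register_device(
    sequence: ImageSequence,
    boundary_offset_um: float = DEFAULT_BOUNDARY_OFFSET_UM,
    radius_range_px: tuple[int, int] = DEFAULT_RADIUS_RANGE_PX,
    sensitivity: float = 0.6,
) -> tuple[ImageSequence, DeviceGeometry]:
    """Full registration: detect pillars in frame 1, rotate the stack level,
    re-detect on the rotated frame, and build the geometry."""
    first = sequence.frame(0, "transmitted")
    pillars = detect_pillars(first, radius_range_px, sensitivity)
    angle = estimate_rotation(pillars)
    rotated = rotate_sequence(sequence, angle)
    pillars_rot = detect_pillars(rotated.frame(0, "transmitted"), radius_range_px, sensitivity)
    geometry = build_geometry(
        pillars_rot,
        boundary_offset_um=boundary_offset_um,
        pixel_size_um=sequence.pixel_size_um,
        rotation_deg=angle,
    )
    return rotated, geometry
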