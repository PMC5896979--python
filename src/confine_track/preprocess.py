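"""Fluorescence denoising and stage-drift stabilization.

Smoothing uses a Gaussian kernel (sigma 2.5 px, support ~10 px) on the
fluorescence channels only; reported object intensities are always measured
on the raw channels so that ratios are not blur-dependent.

Drift is estimated on the transmitted-light channel by normalized 2-D
cross-correlation between each frame and its predecessor (integer-pixel
offsets), accumulated into a per-frame trace relative to frame 1, and the
same translation is applied to every channel of a frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template

from .sequence import ImageSequence

GAUSSIAN_SIGMA_PX = 2.5  # support truncated to ~10 px (radius 5)
DEFAULT_MAX_DRIFT_PX = 20


@dataclass
class DriftTrace:
    """Per-frame integer (dx, dy) offsets relative to frame 1."""

    offsets: np.ndarray  # shape (T, 2), columns dx, dy

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must have shape (T, 2)")
        if tuple(self.offsets[0]) != (0, 0):
            raise ValueError("frame 1 offset must be (0, 0)")

    def __len__(self) -> int:
        return len(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.offsets)),
                "dx_px": self.offsets[:, 0],
                "dy_px": self.offsets[:, 1],
            }
        )


def smooth_fluorescence(frame: np.ndarray, sigma: float = GAUSSIAN_SIGMA_PX) -> np.ndarray:
    """Gaussian-smooth one fluorescence frame (reflective borders)."""
    return ndimage.gaussian_filter(
        np.asarray(frame, dtype=float), sigma=sigma, radius=5, mode="nearest"
    )


def estimate_shift(
    frame: np.ndarray,
    reference: np.ndarray,
    max_drift_px: int = DEFAULT_MAX_DRIFT_PX,
) -> tuple[int, int]:
    """Integer-pixel (dx, dy) such that ``frame`` is ``reference`` shifted by (dx, dy).

    The central region of ``frame`` (inset by ``max_drift_px``) is matched
    against ``reference`` by normalized cross-correlation; the correlation
    peak gives the offset. A flat (zero-variance) input cannot be matched and
    yields (0, 0) with a warning.
    """
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frame and reference must share a shape")
    d = int(max_drift_px)
    if a.shape[0] <= 2 * d + 1 or a.shape[1] <= 2 * d + 1:
        raise ValueError("image too small for the requested max drift")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("flat image: drift assumed (0, 0)", stacklevel=2)
        return (0, 0)
    template = a[d:-d, d:-d]
    if np.ptp(template) == 0:
        warnings.warn("featureless central region: drift assumed (0, 0)", stacklevel=2)
        return (0, 0)
    ncc = match_template(b, template)  # shape (2d+1, 2d+1)
    peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    dy = d - int(peak[0])
    dx = d - int(peak[1])
    return (dx, dy)


def estimate_drift(
    sequence: ImageSequence,
    channel: str = "transmitted",
    max_drift_px: int = DEFAULT_MAX_DRIFT_PX,
) -> DriftTrace:
    """Chain frame-to-predecessor shift estimates into offsets relative to frame 1.

    Per-step estimates larger than ``max_drift_px`` in either axis are clamped
    with a warning.
    """
    frames = sequence.channel(channel)
    offsets = np.zeros((sequence.n_frames, 2), dtype=int)
    for t in range(1, sequence.n_frames):
        dx, dy = estimate_shift(frames[t], frames[t - 1], max_drift_px=max_drift_px)
        if abs(dx) > max_drift_px or abs(dy) > max_drift_px:
            warnings.warn(
                f"frame {t}: estimated drift ({dx}, {dy}) exceeds {max_drift_px} px; clamped",
                stacklevel=2,
            )
            dx = int(np.clip(dx, -max_drift_px, max_drift_px))
            dy = int(np.clip(dy, -max_drift_px, max_drift_px))
        offsets[t] = offsets[t - 1] + (dx, dy)
    return DriftTrace(offsets)


def _translate(frame: np.ndarray, dx: int, dy: int, cval: float) -> np.ndarray:
    out = np.full_like(frame, cval, dtype=float)
    h, w = frame.shape
    ys_src = slice(max(0, dy), min(h, h + dy))
    ys_dst = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, dx), min(w, w + dx))
    xs_dst = slice(max(0, -dx), min(w, w - dx))
    out[ys_dst, xs_dst] = frame[ys_src, xs_src]
    return out


def stabilize(sequence: ImageSequence, drift: DriftTrace) -> ImageSequence:
    """Undo the drift: translate every channel of frame t by -(dx_t, dy_t).

    All channels of a frame receive the identical integer translation;
    vacated borders are filled with the per-channel median.
    """
    if len(drift) != sequence.n_frames:
        raise ValueError("drift trace length must equal the frame count")
    out = np.empty_like(sequence.frames, dtype=float)
    medians = [float(np.median(sequence.frames[:, c])) for c in range(sequence.frames.shape[1])]
    for t in range(sequence.n_frames):
        dx, dy = (int(v) for v in drift.offsets[t])
        for c in range(sequence.frames.shape[1]):
            if dx == 0 and dy == 0:
                out[t, c] = sequence.frames[t, c]
            else:
                out[t, c] = _translate(sequence.frames[t, c], dx, dy, medians[c])
    return sequence.with_frames(out)
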