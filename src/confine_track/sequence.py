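"""Calibrated multi-channel time-lapse container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: Default channel order: transmitted light, chromatin marker, nucleoplasmic reporter.
DEFAULT_CHANNELS = ("transmitted", "nuclear_marker", "reporter")


@dataclass
class ImageSequence:
    """A T x C x H x W time-lapse stack with physical calibration.

    Parameters
    ----------
    frames
        Array of shape (T, C, H, W). Channel order follows ``channel_names``.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    frame_interval_min
        Time between consecutive frames in minutes.
    channel_names
        One name per channel; must include the channels an analysis needs
        (``transmitted``, ``nuclear_marker``, ``reporter``).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    channel_names: tuple[str, ...] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be 4-D (T, C, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if self.frames.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.frames.shape[1]} channels in array but "
                f"{len(self.channel_names)} channel names"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        self.channel_names = tuple(self.channel_names)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in sequence (has {list(self.channel_names)})"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """All frames of one channel, shape (T, H, W)."""
        return self.frames[:, self.channel_index(name)]

    def frame(self, t: int, name: str) -> np.ndarray:
        return self.frames[t, self.channel_index(name)]

    def with_frames(self, frames: np.ndarray) -> "ImageSequence":
        return replace(self, frames=np.asarray(frames))


def read_sequence(
    path,
    channel_map: dict[str, int] | None = None,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
) -> ImageSequence:
    """Read a multi-page TIFF / OME-TIFF into an :class:`ImageSequence`.

    Axis order is resolved from OME/series metadata when available; a plain
    4-D stack is assumed to be TCYX. ``channel_map`` maps canonical channel
    names (``transmitted``, ``nuclear_marker``, ``reporter``) to channel
    indices in the file; by default channels are taken in file order with the
    canonical names. Calibration is taken from OME metadata when present,
    otherwise from the explicit arguments.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "TCYX", "CTYX", "TYX"
        meta_px, meta_dt = _ome_calibration(tf)

    data, axes = _to_tcyx(data, axes)

    px = pixel_size_um if pixel_size_um is not None else meta_px
    dt = frame_interval_min if frame_interval_min is not None else meta_dt
    if px is None:
        raise ValueError("pixel_size_um not in metadata; pass it explicitly")
    if dt is None:
        raise ValueError("frame_interval_min not in metadata; pass it explicitly")

    n_chan = data.shape[1]
    if channel_map is None:
        names = DEFAULT_CHANNELS[:n_chan]
    else:
        missing = [v for v in channel_map.values() if v >= n_chan]
        if missing:
            raise ValueError(f"channel_map references channel index beyond file ({missing})")
        order = sorted(channel_map.items(), key=lambda kv: kv[1])
        data = data[:, [idx for _, idx in order]]
        names = tuple(name for name, _ in order)
    return ImageSequence(data, pixel_size_um=px, frame_interval_min=dt, channel_names=names)


def write_sequence(path, sequence: ImageSequence) -> None:
    """Write an :class:`ImageSequence` as OME-TIFF with calibration metadata."""
    data = sequence.frames
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "TCYX",
            "PhysicalSizeX": sequence.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": sequence.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": sequence.frame_interval_min,
            "TimeIncrementUnit": "min",
            "Channel": {"Name": list(sequence.channel_names)},
        },
    )


def _to_tcyx(data: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    axes = axes.upper().replace("S", "C").replace("Q", "T")
    if data.ndim == 3 and axes in ("TYX", "IYX", "ZYX"):
        return data[:, None], "TCYX"
    if data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with axes {axes!r} and shape {data.shape}")
    if axes == "TCYX":
        return data, axes
    if axes == "CTYX":
        return np.swapaxes(data, 0, 1), "TCYX"
    if set(axes[:2]) <= {"T", "I", "Z"}:  # bare stack without channel metadata
        return data, "TCYX"
    if axes == "ZCYX":  # some writers use Z for time
        return data, "TCYX"
    if axes == "CZYX":
        return np.swapaxes(data, 0, 1), "TCYX"
    raise ValueError(f"ambiguous axis order {axes!r}; rewrite the file with OME axes metadata")


def _ome_calibration(tf) -> tuple[float | None, float | None]:
    px = dt = None
    try:
        import xml.etree.ElementTree as ET

        if tf.ome_metadata:
            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pixels = root.find(".//ome:Pixels", ns)
            if pixels is not None:
                if pixels.get("PhysicalSizeX"):
                    px = float(pixels.get("PhysicalSizeX"))
                if pixels.get("TimeIncrement"):
                    dt = float(pixels.get("TimeIncrement"))
    except Exception:
        pass
    return px, dt
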