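"""Image-stack container and TIFF I/O.

An :class:`ImageStack` is a time-ordered sequence of 2-D frames from one
spectral channel, plus the frame interval.  Acquisition with a beamsplitter
("split frame") projects both channels side by side onto one camera frame;
:func:`write_split_frame` / :func:`read_split_frame` handle that dialect,
with the green channel in the left half and the red in the right half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "read_stack",
    "write_split_frame",
    "read_split_frame",
]


@dataclass
class ImageStack:
    """Frames of one channel, shape ``(n_frames, rows, cols)``."""

    frames: np.ndarray
    frame_interval: float = 0.1
    channel: str = "green"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.frames.shape[0] == 0:
            raise ValueError("empty stack")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame_index * frame_interval)."""
        return np.arange(self.n_frames) * self.frame_interval

    def save(self, path) -> None:
        meta = {"frame_interval": self.frame_interval, "channel": self.channel}
        tifffile.imwrite(
            path, self.frames.astype(np.float32), description=json.dumps(meta)
        )


def read_stack(path, frame_interval: float | None = None, channel: str | None = None) -> ImageStack:
    """Read a single-channel multi-page TIFF written by :meth:`ImageStack.save`
    (or any plain stack; pass ``frame_interval`` if no metadata is embedded)."""
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = {}
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (ValueError, TypeError):
                meta = {}
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        frame_interval=frame_interval or float(meta.get("frame_interval", 0.1)),
        channel=channel or str(meta.get("channel", "green")),
    )


def write_split_frame(path, green: ImageStack, red: ImageStack) -> None:
    """Write both channels as one stack: green left half, red right half.

    A fixed channel offset (the column where the red half starts) is written
    to the TIFF description so the reader can split the frame back.
    """
    if green.frames.shape != red.frames.shape:
        raise ValueError("channel stacks must share a shape")
    combined = np.concatenate([green.frames, red.frames], axis=2)
    meta = {
        "frame_interval": green.frame_interval,
        "split_frame": True,
        "channel_offset_cols": int(green.frames.shape[2]),
    }
    tifffile.imwrite(path, combined.astype(np.float32), description=json.dumps(meta))


def read_split_frame(path) -> tuple[ImageStack, ImageStack]:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    if frames.ndim == 2:
        frames = frames[None]
    off = int(meta["channel_offset_cols"])
    dt = float(meta.get("frame_interval", 0.1))
    frames = np.asarray(frames, dtype=float)
    green = ImageStack(frames[:, :, :off], frame_interval=dt, channel="green")
    red = ImageStack(frames[:, :, off:], frame_interval=dt, channel="red")
    return green, red
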