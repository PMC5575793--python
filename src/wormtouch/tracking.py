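"""Locate the labeled neuron soma in every frame of a stack.

Animals are trapped but not immobilized, so the soma drifts by a few pixels
per frame; ROI extraction needs its position in every frame.  Tracking is
local: each frame's candidate is the brightest pixel within a search radius
of the previous position, refined to an intensity-weighted centroid over a
small disc.  Frames whose candidate does not stand out from the local
background (blinking, defocus, the soma leaving the plane) are "coasted":
the previous position is reused and the frame flagged, so the trajectory
never drifts onto noise.

Track on the calcium-independent red channel when available — its intensity
does not change with stimulation — otherwise on the green channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .stack import ImageStack

__all__ = ["Trajectory", "initialize", "track"]

CENTROID_RADIUS = 5  # px disc for the intensity-weighted refinement
RING_INNER, RING_OUTER = 6, 12  # px annulus for the local-background estimate
COAST_SIGMA = 3.0  # candidate must exceed background mean + 3 SD


@dataclass
class Trajectory:
    """Per-frame neuron position with a tracking-confidence flag.

    ``locked`` frames were located in that frame; ``coasted`` frames copy
    the last locked position.
    """

    positions: np.ndarray  # (n_frames, 2) of (row, col)
    locked: np.ndarray  # bool per frame
    source_channel: str = "red"
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.locked = np.asarray(self.locked, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if len(self.locked) != len(self.positions):
            raise ValueError("one confidence flag per frame required")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def confidence(self) -> np.ndarray:
        return np.where(self.locked, "locked", "coasted")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": np.arange(self.n_frames) * self.frame_interval,
                "row": self.positions[:, 0],
                "col": self.positions[:, 1],
                "confidence": self.confidence,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source_channel: str = "red") -> "Trajectory":
        df = pd.read_csv(path)
        dt = 0.1
        if len(df) > 1:
            dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
        return cls(
            positions=df[["row", "col"]].to_numpy(float),
            locked=(df["confidence"] == "locked").to_numpy(),
            source_channel=source_channel,
            frame_interval=dt,
        )


def _frames_of(stack) -> np.ndarray:
    if isinstance(stack, ImageStack):
        return stack.frames
    frames = np.asarray(stack, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a (n_frames, rows, cols) stack")
    if frames.shape[0] == 0:
        raise ValueError("empty stack")
    return frames


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return rr * rr + cc * cc <= radius * radius


def _weighted_centroid(frame, peak_rc, background) -> tuple[np.ndarray, float]:
    """Centroid of background-subtracted intensity over a small disc around
    the peak pixel; returns (position, total weight)."""
    r0, c0 = peak_rc
    rows, cols = frame.shape
    rlo, rhi = max(0, r0 - CENTROID_RADIUS), min(rows, r0 + CENTROID_RADIUS + 1)
    clo, chi = max(0, c0 - CENTROID_RADIUS), min(cols, c0 + CENTROID_RADIUS + 1)
    patch = frame[rlo:rhi, clo:chi]
    pr = np.arange(rlo, rhi)[:, None] - r0
    pc = np.arange(clo, chi)[None, :] - c0
    disc = pr * pr + pc * pc <= CENTROID_RADIUS**2
    w = np.clip(patch - background, 0.0, None) * disc
    total = float(w.sum())
    if total <= 0:
        return np.array([float(r0), float(c0)]), 0.0
    r = float((w * np.arange(rlo, rhi)[:, None]).sum() / total)
    c = float((w * np.arange(clo, chi)[None, :]).sum() / total)
    return np.array([r, c]), total


def _ring_stats(frame, center) -> tuple[float, float]:
    """Mean and SD of the annulus around ``center`` used as the local
    background reference."""
    rows, cols = frame.shape
    r0, c0 = center
    rlo, rhi = max(0, r0 - RING_OUTER), min(rows, r0 + RING_OUTER + 1)
    clo, chi = max(0, c0 - RING_OUTER), min(cols, c0 + RING_OUTER + 1)
    pr = np.arange(rlo, rhi)[:, None] - r0
    pc = np.arange(clo, chi)[None, :] - c0
    d2 = pr * pr + pc * pc
    ring = (d2 > RING_INNER**2) & (d2 <= RING_OUTER**2)
    vals = frame[rlo:rhi, clo:chi][ring]
    if vals.size == 0:
        return float(frame.min()), 0.0
    return float(vals.mean()), float(vals.std())


def _argmax_masked(frame, mask) -> tuple[int, int]:
    """Brightest masked pixel; ties broken by smallest row, then column
    (C-order argmax is exactly that)."""
    masked = np.where(mask, frame, -np.inf)
    idx = int(np.argmax(masked))
    return idx // frame.shape[1], idx % frame.shape[1]


def initialize(frame: np.ndarray, hint: tuple[float, float] | None = None,
               hint_radius: float = 15.0) -> tuple[float, float]:
    """Seed position: intensity-weighted centroid of the brightest connected
    region of the frame (restricted to a window around ``hint`` if given).

    Raises ``ValueError`` on a flat frame, which offers no landmark.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a nonempty 2-D image")
    if hint is not None:
        mask = _disc_mask(frame.shape, hint, hint_radius)
    else:
        mask = np.ones(frame.shape, dtype=bool)
    sub = frame[mask]
    lo, hi = float(sub.min()), float(sub.max())
    if hi == lo:
        raise ValueError("flat frame: no landmark to initialize on")
    peak = _argmax_masked(frame, mask)
    # connected region above half the peak prominence, containing the peak
    thresh = lo + 0.5 * (hi - lo)
    labels = measure.label(np.where(mask, frame, lo) >= thresh)
    region = labels == labels[peak]
    w = np.clip(frame - lo, 0.0, None) * region
    total = w.sum()
    r = float((w.sum(axis=1) * np.arange(frame.shape[0])).sum() / total)
    c = float((w.sum(axis=0) * np.arange(frame.shape[1])).sum() / total)
    return r, c


def track(
    stack,
    start: tuple[float, float],
    search_radius: float = 15.0,
    source_channel: str | None = None,
) -> Trajectory:
    """Follow the soma through the stack from a starting position.

    Per frame: the brightest pixel within ``search_radius`` of the previous
    position is the candidate; if it exceeds the local background (annulus
    mean + 3 SD) the position is refined to the intensity-weighted centroid
    of a small disc and the frame is locked, otherwise the frame coasts on
    the previous position.  Locked displacements are capped at
    ``search_radius``.
    """
    frames = _frames_of(stack)
    n, rows, cols = frames.shape
    r0, c0 = float(start[0]), float(start[1])
    if not (0 <= r0 <= rows - 1 and 0 <= c0 <= cols - 1):
        raise ValueError("start position outside the frame")
    if search_radius < 1:
        raise ValueError("search_radius must be at least 1 pixel")

    positions = np.empty((n, 2))
    locked = np.zeros(n, dtype=bool)
    prev = np.array([r0, c0])
    for t in range(n):
        frame = frames[t]
        mask = _disc_mask(frame.shape, prev, search_radius)
        peak = _argmax_masked(frame, mask)
        bg_mean, bg_sd = _ring_stats(frame, peak)
        if frame[peak] > bg_mean + COAST_SIGMA * bg_sd:
            pos, weight = _weighted_centroid(frame, peak, bg_mean)
            if weight > 0:
                step = pos - prev
                dist = float(np.hypot(*step))
                if dist > search_radius:
                    pos = prev + step * (search_radius / dist)
                prev = np.clip(pos, [0, 0], [rows - 1, cols - 1])
                locked[t] = True
        positions[t] = prev
    dt = stack.frame_interval if isinstance(stack, ImageStack) else 0.1
    channel = source_channel or (
        stack.channel if isinstance(stack, ImageStack) else "red"
    )
    return Trajectory(
        positions=positions,
        locked=locked,
        source_channel=channel,
        frame_interval=dt,
    )
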