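"""ROI fluorescence extraction and baseline-normalized calcium traces.

Per frame, the neuron intensity is the mean of the ``top_k`` brightest
pixels of a circular ROI centered on the tracked position (default: 100
brightest pixels of a 10-pixel-radius disc), and a background intensity —
the plain mean over a disc in a neuron-free region — is subtracted from it
to absorb illumination changes.  With both channels available the ratio

    R = (I_G_roi - I_G_back) / (I_R_roi - I_R_back)

cancels motion and focus artifacts shared by the channels; with only the
green channel, F = I_G_roi - I_G_back is used instead.  Traces are then
normalized to the pre-stimulus baseline:

    R0 = mean R before the first stimulus onset,   dR/R0 = (R - R0) / R0

(and identically for F).  dR/R0 is the quantity all response metrics are
computed on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol
from .stack import ImageStack
from .tracking import Trajectory, track

__all__ = [
    "RoiSpec",
    "CalciumTrace",
    "roi_intensity",
    "background_intensity",
    "ratio_trace",
    "fluor_trace",
    "normalize",
    "auto_background_center",
    "extract_trial",
]


@dataclass(frozen=True)
class RoiSpec:
    """Signal- and background-ROI geometry.

    The signal ROI is a disc of ``radius`` pixels around the tracked
    position; its intensity statistic is the mean of the ``top_k`` brightest
    member pixels.  The background ROI is a fixed disc whose plain mean is
    subtracted.  A pixel belongs to a disc when its center lies within the
    radius of the (rounded) disc center.
    """

    radius: float = 10.0
    top_k: int = 100
    background_center: tuple[float, float] = (0.0, 0.0)
    background_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.background_radius <= 0:
            raise ValueError("ROI radii must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")


def _disc_values(frame: np.ndarray, center, radius: float) -> tuple[np.ndarray, int]:
    """In-frame pixel values of the disc (scan order) and the full disc size.

    The disc center is rounded to the nearest pixel; membership is Euclidean
    distance of pixel centers.
    """
    r0 = int(round(float(center[0])))
    c0 = int(round(float(center[1])))
    rad = int(np.floor(radius))
    rows, cols = frame.shape
    full = 0
    vals = []
    r2 = radius * radius
    for dr in range(-rad, rad + 1):
        for dc in range(-rad, rad + 1):
            if dr * dr + dc * dc <= r2:
                full += 1
                r, c = r0 + dr, c0 + dc
                if 0 <= r < rows and 0 <= c < cols:
                    vals.append(frame[r, c])
    return np.asarray(vals, dtype=float), full


def roi_intensity(
    frame: np.ndarray, center, spec: RoiSpec, with_count: bool = False
):
    """Mean of the ``top_k`` brightest pixels of the signal disc.

    If the in-frame part of the disc holds fewer than ``top_k`` pixels, all
    available pixels are used (the caller flags the trace).  Ties at the
    cutoff do not affect the mean.  Raises if the disc lies fully outside
    the frame.
    """
    frame = np.asarray(frame, dtype=float)
    vals, _ = _disc_values(frame, center, spec.radius)
    if vals.size == 0:
        raise ValueError("ROI disc lies fully outside the frame")
    k = min(spec.top_k, vals.size)
    top = np.partition(vals, vals.size - k)[vals.size - k:]
    value = float(top.mean())
    if with_count:
        return value, int(vals.size)
    return value


def background_intensity(
    frame: np.ndarray, spec: RoiSpec, signal_center=None
) -> float:
    """Plain mean over the background disc (all pixels, not top-k).

    If ``signal_center`` is given, raises when the background disc overlaps
    the signal ROI.
    """
    frame = np.asarray(frame, dtype=float)
    if signal_center is not None:
        d = float(
            np.hypot(
                signal_center[0] - spec.background_center[0],
                signal_center[1] - spec.background_center[1],
            )
        )
        if d < spec.radius + spec.background_radius:
            raise ValueError("background ROI overlaps the signal ROI")
    vals, full = _disc_values(frame, spec.background_center, spec.background_radius)
    if vals.size < full:
        raise ValueError("background ROI extends outside the frame")
    return float(vals.mean())


@dataclass
class CalciumTrace:
    """Per-frame intensities, ratio/fluorescence and normalized trace.

    ``valid`` marks frames usable for metrics (ratio denominator positive).
    ``baseline`` and ``dRR`` are filled by :func:`normalize`.
    """

    time: np.ndarray
    I_G_roi: np.ndarray
    I_G_back: np.ndarray
    R_or_F: np.ndarray
    valid: np.ndarray
    mode: str  # "ratiometric" | "single_channel"
    I_R_roi: np.ndarray | None = None
    I_R_back: np.ndarray | None = None
    protocol: StimulusProtocol | None = None
    baseline: float | None = None
    dRR: np.ndarray | None = None
    roi_clipped: bool = False

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("I_G_roi", "I_G_back", "R_or_F", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError("all trace series must share a length")
        if self.mode not in ("ratiometric", "single_channel"):
            raise ValueError("mode must be 'ratiometric' or 'single_channel'")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def interpolated_dRR(self) -> np.ndarray:
        """dRR with invalid frames linearly interpolated (for plotting only;
        metrics use valid frames)."""
        if self.dRR is None:
            raise ValueError("trace is not normalized")
        out = self.dRR.copy()
        bad = ~self.valid
        if bad.any() and (~bad).any():
            out[bad] = np.interp(
                self.time[bad], self.time[~bad], self.dRR[~bad]
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        n = self.n_frames
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_s": self.time,
                "I_G_roi": self.I_G_roi,
                "I_G_back": self.I_G_back,
                "I_R_roi": self.I_R_roi if self.I_R_roi is not None else np.nan,
                "I_R_back": self.I_R_back if self.I_R_back is not None else np.nan,
                "R_or_F": self.R_or_F,
                "dRR": self.dRR if self.dRR is not None else np.nan,
                "valid_flag": self.valid.astype(int),
            }
        )

    def to_csv(self, path, metadata_path=None, spec: RoiSpec | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if metadata_path is not None:
            meta = {
                "mode": self.mode,
                "baseline": self.baseline,
                "roi_clipped": self.roi_clipped,
                "protocol": self.protocol.to_dict() if self.protocol else None,
            }
            if spec is not None:
                meta["roi"] = {
                    "radius": spec.radius,
                    "top_k": spec.top_k,
                    "background_center": list(spec.background_center),
                    "background_radius": spec.background_radius,
                }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path, protocol: StimulusProtocol | None = None) -> "CalciumTrace":
        df = pd.read_csv(path)
        has_red = not df["I_R_roi"].isna().all()
        dRR = df["dRR"].to_numpy(float)
        return cls(
            time=df["time_s"].to_numpy(float),
            I_G_roi=df["I_G_roi"].to_numpy(float),
            I_G_back=df["I_G_back"].to_numpy(float),
            I_R_roi=df["I_R_roi"].to_numpy(float) if has_red else None,
            I_R_back=df["I_R_back"].to_numpy(float) if has_red else None,
            R_or_F=df["R_or_F"].to_numpy(float),
            valid=df["valid_flag"].to_numpy(bool),
            mode="ratiometric" if has_red else "single_channel",
            protocol=protocol,
            dRR=None if np.isnan(dRR).all() else dRR,
        )


def _series(stack, traj: Trajectory, spec: RoiSpec):
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack, float)
    if frames.shape[0] != traj.n_frames:
        raise ValueError("stack and trajectory lengths differ")
    n = frames.shape[0]
    roi = np.empty(n)
    back = np.empty(n)
    clipped = False
    for t in range(n):
        roi[t], count = roi_intensity(
            frames[t], traj.positions[t], spec, with_count=True
        )
        if count < spec.top_k:
            clipped = True
        back[t] = background_intensity(
            frames[t], spec, signal_center=traj.positions[t]
        )
    return roi, back, clipped


def ratio_trace(
    traj: Trajectory,
    green,
    red,
    spec: RoiSpec,
    protocol: StimulusProtocol | None = None,
    subtract_background_red: bool = True,
) -> CalciumTrace:
    """Ratiometric trace R = (I_G_roi - I_G_back) / (I_R_roi - I_R_back).

    Frames whose red denominator is not positive are flagged invalid and
    excluded from metric computation.  ``subtract_background_red=False``
    selects the dialect that divides by the raw red ROI intensity instead.
    """
    g = green.frames if isinstance(green, ImageStack) else np.asarray(green, float)
    r = red.frames if isinstance(red, ImageStack) else np.asarray(red, float)
    if g.shape[0] != r.shape[0]:
        raise ValueError("green and red stacks must have equal length")
    gr, gb, gclip = _series(green, traj, spec)
    rr, rb, rclip = _series(red, traj, spec)
    denom = rr - rb if subtract_background_red else rr
    valid = denom > 0
    R = np.full(len(gr), np.nan)
    R[valid] = (gr[valid] - gb[valid]) / denom[valid]
    dt = green.frame_interval if isinstance(green, ImageStack) else 0.1
    return CalciumTrace(
        time=np.arange(len(gr)) * dt,
        I_G_roi=gr,
        I_G_back=gb,
        I_R_roi=rr,
        I_R_back=rb,
        R_or_F=R,
        valid=valid,
        mode="ratiometric",
        protocol=protocol,
        roi_clipped=gclip or rclip,
    )


def fluor_trace(
    traj: Trajectory,
    green,
    spec: RoiSpec,
    protocol: StimulusProtocol | None = None,
) -> CalciumTrace:
    """Single-channel trace F = I_G_roi - I_G_back (no red reference)."""
    gr, gb, clipped = _series(green, traj, spec)
    dt = green.frame_interval if isinstance(green, ImageStack) else 0.1
    return CalciumTrace(
        time=np.arange(len(gr)) * dt,
        I_G_roi=gr,
        I_G_back=gb,
        R_or_F=gr - gb,
        valid=np.ones(len(gr), dtype=bool),
        mode="single_channel",
        protocol=protocol,
        roi_clipped=clipped,
    )


def normalize(
    trace: CalciumTrace, protocol: StimulusProtocol | None = None
) -> CalciumTrace:
    """Baseline-normalize: R0 = mean R over the valid frames before the first
    stimulus onset; dR/R0 = (R - R0)/R0.

    Requires at least 5 valid pre-stimulus frames; in ratiometric mode the
    baseline must be positive.
    """
    protocol = protocol or trace.protocol
    if protocol is None:
        raise ValueError("a stimulus protocol is required to normalize")
    pre = (trace.time < protocol.onsets[0]) & trace.valid
    if pre.sum() < 5:
        raise ValueError("need at least 5 valid pre-stimulus frames")
    baseline = float(trace.R_or_F[pre].mean())
    if trace.mode == "ratiometric" and baseline <= 0:
        raise ValueError("ratiometric baseline must be positive")
    if baseline == 0:
        raise ValueError("baseline is zero; dF/F0 undefined")
    dRR = (trace.R_or_F - baseline) / baseline
    return replace(trace, baseline=baseline, dRR=dRR, protocol=protocol)


def auto_background_center(
    frame: np.ndarray,
    spec_radius: float = 10.0,
    signal_radius: float = 10.0,
    exclusion: float = 20.0,
) -> tuple[float, float]:
    """Default background-ROI placement from the first frame: the disc
    center with the lowest local mean intensity whose disc stays inside the
    frame and clear of the brightest spot (the soma) by at least
    ``signal_radius + spec_radius + exclusion`` pixels."""
    from scipy.ndimage import uniform_filter

    frame = np.asarray(frame, dtype=float)
    rows, cols = frame.shape
    size = 2 * int(spec_radius) + 1
    local_mean = uniform_filter(frame, size=size, mode="nearest")
    peak = np.unravel_index(np.argmax(frame), frame.shape)
    rr = np.arange(rows)[:, None] - peak[0]
    cc = np.arange(cols)[None, :] - peak[1]
    min_dist = signal_radius + spec_radius + exclusion
    rad = int(np.ceil(spec_radius))
    forbidden = rr * rr + cc * cc < min_dist * min_dist
    forbidden[:rad, :] = forbidden[-rad:, :] = True
    forbidden[:, :rad] = forbidden[:, -rad:] = True
    if forbidden.all():
        raise ValueError("frame too small to place a background ROI")
    masked = np.where(forbidden, np.inf, local_mean)
    r, c = np.unravel_index(np.argmin(masked), masked.shape)
    return float(r), float(c)


def extract_trial(
    green: ImageStack,
    red: ImageStack | None,
    protocol: StimulusProtocol,
    spec: RoiSpec | None = None,
    start: tuple[float, float] | None = None,
    search_radius: float = 15.0,
) -> tuple[CalciumTrace, Trajectory]:
    """Full per-trial chain: track (red channel when available), place the
    background ROI, extract the ratio (or single-channel) trace, normalize.
    """
    from .tracking import initialize

    track_stack = red if red is not None else green
    if start is None:
        start = initialize(track_stack.frames[0])
    traj = track(track_stack, start, search_radius=search_radius)
    if spec is None:
        r, c = auto_background_center(track_stack.frames[0])
        spec = RoiSpec(background_center=(r, c))
    if red is not None:
        trace = ratio_trace(traj, green, red, spec, protocol=protocol)
    else:
        trace = fluor_trace(traj, green, spec, protocol=protocol)
    return normalize(trace), traj
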