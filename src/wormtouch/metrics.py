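"""Per-trial response metrics and ensemble summaries.

Three nonparametric quantities describe one stimulus-evoked transient:

* **max dR/R0** — the maximum of the normalized trace over the response
  window ``[onset, next onset or end of recording)``;
* **delay time** — time from the *end* of the stimulus to the arrival of
  the maximum (negative, and flagged, if the peak arrives during the
  stimulus);
* **half-life** — time after the peak for the trace to decay to half of
  the maximum, linearly interpolated between frames and undefined when the
  recording ends before the crossing.

A trial is a *responder* when its max dR/R0 strictly exceeds a threshold
(0.5 by convention), and the response fraction of an ensemble is the
proportion of responders.  Grid summaries tabulate mean peak and response
fraction over (pressure, duration) cells; habituation series list the
per-stimulus peaks of a repeated-stimulus trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol
from .traces import CalciumTrace

__all__ = [
    "ResponseMetrics",
    "GridSummary",
    "HabituationSeries",
    "RESPONDER_THRESHOLD",
    "peak_response",
    "delay_time",
    "half_life",
    "classify_responder",
    "response_fraction",
    "summarize_grid",
    "habituation_series",
    "trial_metrics",
    "ensemble_mean_sem",
]

RESPONDER_THRESHOLD = 0.5


@dataclass(frozen=True)
class ResponseMetrics:
    """Metrics of one stimulus in one trial."""

    stimulus_index: int
    max_dRR: float
    t_peak: float
    delay_time: float
    peak_during_stimulus: bool
    half_life: float | None
    responder: bool

    def to_dict(self) -> dict:
        return {
            "stimulus_index": self.stimulus_index,
            "max_dRR": self.max_dRR,
            "t_peak": self.t_peak,
            "delay_time": self.delay_time,
            "peak_during_stimulus": self.peak_during_stimulus,
            "half_life": np.nan if self.half_life is None else self.half_life,
            "responder": self.responder,
        }


def _window_mask(trace: CalciumTrace, protocol: StimulusProtocol, index: int):
    start, end = protocol.stimulus_window(index)
    return (trace.time >= start) & (trace.time < end) & trace.valid


def peak_response(
    trace: CalciumTrace, stimulus_index: int = 0
) -> tuple[float, float]:
    """Maximum dR/R0 over the stimulus window and its time.

    The window runs from the stimulus onset to the next onset (or the end of
    the recording); ties are broken by the earliest time.  Raises when the
    trace is not normalized or the window holds no valid frame.
    """
    if trace.dRR is None:
        raise ValueError("trace must be normalized first")
    if trace.protocol is None:
        raise ValueError("trace carries no stimulus protocol")
    mask = _window_mask(trace, trace.protocol, stimulus_index)
    if not mask.any():
        raise ValueError(f"empty response window for stimulus {stimulus_index}")
    vals = trace.dRR[mask]
    times = trace.time[mask]
    i = int(np.argmax(vals))  # argmax returns the first (earliest) maximum
    return float(vals[i]), float(times[i])


def delay_time(
    t_peak: float, protocol: StimulusProtocol, stimulus_index: int = 0
) -> tuple[float, bool]:
    """Time from stimulus end to the peak: ``t_peak - (onset + duration)``.

    Reported as-is; the boolean flags a negative delay (peak during the
    stimulus).
    """
    d = float(t_peak - protocol.stimulus_end(stimulus_index))
    return d, d < 0


def half_life(
    trace: CalciumTrace, t_peak: float, max_dRR: float
) -> float | None:
    """Decay half-life: first time after the peak at which dR/R0 falls to
    half the maximum, linearly interpolated between the bracketing frames,
    minus the peak time.

    Returns ``None`` when the maximum is not positive or the trace never
    crosses half-maximum before the recording ends.
    """
    if max_dRR <= 0:
        return None
    if trace.dRR is None:
        raise ValueError("trace must be normalized first")
    half = max_dRR / 2.0
    after = (trace.time > t_peak) & trace.valid
    times = trace.time[after]
    vals = trace.dRR[after]
    below = np.nonzero(vals <= half)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        # crossed within the first frame after the peak; interpolate from the peak
        t_prev, v_prev = t_peak, max_dRR
    else:
        t_prev, v_prev = times[i - 1], vals[i - 1]
    t_cross = times[i]
    if vals[i] < v_prev:  # linear interpolation to the exact crossing
        frac = (v_prev - half) / (v_prev - vals[i])
        t_cross = t_prev + frac * (times[i] - t_prev)
    return float(t_cross - t_peak)


def classify_responder(
    max_dRR: float, threshold: float = RESPONDER_THRESHOLD
) -> bool:
    """Responder iff the peak strictly exceeds the threshold."""
    return bool(max_dRR > threshold)


def response_fraction(
    peaks, threshold: float = RESPONDER_THRESHOLD
) -> float:
    """Fraction of trials whose peak strictly exceeds the threshold."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("response_fraction of an empty trial list")
    return float((peaks > threshold).sum() / peaks.size)


def trial_metrics(
    trace: CalciumTrace,
    stimulus_index: int = 0,
    threshold: float = RESPONDER_THRESHOLD,
) -> ResponseMetrics:
    """All per-stimulus metrics of one normalized trace."""
    if trace.protocol is None:
        raise ValueError("trace carries no stimulus protocol")
    peak, t_peak = peak_response(trace, stimulus_index)
    delay, during = delay_time(t_peak, trace.protocol, stimulus_index)
    hl = half_life(trace, t_peak, peak)
    return ResponseMetrics(
        stimulus_index=stimulus_index,
        max_dRR=peak,
        t_peak=t_peak,
        delay_time=delay,
        peak_during_stimulus=during,
        half_life=hl,
        responder=classify_responder(peak, threshold),
    )


@dataclass
class GridSummary:
    """Mean peak / response fraction / n per (pressure, duration) cell.

    ``table`` has one row per tested cell; untested cells are simply absent
    (callers render them as untested).  ``median_peak`` is reported next to
    the mean because the per-cell statistic convention varies.
    """

    table: pd.DataFrame

    @property
    def pressures(self) -> np.ndarray:
        return np.sort(self.table["pressure"].unique())

    @property
    def durations(self) -> np.ndarray:
        return np.sort(self.table["duration"].unique())

    def matrix(self, column: str) -> pd.DataFrame:
        """Pivot a summary column to a duration x pressure matrix; untested
        cells are NaN."""
        return self.table.pivot(index="duration", columns="pressure", values=column)


def summarize_grid(
    trials, threshold: float = RESPONDER_THRESHOLD
) -> GridSummary:
    """Summarize (pressure, duration, max_dRR) trials per stimulus cell.

    ``trials`` is an iterable of (pressure, duration, max_dRR) triples or a
    DataFrame with those columns.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials[["pressure", "duration", "max_dRR"]].copy()
    else:
        df = pd.DataFrame(trials, columns=["pressure", "duration", "max_dRR"])
    if df.empty:
        raise ValueError("no trials to summarize")
    rows = []
    for (p, d), grp in df.groupby(["pressure", "duration"], sort=True):
        peaks = grp["max_dRR"].to_numpy(float)
        rows.append(
            {
                "pressure": p,
                "duration": d,
                "mean_peak": float(peaks.mean()),
                "median_peak": float(np.median(peaks)),
                "response_fraction": response_fraction(peaks, threshold),
                "n": int(peaks.size),
            }
        )
    return GridSummary(table=pd.DataFrame(rows))


@dataclass
class HabituationSeries:
    """Per-stimulus peaks of one repeated-stimulus trial."""

    per_stimulus_peaks: np.ndarray
    isi: float
    n_stimuli: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_index": np.arange(self.n_stimuli),
                "max_dRR": self.per_stimulus_peaks,
                "isi": self.isi,
            }
        )


def habituation_series(trace: CalciumTrace) -> HabituationSeries:
    """Peak dR/R0 of every stimulus of a repeated-stimulus trial, computed
    on the inter-onset windows.  Requires at least two stimuli."""
    protocol = trace.protocol
    if protocol is None:
        raise ValueError("trace carries no stimulus protocol")
    if protocol.n_stimuli < 2:
        raise ValueError("habituation analysis needs at least 2 stimuli")
    peaks = np.array(
        [peak_response(trace, i)[0] for i in range(protocol.n_stimuli)]
    )
    isi = protocol.onsets[1] - protocol.stimulus_end(0)
    return HabituationSeries(
        per_stimulus_peaks=peaks, isi=float(isi), n_stimuli=protocol.n_stimuli
    )


def ensemble_mean_sem(traces) -> pd.DataFrame:
    """Frame-wise mean +/- SEM of dR/R0 over trials sharing a protocol and
    frame grid (trials are aligned on their common stimulus onsets)."""
    mats = []
    time = None
    for tr in traces:
        if tr.dRR is None:
            raise ValueError("all traces must be normalized")
        if time is None:
            time = tr.time
        elif len(tr.time) != len(time):
            raise ValueError("traces must share a frame grid")
        d = tr.dRR.copy()
        d[~tr.valid] = np.nan
        mats.append(d)
    if not mats:
        raise ValueError("no traces given")
    m = np.vstack(mats)
    n = np.sum(~np.isnan(m), axis=0)
    mean = np.nanmean(m, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = np.nanstd(m, axis=0, ddof=1) / np.sqrt(n)
    return pd.DataFrame({"time_s": time, "mean_dRR": mean, "sem_dRR": sem, "n": n})
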