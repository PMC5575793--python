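"""Stimulus protocol description.

A trial is a timed sequence of pressure pulses delivered to a trapped
animal while a two-channel fluorescence video is recorded.  The protocol
records when each pulse starts, how long it lasts and at which nominal
actuation pressure, plus the length of the pre-stimulus baseline window
and of the whole recording.  Times are in seconds from the first frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["StimulusProtocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Onsets, durations and nominal pressures of the stimuli in one trial.

    Parameters
    ----------
    onsets:
        Stimulus onset times in seconds, strictly increasing.
    durations:
        Stimulus durations in seconds, paired with ``onsets``.
    pressures:
        Nominal actuation pressures in psi, paired with ``onsets``.
    baseline_window:
        Length of the pre-stimulus baseline period in seconds.  Must not
        exceed the first onset.
    record_duration:
        Total recording length in seconds.
    """

    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    pressures: tuple[float, ...]
    baseline_window: float = 10.0
    record_duration: float = 60.0

    def __init__(
        self,
        onsets: Sequence[float],
        durations: Sequence[float],
        pressures: Sequence[float],
        baseline_window: float = 10.0,
        record_duration: float = 60.0,
    ) -> None:
        object.__setattr__(self, "onsets", tuple(float(x) for x in onsets))
        object.__setattr__(self, "durations", tuple(float(x) for x in durations))
        object.__setattr__(self, "pressures", tuple(float(x) for x in pressures))
        object.__setattr__(self, "baseline_window", float(baseline_window))
        object.__setattr__(self, "record_duration", float(record_duration))
        self._validate()

    def _validate(self) -> None:
        n = len(self.onsets)
        if n == 0:
            raise ValueError("protocol needs at least one stimulus")
        if not (len(self.durations) == len(self.pressures) == n):
            raise ValueError("onsets, durations and pressures must have equal length")
        if any(d <= 0 for d in self.durations):
            raise ValueError("durations must be positive")
        if any(p < 0 for p in self.pressures):
            raise ValueError("pressures must be nonnegative")
        if any(b >= a for a, b in zip(self.onsets[1:], self.onsets[:-1])):
            raise ValueError("onsets must be strictly increasing")
        if self.baseline_window <= 0:
            raise ValueError("baseline_window must be positive")
        if self.baseline_window > self.onsets[0]:
            raise ValueError("baseline_window cannot extend past the first onset")
        if self.record_duration < self.onsets[-1] + self.durations[-1]:
            raise ValueError("record_duration must cover the last stimulus")

    @property
    def n_stimuli(self) -> int:
        return len(self.onsets)

    def stimulus_window(self, index: int) -> tuple[float, float]:
        """Response-search window for stimulus ``index``.

        The window runs from the stimulus onset to the next onset, or to
        the end of the recording for the last stimulus.  Using inter-onset
        windows keeps repeated-stimulus (habituation) analysis well defined.
        """
        if not 0 <= index < self.n_stimuli:
            raise IndexError(f"stimulus index {index} out of range")
        start = self.onsets[index]
        end = (
            self.onsets[index + 1]
            if index + 1 < self.n_stimuli
            else self.record_duration
        )
        return start, end

    def stimulus_end(self, index: int) -> float:
        return self.onsets[index] + self.durations[index]

    def n_frames(self, frame_interval: float) -> int:
        if frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        return int(np.ceil(self.record_duration / frame_interval))

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "onsets": list(self.onsets),
            "durations": list(self.durations),
            "pressures": list(self.pressures),
            "baseline_window": self.baseline_window,
            "record_duration": self.record_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            onsets=d["onsets"],
            durations=d["durations"],
            pressures=d["pressures"],
            baseline_window=d.get("baseline_window", 10.0),
            record_duration=d["record_duration"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def single_pulse(
        cls,
        pressure: float = 40.0,
        duration: float = 1.0,
        baseline_window: float = 10.0,
        record_duration: float = 60.0,
    ) -> "StimulusProtocol":
        """One pulse delivered after the baseline window (the common trial)."""
        return cls(
            onsets=[baseline_window],
            durations=[duration],
            pressures=[pressure],
            baseline_window=baseline_window,
            record_duration=record_duration,
        )

    @classmethod
    def pulse_train(
        cls,
        n_stimuli: int,
        isi: float,
        pressure: float = 40.0,
        duration: float = 1.0,
        baseline_window: float = 10.0,
        tail: float = 20.0,
    ) -> "StimulusProtocol":
        """Repeated identical pulses separated by ``isi`` seconds (offset to
        next onset), as used in habituation experiments."""
        if n_stimuli < 1:
            raise ValueError("need at least one stimulus")
        onsets = [baseline_window + i * (duration + isi) for i in range(n_stimuli)]
        return cls(
            onsets=onsets,
            durations=[duration] * n_stimuli,
            pressures=[pressure] * n_stimuli,
            baseline_window=baseline_window,
            record_duration=onsets[-1] + duration + tail,
        )
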