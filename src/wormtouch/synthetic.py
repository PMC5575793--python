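"""Synthetic two-channel calcium-imaging scenes with known ground truth.

Real trials record a moving, fluorescently labeled neuron soma through a
beamsplitter: a green calcium-sensitive channel (GCaMP) and a red
calcium-independent reference (RFP) that shares every motion, focus and
illumination artifact.  This module generates such videos from first
principles so that every downstream stage — tracking, ROI extraction,
ratiometric normalization, response metrics — can be validated against a
known answer without any microscope.

The per-frame render model is

    green(t) = g(t) * (B + b(t) * (S0 + gain * s(t)) * blob(t)) + noise
    red(t)   = g(t) * (B + b(t) * RFP * blob(t))               + noise

where ``s(t)`` is the true relative calcium trace, ``blob`` a Gaussian soma
at the (shared) neuron position, ``g(t)`` a multiplicative artifact common
to both channels, ``b(t) = exp(-bleach_rate * t)`` photobleaching applied to
the fluorophore terms only, ``B`` a constant background offset and the noise
additive Gaussian.  Because the artifact ``g`` and bleaching ``b`` multiply
both channels identically, the background-subtracted green/red ratio cancels
them exactly; with ``gain == S0`` (the defaults) the ratiometric dR/R0 of a
noiseless scene equals ``s(t)`` to machine precision.

Calcium dynamics are phenomenological: a saturating-rise x exponential-decay
kernel, a Hill curve in pressure times a saturating function of stimulus
duration for the amplitude, a logistic Bernoulli responder model in
pressure, and per-stimulus amplitude multipliers for habituation under
repeated stimulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol
from .stack import ImageStack, write_split_frame

__all__ = [
    "ResponseModel",
    "SceneConfig",
    "GroundTruth",
    "calcium_kernel",
    "simulate_amplitude",
    "responder_probability",
    "build_true_trace",
    "random_walk_path",
    "default_motion_gain",
    "render_scene",
    "simulate_trial",
    "simulate_trace",
    "write_scene",
]

# Inter-stimulus intervals at or below this (seconds) use the short-ISI
# habituation multipliers; the experimental contrast is 1 s vs 3 min.
SHORT_ISI_THRESHOLD = 30.0


@dataclass(frozen=True)
class ResponseModel:
    """Phenomenological stimulus->calcium model.

    Parameters
    ----------
    amp_max:
        Saturating peak dR/R0 amplitude (the strongest responses of gentle
        touch neurons reach ~3).
    pressure_half:
        Hill midpoint in psi: pressure at which amplitude is half of its
        duration-limited maximum.
    hill_coef:
        Hill coefficient; >1 gives the steep gentle-touch pressure dependence
        (stochastic below 30 psi, saturated above 40 psi).
    duration_sat:
        Duration saturation constant in seconds; amplitude grows like
        ``1 - exp(-duration/duration_sat)``.
    tau_rise, tau_decay:
        Kernel rise and decay time constants in seconds.  Responses rise
        within a second of stimulation and decline back to baseline over
        several seconds.
    respond_prob_slope, respond_prob_mid:
        Logistic Bernoulli responder model: the probability that a stimulus
        at pressure p elicits any response is
        ``1/(1 + exp(-slope*(p - mid)))``, reproducing response rates >90%
        above 40 psi and <20% below 30 psi.
    habituation_short_isi, habituation_long_isi:
        Per-stimulus amplitude multipliers under repeated stimulation.
        Short intervals facilitate up to the second stimulus then depress;
        long intervals depress monotonically.
    """

    amp_max: float = 3.0
    pressure_half: float = 30.0
    hill_coef: float = 4.0
    duration_sat: float = 2.0
    tau_rise: float = 0.5
    tau_decay: float = 4.0
    respond_prob_slope: float = 0.5
    respond_prob_mid: float = 30.0
    habituation_short_isi: tuple[float, ...] = (1.0, 1.3, 0.8, 0.5)
    habituation_long_isi: tuple[float, ...] = (1.0, 0.7, 0.5, 0.35)

    def __post_init__(self) -> None:
        if self.amp_max < 0:
            raise ValueError("amp_max must be nonnegative")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.duration_sat <= 0:
            raise ValueError("duration_sat must be positive")
        if any(m < 0 for m in self.habituation_short_isi + self.habituation_long_isi):
            raise ValueError("habituation multipliers must be nonnegative")

    def with_(self, **kwargs) -> "ResponseModel":
        """Return a copy with some parameters replaced."""
        return replace(self, **kwargs)


def calcium_kernel(
    t_rel, duration: float, model: ResponseModel
) -> np.ndarray | float:
    """Unit-peak response kernel as a function of time since stimulus onset.

    Zero before onset; rises with time constant ``tau_rise`` while the
    stimulus is on, peaks shortly after the stimulus ends (at
    ``duration + tau_rise``), then decays exponentially with ``tau_decay``.
    Continuous, bounded by 1, with peak value exactly 1 so that the kernel
    scaled by an amplitude peaks at that amplitude and falls to half of it
    ``tau_decay * ln 2`` after the peak.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(t_rel, dtype=float)
    t_peak = duration + model.tau_rise
    peak = 1.0 - np.exp(-t_peak / model.tau_rise)
    rising = (1.0 - np.exp(-np.clip(t, 0.0, None) / model.tau_rise)) / peak
    decaying = np.exp(-(t - t_peak) / model.tau_decay)
    out = np.where(t < t_peak, rising, decaying)
    out = np.where(t < 0, 0.0, out)
    return out if out.ndim else float(out)


def simulate_amplitude(
    pressure: float, duration: float, model: ResponseModel
) -> float:
    """Peak dR/R0 amplitude for a stimulus: Hill curve in pressure times a
    saturating function of duration.

    ``amp_max * p^h / (p^h + pressure_half^h) * (1 - exp(-duration/duration_sat))``
    — monotone nondecreasing in both arguments.
    """
    if pressure < 0:
        raise ValueError("pressure must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    h = model.hill_coef
    if pressure == 0:
        hill = 0.0
    else:
        # log-space ratio for numerical stability at large hill coefficients
        ratio = (model.pressure_half / pressure) ** h
        hill = 1.0 / (1.0 + ratio)
    sat = 1.0 - np.exp(-duration / model.duration_sat)
    return float(model.amp_max * hill * sat)


def responder_probability(
    pressure: float, model: ResponseModel, duration: float = 1.0
) -> float:
    """Logistic Bernoulli responder probability.

    Response rates are graded in both pressure and duration (longer stimuli
    recruit more responders), so the logistic acts on an effective pressure
    ``p * (1 - exp(-duration/duration_sat)) / (1 - exp(-1/duration_sat))``,
    normalized so a 1 s stimulus (the canonical trial) uses the nominal
    pressure.  Monotone nondecreasing in both arguments.
    """
    sat = 1.0 - np.exp(-duration / model.duration_sat)
    ref = 1.0 - np.exp(-1.0 / model.duration_sat)
    p_eff = pressure * sat / ref
    z = model.respond_prob_slope * (p_eff - model.respond_prob_mid)
    return float(1.0 / (1.0 + np.exp(-z)))


def habituation_multipliers(
    protocol: StimulusProtocol, model: ResponseModel
) -> np.ndarray:
    """Per-stimulus amplitude multipliers implied by the protocol's ISI.

    Single-stimulus protocols get multiplier 1.  Trains use the short- or
    long-ISI series depending on the offset-to-onset interval; series shorter
    than the train are extended with their last value.
    """
    n = protocol.n_stimuli
    if n == 1:
        return np.ones(1)
    isi = protocol.onsets[1] - protocol.stimulus_end(0)
    series = (
        model.habituation_short_isi
        if isi <= SHORT_ISI_THRESHOLD
        else model.habituation_long_isi
    )
    out = np.empty(n)
    for i in range(n):
        out[i] = series[i] if i < len(series) else series[-1]
    return out


def build_true_trace(
    times: np.ndarray,
    protocol: StimulusProtocol,
    model: ResponseModel,
    rng: np.random.Generator,
    amplitude_multipliers: Sequence[float] | None = None,
    force_respond: bool | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth dR/R0 trace on a time grid.

    Each stimulus independently responds with the logistic Bernoulli
    probability (or deterministically if ``force_respond`` is set); a
    responding stimulus contributes ``amplitude * kernel`` where the
    amplitude follows the pressure/duration dose-response model times the
    habituation multiplier.  Contributions of overlapping windows add.

    Returns ``(trace, responder_flags, per_stimulus_amplitudes)``.
    """
    times = np.asarray(times, dtype=float)
    mult = (
        np.asarray(amplitude_multipliers, dtype=float)
        if amplitude_multipliers is not None
        else habituation_multipliers(protocol, model)
    )
    if len(mult) != protocol.n_stimuli:
        raise ValueError("one amplitude multiplier per stimulus required")
    trace = np.zeros_like(times)
    responders = np.zeros(protocol.n_stimuli, dtype=bool)
    amps = np.zeros(protocol.n_stimuli)
    for i, (onset, dur, p) in enumerate(
        zip(protocol.onsets, protocol.durations, protocol.pressures)
    ):
        if force_respond is None:
            responds = rng.random() < responder_probability(p, model, dur)
        else:
            responds = force_respond
        responders[i] = responds
        if not responds:
            continue
        amps[i] = simulate_amplitude(p, dur, model) * mult[i]
        trace += amps[i] * calcium_kernel(times - onset, dur, model)
    return trace, responders, amps


# ---------------------------------------------------------------------------
# scene geometry and rendering


@dataclass
class SceneConfig:
    """Geometry, optics and artifact parameters of one rendered scene.

    ``gcamp_baseline`` is the calcium-independent green soma intensity and
    ``gcamp_gain`` the green intensity added per unit of true dR/R0; with
    the two equal (the default) the rendered ratio trace reproduces the
    ground-truth trace in dR/R0 units exactly in the noiseless limit.
    """

    frame_shape: tuple[int, int] = (96, 96)
    n_frames: int = 300
    frame_interval: float = 0.1  # 100 ms exposure
    neuron_path: np.ndarray | None = None  # (n_frames, 2) of (row, col)
    soma_sigma: float = 3.0
    gcamp_baseline: float = 100.0
    gcamp_gain: float = 100.0
    rfp_level: float = 150.0
    background_level: float = 100.0
    bleach_rate: float = 0.002
    motion_gain_series: np.ndarray | None = None
    noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.soma_sigma <= 0:
            raise ValueError("soma_sigma must be positive")
        if self.neuron_path is not None:
            self.neuron_path = np.asarray(self.neuron_path, dtype=float)
            if self.neuron_path.shape != (self.n_frames, 2):
                raise ValueError("neuron_path must have shape (n_frames, 2)")
            r, c = self.neuron_path[:, 0], self.neuron_path[:, 1]
            if (
                (r < 0).any()
                or (c < 0).any()
                or (r > self.frame_shape[0] - 1).any()
                or (c > self.frame_shape[1] - 1).any()
            ):
                raise ValueError("neuron_path leaves the frame")
        if self.motion_gain_series is not None:
            self.motion_gain_series = np.asarray(self.motion_gain_series, dtype=float)
            if self.motion_gain_series.shape != (self.n_frames,):
                raise ValueError("motion_gain_series must have one value per frame")
            if (self.motion_gain_series <= 0).any():
                raise ValueError("motion gains must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    true_trace: np.ndarray  # dR/R0 per frame
    true_path: np.ndarray  # (n_frames, 2)
    responder: np.ndarray  # bool per stimulus
    per_stimulus_amplitude: np.ndarray  # planted peak dR/R0 per stimulus

    def to_frame(self, frame_interval: float) -> pd.DataFrame:
        n = len(self.true_trace)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_s": np.arange(n) * frame_interval,
                "row": self.true_path[:, 0],
                "col": self.true_path[:, 1],
                "true_dRR": self.true_trace,
            }
        )


def random_walk_path(
    n_frames: int,
    frame_shape: tuple[int, int],
    rng: np.random.Generator,
    step_sd: float = 0.5,
    margin: float = 25.0,
    reversion: float = 0.02,
    start: tuple[float, float] | None = None,
) -> np.ndarray:
    """Mean-reverting random walk confined to the frame interior.

    Emulates the residual motion of a trapped but non-immobilized animal:
    small per-frame displacements (``step_sd`` px RMS per axis) around a
    home position, never approaching the border closer than ``margin`` so
    ROI discs stay inside the frame.
    """
    lo = np.array([margin, margin])
    hi = np.array([frame_shape[0] - 1 - margin, frame_shape[1] - 1 - margin])
    if (hi <= lo).any():
        raise ValueError("frame too small for the requested margin")
    home = np.array(start, dtype=float) if start is not None else (lo + hi) / 2
    pos = home.copy()
    path = np.empty((n_frames, 2))
    for t in range(n_frames):
        path[t] = pos
        step = rng.normal(0.0, step_sd, size=2) + reversion * (home - pos)
        pos = np.clip(pos + step, lo, hi)
    return path


def default_motion_gain(
    n_frames: int, rng: np.random.Generator, sd: float = 0.05, ar: float = 0.9
) -> np.ndarray:
    """Slowly varying multiplicative illumination/focus artifact around 1."""
    g = np.empty(n_frames)
    x = 0.0
    scale = sd * np.sqrt(1 - ar**2)
    for t in range(n_frames):
        x = ar * x + rng.normal(0.0, scale)
        g[t] = x
    return np.clip(1.0 + g, 0.2, None)


def render_scene(
    config: SceneConfig,
    protocol: StimulusProtocol,
    model: ResponseModel,
    true_trace: np.ndarray | None = None,
    force_respond: bool | None = None,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Render the two channel stacks and return them with the ground truth.

    The neuron path, motion-gain series and (via ``build_true_trace``) the
    calcium trace are drawn from ``config.rng_seed`` unless supplied;
    identical inputs give bit-identical stacks.
    """
    rng = np.random.default_rng(config.rng_seed)
    times = config.times

    path = config.neuron_path
    if path is None:
        path = random_walk_path(config.n_frames, config.frame_shape, rng)
    gain = config.motion_gain_series
    if gain is None:
        gain = default_motion_gain(config.n_frames, rng)

    if true_trace is None:
        trace, responders, amps = build_true_trace(
            times, protocol, model, rng, force_respond=force_respond
        )
    else:
        trace = np.asarray(true_trace, dtype=float)
        if trace.shape != (config.n_frames,):
            raise ValueError("true_trace must have one value per frame")
        responders = np.zeros(protocol.n_stimuli, dtype=bool)
        amps = np.zeros(protocol.n_stimuli)

    rows, cols = config.frame_shape
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    bleach = np.exp(-config.bleach_rate * times)

    green = np.empty((config.n_frames, rows, cols))
    red = np.empty_like(green)
    inv2s2 = 1.0 / (2.0 * config.soma_sigma**2)
    for t in range(config.n_frames):
        blob = np.exp(-(((rr - path[t, 0]) ** 2) + ((cc - path[t, 1]) ** 2)) * inv2s2)
        soma_green = (config.gcamp_baseline + config.gcamp_gain * trace[t]) * blob
        soma_red = config.rfp_level * blob
        green[t] = gain[t] * (config.background_level + bleach[t] * soma_green)
        red[t] = gain[t] * (config.background_level + bleach[t] * soma_red)
    if config.noise_sd > 0:
        green += rng.normal(0.0, config.noise_sd, size=green.shape)
        red += rng.normal(0.0, config.noise_sd, size=red.shape)

    truth = GroundTruth(
        true_trace=trace,
        true_path=path,
        responder=responders,
        per_stimulus_amplitude=amps,
    )
    g = ImageStack(green, frame_interval=config.frame_interval, channel="green")
    r = ImageStack(red, frame_interval=config.frame_interval, channel="red")
    return g, r, truth


def simulate_trial(
    protocol: StimulusProtocol | None = None,
    model: ResponseModel | None = None,
    seed: int = 0,
    force_respond: bool | None = None,
    **config_kwargs,
) -> tuple[ImageStack, ImageStack, GroundTruth, SceneConfig]:
    """Convenience wrapper: default protocol/model, config built from kwargs."""
    protocol = protocol or StimulusProtocol.single_pulse(record_duration=30.0)
    model = model or ResponseModel()
    n_frames = config_kwargs.pop(
        "n_frames", protocol.n_frames(config_kwargs.get("frame_interval", 0.1))
    )
    config = SceneConfig(n_frames=n_frames, rng_seed=seed, **config_kwargs)
    green, red, truth = render_scene(
        config, protocol, model, force_respond=force_respond
    )
    return green, red, truth, config


def simulate_trace(
    protocol: StimulusProtocol,
    model: ResponseModel,
    seed: int,
    frame_interval: float = 0.1,
    trace_noise_sd: float = 0.02,
    amplitude_multipliers: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Trace-level simulation: the true dR/R0 series plus measurement noise,
    skipping video rendering.  Used for large metric/screen ensembles where
    rendering every trial adds nothing.

    Returns ``(times, noisy_dRR, ground_truth)``; the ground-truth path is
    empty.
    """
    n = protocol.n_frames(frame_interval)
    times = np.arange(n) * frame_interval
    rng = np.random.default_rng(seed)
    trace, responders, amps = build_true_trace(
        times, protocol, model, rng, amplitude_multipliers=amplitude_multipliers
    )
    noisy = trace + rng.normal(0.0, trace_noise_sd, size=n)
    truth = GroundTruth(
        true_trace=trace,
        true_path=np.empty((0, 2)),
        responder=responders,
        per_stimulus_amplitude=amps,
    )
    return times, noisy, truth


def write_scene(
    outdir,
    green: ImageStack,
    red: ImageStack,
    config: SceneConfig,
    protocol: StimulusProtocol,
    truth: GroundTruth,
    split_frame: bool = False,
) -> dict:
    """Write TIFF stack(s), ground-truth CSV and a JSON sidecar; returns the
    sidecar dict (file names, protocol, scene parameters, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if split_frame:
        write_split_frame(outdir / "scene_split.tif", green, red)
        files = {"split": "scene_split.tif"}
    else:
        green.save(outdir / "scene_green.tif")
        red.save(outdir / "scene_red.tif")
        files = {"green": "scene_green.tif", "red": "scene_red.tif"}
    truth.to_frame(config.frame_interval).to_csv(
        outdir / "ground_truth.csv", index=False
    )
    sidecar = {
        "files": files,
        "ground_truth": "ground_truth.csv",
        "protocol": protocol.to_dict(),
        "seed": config.rng_seed,
        "scene": {
            "frame_shape": list(config.frame_shape),
            "n_frames": config.n_frames,
            "frame_interval": config.frame_interval,
            "soma_sigma": config.soma_sigma,
            "gcamp_baseline": config.gcamp_baseline,
            "gcamp_gain": config.gcamp_gain,
            "rfp_level": config.rfp_level,
            "background_level": config.background_level,
            "bleach_rate": config.bleach_rate,
            "noise_sd": config.noise_sd,
        },
    }
    with open(outdir / "scene.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar
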