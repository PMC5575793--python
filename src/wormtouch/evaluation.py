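"""End-to-end validation runs on synthetic ground truth.

These routines drive the whole pipeline — render a scene, track, extract,
normalize, measure — against the generator's known answers, and calibrate
the statistics against brute-force oracles.  They back both the test suite
and the reproduction script; each returns plain numbers.

Problem sizes (50 rendered scenes of 300 frames at 96x96 px, 2000-replicate
null calibrations, 20-replicate screen simulations) are chosen so a full
validation pass completes in minutes on one CPU while keeping Monte-Carlo
error well inside the checked bands.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import (
    half_life,
    peak_response,
    response_fraction,
    summarize_grid,
    trial_metrics,
)
from .protocol import StimulusProtocol
from .screen import mann_whitney, screen_report
from .synthetic import (
    ResponseModel,
    SceneConfig,
    render_scene,
    simulate_trace,
)
from .traces import CalciumTrace, extract_trial

__all__ = [
    "recovery_benchmark",
    "gain_invariance_deviation",
    "halflife_closed_form_error",
    "mann_whitney_enumeration_deviation",
    "kruskal_wallis_type1_rate",
    "simulate_screen",
    "screen_detection_benchmark",
    "grid_monotonicity",
]


def _standard_protocol(record_duration: float = 30.0) -> StimulusProtocol:
    return StimulusProtocol.single_pulse(
        pressure=40.0, duration=1.0, baseline_window=10.0,
        record_duration=record_duration,
    )


# ---------------------------------------------------------------------------
# ground-truth recovery


@dataclass
class RecoveryResult:
    trace_rmse: np.ndarray  # per scene
    peak_rel_error: np.ndarray  # per responding stimulus, |peak-amp|/amp
    position_errors: np.ndarray  # pooled per-frame tracker errors (px)

    @property
    def median_position_error(self) -> float:
        return float(np.median(self.position_errors))

    @property
    def p95_position_error(self) -> float:
        return float(np.percentile(self.position_errors, 95))


def recovery_benchmark(
    n_scenes: int = 50, seed: int = 0, noise_sd: float = 2.0
) -> RecoveryResult:
    """Render seeded scenes, run the full chain, compare to ground truth.

    Every scene delivers one 40 psi / 1 s stimulus after a 10 s baseline and
    forces a response so peak recovery is measurable.  Returns per-scene
    trace RMSE, per-stimulus relative peak errors and pooled per-frame
    tracker position errors.
    """
    protocol = _standard_protocol()
    model = ResponseModel()
    rmses, peak_errs, pos_errs = [], [], []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_scenes):
        scene_seed = int(child.generate_state(1)[0] % (2**31))
        config = SceneConfig(
            n_frames=protocol.n_frames(0.1), noise_sd=noise_sd, rng_seed=scene_seed
        )
        green, red, truth = render_scene(
            config, protocol, model, force_respond=True
        )
        trace, traj = extract_trial(green, red, protocol)
        ok = trace.valid
        rmses.append(
            float(np.sqrt(np.mean((trace.dRR[ok] - truth.true_trace[ok]) ** 2)))
        )
        m = trial_metrics(trace, 0)
        amp = truth.per_stimulus_amplitude[0]
        peak_errs.append(abs(m.max_dRR - amp) / amp)
        pos_errs.append(
            np.hypot(*(traj.positions - truth.true_path).T)
        )
    return RecoveryResult(
        trace_rmse=np.asarray(rmses),
        peak_rel_error=np.asarray(peak_errs),
        position_errors=np.concatenate(pos_errs),
    )


def gain_invariance_deviation(seed: int = 0) -> float:
    """Max |ratiometric dR/R0 (gain-fluctuating scene) - single-channel
    dF/F0 (gain-free scene)| on a noiseless static-soma scene.

    With a shared per-frame multiplicative artifact in both channels the
    background-subtracted ratio cancels it exactly, so the two normalized
    traces must agree to machine precision.
    """
    protocol = _standard_protocol()
    model = ResponseModel()
    rng = np.random.default_rng(seed)
    n = protocol.n_frames(0.1)
    path = np.tile([48.0, 48.0], (n, 1))
    gains = np.exp(rng.normal(0.0, 0.3, size=n))  # strong artifact, 1/3 log-SD
    base = dict(
        n_frames=n, neuron_path=path, noise_sd=0.0, bleach_rate=0.0,
        rng_seed=seed,
    )
    cfg_gain = SceneConfig(motion_gain_series=gains, **base)
    cfg_flat = SceneConfig(motion_gain_series=np.ones(n), **base)
    g1, r1, truth = render_scene(cfg_gain, protocol, model, force_respond=True)
    g2, _, _ = render_scene(cfg_flat, protocol, model, force_respond=True)
    ratio, _ = extract_trial(g1, r1, protocol)
    single, _ = extract_trial(g2, None, protocol)
    return float(np.max(np.abs(ratio.dRR - single.dRR)))


# ---------------------------------------------------------------------------
# metric closed forms


def halflife_closed_form_error(
    tau: float = 2.0, frame_interval: float = 0.1
) -> float:
    """|measured - tau*ln2| for a sampled pure exponential decay."""
    t_peak = 10.0
    time = np.arange(0.0, 40.0, frame_interval)
    dRR = np.where(time >= t_peak, np.exp(-(time - t_peak) / tau), 0.0)
    trace = CalciumTrace(
        time=time,
        I_G_roi=dRR,
        I_G_back=np.zeros_like(time),
        R_or_F=dRR,
        valid=np.ones_like(time, dtype=bool),
        mode="single_channel",
        dRR=dRR,
    )
    hl = half_life(trace, t_peak=t_peak, max_dRR=1.0)
    assert hl is not None
    return abs(hl - tau * math.log(2))


# ---------------------------------------------------------------------------
# statistic oracles


def mann_whitney_p_enumerated(x, y) -> float:
    """Brute-force two-sided Mann-Whitney p: enumerate every assignment of
    the pooled ranks to the first sample and count U values at least as
    extreme (in either tail) as observed.  Tie-free samples only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ValueError("enumeration oracle requires tie-free samples")
    ranks = sps.rankdata(pooled)
    nx = x.size
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mean_u = nx * y.size / 2
    dev = abs(u_obs - mean_u)
    count = 0
    total = 0
    for comb in itertools.combinations(range(pooled.size), nx):
        u = sum(sorted(ranks)[i] for i in comb) - nx * (nx + 1) / 2
        if abs(u - mean_u) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney_enumeration_deviation(max_total: int = 10) -> float:
    """Max |scipy-exact p - enumerated p| over every tie-free rank
    configuration with n_x + n_y <= ``max_total`` (both sides nonempty)."""
    worst = 0.0
    for total in range(2, max_total + 1):
        values = np.arange(1.0, total + 1.0)
        for nx in range(1, total):
            for comb in itertools.combinations(range(total), nx):
                x = values[list(comb)]
                y = np.delete(values, list(comb))
                p_pkg = mann_whitney(x, y).p_value
                p_ref = mann_whitney_p_enumerated(x, y)
                worst = max(worst, abs(p_pkg - p_ref))
    return worst


def kruskal_wallis_type1_rate(
    n_reps: int = 2000,
    n_groups: int = 3,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the Kruskal-Wallis test under the null
    (all groups drawn from one distribution)."""
    from .screen import kruskal_wallis

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        groups = rng.normal(size=(n_groups, n_per_group))
        if kruskal_wallis(list(groups)).p_value < alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# synthetic screen


def simulate_screen(
    group_models: dict[str, ResponseModel],
    n_per_group: int = 25,
    n_days: int = 3,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
) -> pd.DataFrame:
    """Simulate a screen at trace level: per animal, one trial under its
    group's response model, metrics computed by the standard chain.

    ``group_models`` maps group name -> model; a 'control' key is required.
    Animals are spread evenly over ``n_days`` imaging days.
    """
    if "control" not in group_models:
        raise ValueError("group_models needs a 'control' entry")
    protocol = protocol or _standard_protocol(record_duration=40.0)
    root = np.random.SeedSequence(seed)
    group_seqs = root.spawn(len(group_models))
    rows = []
    for g_i, (group, model) in enumerate(sorted(group_models.items())):
        for a_i, child in enumerate(group_seqs[g_i].spawn(n_per_group)):
            trial_seed = int(child.generate_state(1)[0] % (2**31))
            _, noisy, _ = simulate_trace(protocol, model, seed=trial_seed)
            trace = CalciumTrace(
                time=np.arange(len(noisy)) * 0.1,
                I_G_roi=noisy,
                I_G_back=np.zeros_like(noisy),
                R_or_F=noisy,
                valid=np.ones_like(noisy, dtype=bool),
                mode="single_channel",
                protocol=protocol,
                dRR=noisy,
            )
            m = trial_metrics(trace, 0)
            rows.append(
                {
                    "animal_id": f"{group}-{a_i:03d}",
                    "compound": group,
                    "day": f"day-{a_i % n_days + 1}",
                    "max_dRR": m.max_dRR,
                    "delay_time": m.delay_time,
                    "half_life": np.nan if m.half_life is None else m.half_life,
                    "responder": m.responder,
                }
            )
    return pd.DataFrame(rows)


def model_for_probability(
    p: float, pressure: float, model: ResponseModel
) -> ResponseModel:
    """Shift the logistic responder midpoint so that a stimulus at
    ``pressure`` responds with probability ``p``."""
    if not 0 < p < 1:
        raise ValueError("probability must be in (0, 1)")
    logit = math.log(p / (1 - p))
    return model.with_(respond_prob_mid=pressure - logit / model.respond_prob_slope)


def screen_detection_benchmark(
    n_reps: int = 20, n_per_group: int = 25, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Planted-effect screen recovery.

    Control responds with probability 0.9 at the test stimulus; compound
    'suppressor' drops that to 0.05, compound 'slow_decay' doubles the decay
    time constant (doubling the half-life), compound 'inert' is identical to
    control.  A replicate succeeds when the report flags suppressor (on max
    dR/R0) and slow_decay (on half-life), does not flag inert on any metric,
    and ranks suppressor's responder fraction lowest.
    """
    base = model_for_probability(0.9, 40.0, ResponseModel())
    groups = {
        "control": base,
        "suppressor": model_for_probability(0.05, 40.0, base),
        "slow_decay": base.with_(tau_decay=2 * base.tau_decay),
        "inert": base,
    }
    successes = 0
    per_rep = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        records = simulate_screen(groups, n_per_group=n_per_group, seed=rep_seed)
        report = screen_report(records)
        flagged = report.flagged(alpha)
        inert_hit = any("inert" in v for v in flagged.values())
        frac = report.fractions.set_index("compound")["responder_fraction"]
        ok = (
            "suppressor" in flagged["max_dRR"]
            and "slow_decay" in flagged["half_life"]
            and not inert_hit
            and frac.idxmin() == "suppressor"
        )
        per_rep.append(ok)
        successes += ok
    return {
        "detection_rate": successes / n_reps,
        "per_replicate": per_rep,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# dose-response grids


def grid_monotonicity(
    seed: int = 0,
    pressures=(25.0, 30.0, 35.0, 40.0, 45.0),
    durations=(1.0, 2.0, 5.0),
    n_per_cell: int = 15,
) -> dict:
    """Simulate a pressure x duration grid of trials and rank-correlate the
    cell summaries with the stimulus parameters.

    Returns Spearman correlations of mean peak and response fraction with
    pressure and with duration across cells (positive under the generative
    dose-response model).
    """
    model = ResponseModel()
    root = np.random.SeedSequence(seed)
    trials = []
    cells = [(p, d) for p in pressures for d in durations]
    for (p, d), cell_seq in zip(cells, root.spawn(len(cells))):
        protocol = StimulusProtocol.single_pulse(
            pressure=p, duration=d, record_duration=10.0 + d + 15.0
        )
        for child in cell_seq.spawn(n_per_cell):
            s = int(child.generate_state(1)[0] % (2**31))
            _, noisy, _ = simulate_trace(protocol, model, seed=s)
            trace = CalciumTrace(
                time=np.arange(len(noisy)) * 0.1,
                I_G_roi=noisy,
                I_G_back=np.zeros_like(noisy),
                R_or_F=noisy,
                valid=np.ones_like(noisy, dtype=bool),
                mode="single_channel",
                protocol=protocol,
                dRR=noisy,
            )
            trials.append((p, d, peak_response(trace, 0)[0]))
    summary = summarize_grid(trials)
    t = summary.table
    out = {}
    for col in ("mean_peak", "response_fraction"):
        for var, other in (("pressure", "duration"), ("duration", "pressure")):
            # monotone along one axis: Spearman within each level of the
            # other axis, averaged over the non-constant levels
            rhos = []
            for _, grp in t.groupby(other):
                if grp[col].nunique() > 1 and len(grp) > 1:
                    rhos.append(sps.spearmanr(grp[var], grp[col]).statistic)
            out[f"{col}_vs_{var}_spearman"] = float(np.mean(rhos)) if rhos else np.nan
    out["table"] = t
    return out
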