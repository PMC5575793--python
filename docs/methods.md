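# Methods

This note documents the models, defaults and numerical choices behind
`wormtouch`, and what the synthetic benchmark does and does not establish
about real recordings.

## Pipeline model and assumptions

The pipeline assumes a single labeled soma per field of view, imaged at a
fixed frame interval (default 0.1 s, the typical EM-CCD exposure for this
assay), either in two spectrally split channels (calcium-sensitive green,
calcium-independent red) or green alone.  The animal is restrained but not
immobilized: the soma drifts by up to a few pixels per frame, and focus and
illumination fluctuate.  The central modeling assumption is that these
artifacts act *multiplicatively and identically on both channels*, so the
background-subtracted green/red ratio cancels them; single-channel
$\Delta F/F_0$ retains them and is offered only for strains without the red
reference.

### Tracking

Per frame, the candidate is the brightest pixel within `search_radius`
(default 15 px at 10 Hz — generous relative to the observed per-frame
motion) of the previous position, refined to the intensity-weighted
centroid of a 5-px disc after subtracting the local background (median-free
annulus mean over radii 6–12 px).  A frame is *coasted* — previous position
reused, frame flagged — when the candidate does not exceed the annulus mean
by 3 annulus SDs; this keeps blinking or defocused frames from dragging the
trajectory onto noise.  Locked displacements are capped at `search_radius`,
so the trajectory can never jump further than the search window between
locked frames.  Seeding uses the intensity-weighted centroid of the
brightest connected region (pixels above half the peak prominence),
optionally restricted to a window around a user hint.  Tracking runs on the
red channel when available, because its intensity does not change with
stimulation; ties between equal-intensity maxima break deterministically by
smallest row, then column.  No sub-pixel interpolation beyond the centroid
is attempted: the top-k ROI statistic is insensitive to sub-pixel shifts.

### ROI statistic and rasterization

The signal ROI is a disc of radius 10 px; a pixel belongs when its center
lies within the radius of the *rounded* ROI center (317 pixels for a full
disc).  The intensity is the mean of the 100 brightest member pixels, which
makes the statistic robust to the exact disc placement and to the soma
covering only part of the disc.  Ties at the top-k cutoff cannot affect the
mean (tied values are equal), so the statistic is bit-reproducible under
any scan order.  If the disc is clipped by the frame edge, all available
pixels are used and the trace is flagged (`roi_clipped`).

The background ROI is a fixed 10-px disc whose plain mean (all pixels) is
subtracted in both channels.  By default its center is chosen from the
first frame as the position of the lowest local mean intensity whose disc
stays inside the frame and at least 40 px from the brightest spot; a
darkest-pixels centroid was rejected because on a uniform noisy background
the darkest decile scatters everywhere and its centroid lands on the soma.

### Ratio dialects and invalid frames

The default ratio subtracts background in *both* channels before dividing:
$R = (I_G^{ROI}-I_G^{Back})/(I_R^{ROI}-I_R^{Back})$.  A no-red-subtraction
dialect (`subtract_background_red=False`) is provided because conventions
differ between labs.  Frames with a non-positive red denominator are
flagged invalid, excluded from baseline and metrics, and only linearly
interpolated for display (`interpolated_dRR`).

### Baseline and normalization

$R_0$ is the mean of $R$ over all valid frames before the first stimulus
onset (the whole pre-stimulus window, not a sub-window); at least 5 valid
pre-stimulus frames are required, and a non-positive ratiometric baseline
is an error.  By construction the pre-stimulus mean of $\Delta R/R_0$ is
exactly zero.

### Response metrics

The response window of stimulus $i$ is $[t^{on}_i, t^{on}_{i+1})$ (to the
end of the recording for the last stimulus), which keeps repeated-stimulus
analysis well defined; the peak is the earliest maximum of $\Delta R/R_0$
in the window.  Delay time is `t_peak − (onset + duration)`, reported
as-is and flagged when negative (peak during the stimulus) rather than
clamped.  Half-life is the first post-peak crossing of half-maximum,
linearly interpolated between the bracketing frames; traces that never
cross before the recording ends give an *undefined* half-life, which is
excluded from group statistics with counts reported, never imputed.  The
responder threshold is 0.5 with a strict inequality, configurable.  Grid
summaries report the mean peak per cell by default with the median
alongside, since conventions differ; untested cells are simply absent.

## The synthetic generator

Real recordings of this assay are not deposited, so the generator is the
test bed: it must produce data with the statistical structure the analysis
assumes, plus the ground truth.

Render model per frame $t$ (time $t\,\Delta t$):

```
green = g_t * (B + b_t * (S0 + gain * s_t) * blob_t) + N(0, noise_sd)
red   = g_t * (B + b_t * RFP * blob_t)               + N(0, noise_sd)
```

* `blob` — unit-peak Gaussian soma (sigma 3 px) at the shared per-frame
  path position; the path is a mean-reverting random walk (0.5 px RMS step
  per axis, kept ≥ 25 px from the border) emulating residual motion of a
  restrained animal.
* `g_t` — multiplicative artifact shared by both channels, AR(1) around 1
  (SD 0.05) by default, arbitrary positive series in tests.
* `b_t = exp(-bleach_rate * t)` — photobleaching (default 0.002 /s),
  applied to fluorophore terms only so background subtraction stays
  meaningful; because it multiplies both channels' soma terms it cancels in
  the ratio, as in real ratiometric data.
* `B` = 100, `RFP` = 150, `S0` = 100 (calcium-independent green soma
  intensity), `gain` = 100 intensity units per unit $\Delta R/R_0$.  With
  `gain = S0` the noiseless ratiometric $\Delta R/R_0$ equals the planted
  trace exactly (the resting ratio is $S0/RFP \approx 0.667$); `S0` is a
  deliberate extra knob so miscalibrated-gain scenarios can also be
  simulated.
* `noise_sd` = 2 additive Gaussian counts.  At these levels the per-frame
  SNR of the soma over background is ~25:1 and the noise floor of the
  extracted $\Delta R/R_0$ is ~0.01 — a deliberately clean-but-not-ideal
  regime; the analysis never models noise, so a mixed Poisson–Gaussian
  camera model would add realism without exercising any additional code
  path.

Calcium dynamics are phenomenological — the assay literature shows trace
shapes but no quantitative model, so every kernel/dose–response default
below is this package's choice, not a measured constant:

* **Kernel**: rise $1-e^{-t/\tau_r}$ while driven, peak at
  `duration + tau_rise` (responses peak shortly after the stimulus ends),
  then decay $e^{-t/\tau_d}$; normalized to unit peak so a planted
  amplitude is exactly the trace's peak and the post-peak half-life is
  exactly $\tau_d \ln 2$.  Defaults $\tau_r = 0.5$ s, $\tau_d = 4$ s give
  the observed fast-rise/slow-decay shape.  Overlapping stimuli add
  linearly.
* **Amplitude**: $A = A_{max} \cdot p^h/(p^h + p_{1/2}^h) \cdot
  (1 - e^{-d/d_{sat}})$ with $A_{max} = 3$ (the top of the reported peak
  scale), $p_{1/2} = 30$ psi, $h = 4$, $d_{sat} = 2$ s — monotone in
  pressure and duration, steep around 30–40 psi.
* **Responders**: per-stimulus Bernoulli with logistic probability in an
  *effective pressure* $p \cdot (1-e^{-d/d_{sat}})/(1-e^{-1/d_{sat}})$
  (normalized at the canonical 1 s stimulus), midpoint 30 psi, slope
  0.5 /psi.  Duration enters because response *rates*, not just
  amplitudes, are graded in stimulus duration in this assay; with these
  defaults a 1 s stimulus responds >99% of the time at 45 psi and <10% at
  25 psi, bracketing the reported >90%-above-40-psi / <20%-below-30-psi
  behavior.
* **Habituation**: per-stimulus amplitude multipliers, short-ISI series
  (1.0, 1.3, 0.8, 0.5) — facilitation up to the second stimulus, then
  depression — and long-ISI series (1.0, 0.7, 0.5, 0.35), selected at an
  ISI threshold of 30 s (the experimental contrast is 1 s vs 3 min).

`simulate_trace` generates the same dynamics at trace level (kernel +
Gaussian noise, SD 0.02) for large metric/screen ensembles where rendering
video adds nothing.

### What the generator does not emulate

No body deformation or rolling (the soma is a rigid Gaussian), no
neighboring fluorescent structures (gut autofluorescence, other neurons),
no focus drift that differs between channels, no Poisson shot noise or
camera pattern noise, no chromatic misregistration beyond the configurable
split-frame offset, and single-soma scenes only.  Passing tests therefore
establish that the estimator chain is *correct and artifact-cancelling
under its stated assumptions*, not that tracking survives severe body
motion or that the ratio cancels channel-asymmetric artifacts — on real
data those remain the user's responsibility to check.

## Screen statistics

Treated values are divided by the same-day control group mean (median
selectable) per metric, requiring ≥ 3 defined control values per day;
controls therefore normalize to mean 1 by construction, and rank tests are
unaffected by the (positive) normalization within a day.  Two-group
comparisons use Mann–Whitney U: exact enumeration p when
$n_x + n_y \le 16$ with no ties, otherwise the normal approximation with
midrank tie correction and continuity correction.  Multi-group comparisons
use Kruskal–Wallis with tie correction and a $\chi^2_{k-1}$ p-value; an
all-identical sample is flagged degenerate rather than assigned a p.  The
screen report emits both a global Kruskal–Wallis across all groups per
metric and a per-compound two-group test against control (which carries
the star flags, matching how such screens are annotated).  All tests are
two-sided; no multiple-testing correction is applied across compounds by
default (a Benjamini–Hochberg step would be a caller-side addition), and
star tiers use strict inequalities at 0.05/0.01/0.001/0.0001.

The calibration fit is plain OLS with intercept (a through-origin mode is
provided); $R^2 = 1 - SS_{res}/SS_{tot}$, with $SS_{tot} = 0$ flagged
degenerate instead of reporting 0 or 1.

## Numerical and validation choices

* Coordinates are 0-based (row, col); time = frame_index x frame_interval;
  all rendering and extraction run in float64, and identical seeds give
  bit-identical stacks.
* The chi-squared approximation for Kruskal–Wallis is slightly conservative
  at small group sizes; the null calibration (3 groups x 10, 2000
  replicates) typically measures a type-I rate near 0.04 at nominal 0.05.
* Validation problem sizes — 50 rendered scenes of 300 frames at 96x96 px
  for recovery, 2000 replicates for null calibration, 20 replicates x 4
  groups x 25 animals for the planted-effect screen — were chosen so a
  full validation pass runs in a few minutes on one CPU while keeping
  Monte-Carlo error small against the checked margins (measured recovery:
  trace RMSE ≈ 0.006 against a 0.05 bound, tracker median error ≈ 0.18 px
  against 1 px).
* Habituation ordering tests use a 10 s ISI (still in the short-ISI
  regime): with $\tau_d = 4$ s, a 1 s ISI superposes decay tails strongly
  enough that window maxima no longer track the planted multipliers — a
  property of calcium dynamics, not an extraction artifact — so the planted
  ordering is only a valid oracle once carry-over is small.

## Known limitations

* The tracker is a local greedy search; it does not recover from a wrong
  lock (no global re-detection) and is untested against whole-body lunges
  larger than the search radius.
* Ratio cancellation is exact only for artifacts that are truly common to
  both channels; channel-specific focus or spectral changes propagate into
  $\Delta R/R_0$.
* The dose–response and habituation defaults are plausible but synthetic;
  fitted parameters from real data should replace them when available.
* The split-frame reader assumes the fixed left/right layout written by
  this package's writer; other beamsplitter dialects need a custom reader.
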