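# wormtouch

Quantification of stimulus-evoked calcium imaging in *C. elegans*
mechanosensory neurons.

Microfluidic mechanostimulation assays deliver controlled pressure pulses to
a trapped (but not immobilized) worm while a two-channel video records a
genetically encoded calcium indicator (GCaMP, green) and a
calcium-independent reference fluorophore (RFP, red) in a single neuron
soma.  Turning those videos into numbers requires a chain of steps — follow
the moving soma, quantify ROI fluorescence, cancel motion artifacts with the
channel ratio, normalize to the pre-stimulus baseline, and summarize each
transient — and `wormtouch` implements that chain as a tested, reusable
library with a synthetic video generator standing in for the microscope.

It is aimed at experimentalists and methods developers who need a
transparent, scriptable version of this quantification (for real stacks or
for benchmarking alternatives), with ground-truth-driven tests for every
stage.

## The quantities computed

Per frame, with the soma tracked at position $(r_t, c_t)$:

* ROI intensity $I^{ROI}$ — mean of the 100 brightest pixels of a
  10-pixel-radius disc around the tracked position, per channel;
* background intensity $I^{Back}$ — plain mean over a disc in a neuron-free
  region;
* ratio $R = (I_G^{ROI} - I_G^{Back}) / (I_R^{ROI} - I_R^{Back})$, which
  cancels motion/illumination artifacts shared by the channels (when only
  GCaMP is available, $F = I_G^{ROI} - I_G^{Back}$ is used);
* normalized trace $\Delta R/R_0 = (R - R_0)/R_0$ with $R_0$ the mean $R$
  before the first stimulus onset.

Per stimulus-evoked transient:

* **max $\Delta R/R_0$** over the response window (onset to next onset);
* **delay time** — from stimulus end to the peak;
* **half-life** — time for the trace to decay to half its maximum;
* **responder** — max $\Delta R/R_0 > 0.5$ (strict), whose ensemble mean is
  the *response fraction*.

Ensemble layers summarize pressure x duration grids (mean peak and response
fraction per cell), habituation series under repeated stimulation, the
membrane displacement-vs-pressure calibration line (OLS with $R^2$), and
drug screens: per-day control normalization of the three metrics followed by
Kruskal–Wallis / Mann–Whitney rank tests with star tiers
(\* p<0.05, \*\* p<0.01, \*\*\* p<0.001, \*\*\*\* p<0.0001).

The synthetic generator renders two-channel TIFF stacks from a
phenomenological model (saturating-rise x exponential-decay calcium kernel;
Hill dose–response in pressure; logistic Bernoulli responder model;
Gaussian soma on a moving path with shared multiplicative artifacts,
photobleaching and sensor noise) and returns the ground truth next to the
video.  See `docs/methods.md` for the model and every default.

## Worked example

```python
import numpy as np
from wormtouch import (StimulusProtocol, simulate_trial, extract_trial,
                       trial_metrics)

# one 40 psi / 1 s pulse, 10 s baseline, 30 s recording at 10 Hz
protocol = StimulusProtocol.single_pulse(pressure=40, duration=1.0,
                                         baseline_window=10.0,
                                         record_duration=30.0)
green, red, truth, config = simulate_trial(protocol, seed=1,
                                           force_respond=True)
trace, traj = extract_trial(green, red, protocol)

rmse = np.sqrt(np.mean((trace.dRR[trace.valid]
                        - truth.true_trace[trace.valid]) ** 2))
err = np.hypot(*(traj.positions - truth.true_path).T)
m = trial_metrics(trace)
print(f"baseline R0           : {trace.baseline:.4f}")
print(f"trace RMSE vs truth   : {rmse:.4f}")
print(f"tracker median error  : {np.median(err):.3f} px")
print(f"max dR/R0             : {m.max_dRR:.3f}  "
      f"(planted {truth.per_stimulus_amplitude[0]:.3f})")
print(f"delay time            : {m.delay_time:.2f} s")
print(f"half-life             : {m.half_life:.2f} s")
print(f"responder (>0.5)      : {m.responder}")
```

prints

```
baseline R0           : 0.6672
trace RMSE vs truth   : 0.0063
tracker median error  : 0.182 px
max dR/R0             : 0.896  (planted 0.897)
delay time            : 0.50 s
half-life             : 2.81 s
responder (>0.5)      : True
```

The baseline 0.667 is the soma's resting green/red intensity ratio
(100/150 under the default scene); the extracted trace matches the planted
one to within the noise floor; the peak arrives one rise-time (0.5 s) after
the stimulus ends and decays with half-life $\tau_{decay}\ln 2 \approx
2.77$ s; the peak exceeds 0.5, so the trial counts as a responder.

The same stages are available from a shell:

```bash
wormtouch simulate --seed 5 --out scene/
wormtouch track   --stack scene/scene_red.tif --channel red --out traj.csv
wormtouch extract --green scene/scene_green.tif --red scene/scene_red.tif \
                  --traj traj.csv --protocol protocol.json --out trace.csv
wormtouch metrics --traces traces/ --protocol protocol.json --out metrics.csv
wormtouch calibrate --table cal.csv
wormtouch screen  --metrics m.csv --conditions c.csv --out report.json
```

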