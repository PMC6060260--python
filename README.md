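# boutonkit

Analysis toolkit for **presynaptic calcium imaging** with dual-color
genetically encoded sensors: a green, calcium-sensitive indicator
(e.g. synaptophysin-targeted GCaMP) imaged alongside a red,
calcium-independent reference (e.g. mCherry), recorded as interleaved
two-channel time-lapse stacks from stimulated brain slices.

It is written for experimenters who need to turn such raw stacks into
quantitative, reproducible measurements:

* **Deinterleaving and I/O** — alternating-excitation TIFF stacks with a
  YAML metadata sidecar; traces and ROIs as plain CSV/JSON.
* **Photobleach compensation** — the no-stimulus control trace is fitted
  with a double exponential `F(t) = F0·(a1·e^(−t/τ1) + a2·e^(−t/τ2) + c)`
  and stimulated traces are divided by the normalized curve `B(t)`.
* **F/F0 normalization** — `F0` is the mean of all pre-stimulus samples;
  the last pre-stimulus sample defines `t = 0`.
* **Bouton segmentation** — the temporally averaged image is transformed
  with the discrete Laplace operator; a multiple `k` of the SD of all
  Laplacian pixels thresholds punctate components, each centered at its
  brightest pixel. Fixed 3×3 ROIs and neighboring 3×3 background ROIs
  complete the measurement geometry.
* **Responder classification** — hierarchical clustering (Ward,
  Euclidean) of z-scored F/F0 traces cut into two clusters, with a
  minimum-response guard; reports the responding proportion of all ROIs.
* **Transient kinetics** — peak ΔF/F0, time to peak, initial slope,
  area under the curve for 2 s, and the decay time constant fitted as a
  single or double exponential (AICc selection, fast τ reported);
  stimulus–response relations summarized by 4-parameter logistic or
  restricted linear fits.
* **Flat-field and mosaics** — the illumination pattern is estimated by
  Gaussian-blurring the tile average (121-px kernel), tiles are divided
  by it and placed on their known grid; green/red ratio images are
  computed after wild-type background subtraction.
* **Synthetic data** — every stage is validated against a generator that
  emulates the recordings (Gaussian boutons, per-stimulus transient
  increments with exponential decay and saturation, double-exponential
  bleaching, Poisson + Gaussian noise, vignetted tiles) with full ground
  truth.

## Worked example

```python
import numpy as np
from boutonkit import (BleachModel, NoiseModel, StimulusProtocol,
                       classify_responders, compute_f_over_f0, correct_bleach,
                       detect_puncta, extract_traces, fit_bleach_model,
                       random_bouton_field, simulate_bleach_control,
                       simulate_movie, summarize_kinetics, temporal_average,
                       SegmentationParams, Trace)

bleach = BleachModel(a1=0.6, tau1_s=5.0, a2=0.4, tau2_s=50.0, c=0.0)
noise = NoiseModel(photon_gain=1.0, read_sigma=2.0, background_level=20.0)
stim = StimulusProtocol(onset_time_s=2.0, n_stimuli=10, frequency_hz=20.0)

boutons = random_bouton_field(30, (64, 256), responder_fraction=0.3, seed=0)
stack, truth = simulate_movie(boutons, stim, noise, bleach,
                              shape=(120, 64, 256), frame_interval_s=0.098,
                              seed=0)
control = simulate_bleach_control(noise, bleach, (200, 64, 256), 0.25, seed=1)

model = fit_bleach_model(Trace(control.times_s(),
                               control.green.mean(axis=(1, 2)), stage="raw"))
print(f"bleach: tau1={model.tau1_s:.2f} s  tau2={model.tau2_s:.2f} s")

rois = detect_puncta(temporal_average(stack.green), SegmentationParams())
print(f"detected {len(rois)} puncta ({len(boutons)} simulated)")

traces = [compute_f_over_f0(correct_bleach(tr, model), stim.onset_time_s)
          for tr in extract_traces(stack.green, rois, stack.frame_interval_s)]
result = classify_responders(traces, stim_onset_s=0.0, stim_window_s=2.0)
print(f"responder proportion: {result.proportion:.2f} "
      f"(truth {truth.responder_labels.mean():.2f})")

summ = summarize_kinetics(result.mean_responder)
print(f"mean responder: peak dF/F0={summ.peak:.2f}  "
      f"fast tau={summ.fast_tau_s:.2f} s  AUC(2 s)={summ.auc:.2f}")
```

Output:

```
bleach: tau1=5.01 s  tau2=45.63 s
detected 30 puncta (30 simulated)
responder proportion: 0.30 (truth 0.30)
mean responder: peak dF/F0=0.53  fast tau=0.50 s  AUC(2 s)=0.39
```

The fitted bleach constants recover the generating 5 s / 50 s pair from
the noisy control; all 30 simulated boutons are found; the classifier
reproduces the simulated 30% responder fraction; and the mean-responder
kinetics match the generating transient (τ_decay = 0.5 s, ten 0.1 ΔF/F0
increments at 20 Hz decaying between stimuli give a ~0.53 peak).

## Command line

`boutonkit` exposes subcommands `simulate`, `bleach-correct`, `segment`,
`classify`, `kinetics`, `stitch`, `ratio`, `colocalize` and `run`
(end-to-end with a manifest of config, seed and output checksums). All
parameters live in one YAML config; `--seed` overrides the config seed.

```bash
boutonkit run --config analysis.yaml --seed 7 --out-dir results/
```

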