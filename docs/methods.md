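# Methods

This note records the models boutonkit implements, the defaults it
ships, and the choices made where the underlying workflow left the
design open.

## Signal model

A recording is an interleaved two-channel stack: frames alternate
between green (calcium-dependent) and red (calcium-independent)
excitation. After deinterleaving, sample *i* of a channel is assigned
time `i × frame_interval_s`; the half-frame offset between channels is
ignored because it is one to two orders of magnitude below every fitted
time constant. Coordinates are 0-based `(row, col)` with pixel centers
on the integer grid. The default channel order is green-first (`GR`),
overridable in the metadata sidecar, since acquisitions do not
consistently record which excitation leads.

### Transient model

A responding bouton's green fluorescence follows
`green_rest × (1 + c(t))` with

```
c(t) = min(cap, Σ_{s_j ≤ t} A · exp(−(t − s_j)/τ_decay))
```

— each stimulus at time `s_j` adds a fixed ΔF/F0 increment `A`
(default 0.1) that decays with a single exponential
(`τ_decay` default 0.5 s), and the sum is hard-clipped at a saturation
cap (default 2.0). The cap reproduces the empirical plateau of
responses to long stimulus trains without asserting a particular
binding model. Non-responders and the red channel carry no
stimulus-locked component; that the red channel is flat (up to bleach
and noise) is asserted as a generator invariant.

### Bleaching

Both channels bleach multiplicatively with channel-specific
double-exponential curves normalized to 1 at t = 0:
`B(t) = a1·e^(−t/τ1) + a2·e^(−t/τ2) + c`. The default control curve is
`a1 = 0.6, τ1 = 5 s, a2 = 0.4, τ2 = 50 s, c = 0`; the red channel
defaults to the same time constants at 30% of the depth, reflecting the
slower bleaching of red reference fluorophores.

### Noise and background

Noise is Poisson applied through a photon gain (counts per intensity
unit) followed by additive Gaussian read noise; intensities are clipped
at zero. The autofluorescent background is a static field with mean
`background_level` and mild (10% RMS) spatial structure at a
configurable correlation length — enough texture to exercise
segmentation without overwhelming the puncta. Camera noise was never
characterized for the original recordings, so these are generic,
explicit choices rather than calibrated claims; likewise the per-stimulus
amplitude is a free parameter. Consequences for interpretation: passing
recovery tests shows the estimators are correct under this noise family
and transient shape, not that they are robust to motion artifacts,
focus drift, or photochromic effects, none of which are simulated.

### Default acquisition regime

Single-bouton movies default to 64 × 512 px frames at 98 ms intervals
with trains of 10 stimuli at 20 Hz — the multiphoton single-bouton
regime. Validation studies use 64 × 256 crops of that regime to keep
run times in seconds. Bleach controls default to 200 frames at 250 ms
(≈50 s): a control must span the slow bleach constant, otherwise τ2 is
unidentifiable from the record.

## Estimation choices

**Bleach compensation is divisive.** Bleaching scales emitted
fluorescence, so corrected values are `F(t)/B(t)`; a pure-bleach trace
corrects to a constant exactly. The fit uses non-negative-bounded
nonlinear least squares with ≥5 log-spaced τ initializations (fast τ
one decade below slow), normalizes to `B(0) = 1`, orders `τ1 ≤ τ2`, and
falls back to a single exponential (flagged `single=True`) if no
two-component start converges.

**F/F0** divides by the mean of *all* pre-onset samples (no frame
exclusion) and re-references time so the last pre-onset sample is
t = 0. The baseline of every normalized trace therefore averages to
exactly 1 — asserted as an invariant. Background subtraction (scalar or
trace) is applied before normalization and never clipped, keeping
estimators unbiased at the cost of admitting negative values.

**Segmentation.** The discrete Laplacian kernel is fixed as
`[[0,1,0],[1,−4,1],[0,1,0]]`, negated so bright blobs respond
positively, with reflect boundary handling (the kernel sums to zero, so
detection is exactly invariant to adding a constant). The threshold is
`k_sd` × SD of all Laplacian pixels (default 3.0), components use
8-connectivity with a 2–100 px area window, and each ROI is centered at
its brightest average-image pixel (row-major order breaks ties). These
constants are configuration, not claims — the source workflow states
only "a multiple of the standard deviation". Because the 3×3 Laplacian
amplifies independent pixel noise by √20 while responding weakly to
σ ≈ 1.5 px spots, detection operates on the temporal average of a
stack (100 frames by default), where per-pixel noise is ~10× smaller
than in single frames; this mirrors how the segmentation was used in
practice. Background ROIs are 3×3 windows at a Chebyshev offset
(default 5 px) in the first seed-shuffled compass direction whose
window is in-image and overlaps no punctum.

**Classification.** Feature vector = the full z-scored trace (the
clustering targets "changes in fluorescence over time", not summary
statistics); Ward linkage on Euclidean distance, cut at two clusters.
The cluster with the higher mean F/F0 in the stimulus window is the
responder candidate; if its mean peak ΔF/F0 does not exceed
`min_response` (default 2× the pooled pre-onset SD) all traces are
labeled non-responding. This guard replaces the original manual
verification step, which is not reproducible in software. With one
trace the guard alone decides; identical traces (degenerate clustering)
fall through to the guard.

**Kinetics.** Initial slope is the least-squares slope over the first
3 post-onset samples (configurable; the window was never defined by the
source workflow). Peak is measured on the raw normalized trace — no
smoothing by default. AUC integrates `F/F0 − 1` above the fixed
baseline 1 over 2 s with linear interpolation at the window edges.
Decay fits start at the peak, compare one vs two components by
small-sample-corrected AIC with a 2-unit parsimony margin (models
within 2 AICc units are treated as equivalent and the single
exponential wins), and additionally reject "phases" that are not
physically meaningful: components holding <5% of the total amplitude or
with τ below the sampling interval (a one-sample spike) demote the fit
to single. The fast τ is the single τ or the smaller of the two.
Sigmoid stimulus–response fits use the 4-parameter logistic
`y = base + (top − base)/(1 + e^((x50 − x)/rate))` with multi-start on
`x50`; constant responses are returned flagged degenerate rather than
failing.

**Flat-field and mosaics.** "Kernel of 121 pixels" is interpreted as
the support of the Gaussian (σ = 121/6 ≈ 20 px, truncated at the 60-px
radius); σ is configurable since the original convention is ambiguous.
The reference is the blurred pixelwise tile average normalized to mean
1, so correction preserves the global intensity scale. Tile
registration is *not* recomputed: tiles are placed at their nominal
grid positions (stride = tile × (1 − overlap), rounded), which is exact
for the generator's tiles; overlaps blend by distance-to-edge weights
and single-coverage pixels copy the tile value verbatim. The reference
tracks the true vignette faithfully only when the vignette is smooth at
the blur scale — i.e. on camera-scale (≥ ~500 px) tiles; on small tiles
the blur flattens the vignette itself and residual corner error grows
to several percent. Ratio images mask pixels whose background-subtracted
denominator is non-positive instead of emitting infinities; masks
propagate to CSV as empty cells.

**Colocalization.** Pearson r of paired line-profile intensities with a
two-sided p-value from the t-transform with n − 2 degrees of freedom.

## Determinism

Every generator and the full pipeline are pure functions of
(parameters, seed) using `numpy.random.default_rng`; the pipeline
manifest records the config, seed and SHA-256 of every artifact, and
identical config + seed reproduce identical checksums.

## Validation problem sizes

The test and acceptance studies use: 200-sample bleach controls
(noiseless flatness to 1e-6 relative; 20 noisy replicates at 2% noise
for τ1 recovery), 1,000 random traces for the F/F0 contract, 20 bouton
fields of 40 spots (64 × 256, 100 frames, spot amplitude 8× per-frame
noise SD, ≥6 px spacing, 2 px matching radius) for segmentation, 20
sets of 100 traces (30% responders, peak SNR ≈ 6.5) plus 20 pure-noise
sets for classification, 20 replicates per τ ∈ {0.2, 0.5, 1, 2} s at
SNR 10 sampled at τ/20 for decay recovery with 50 replicates for model
selection, 2 × 2 grids of ~500 px tiles for flat-field/stitching, and
duplicate end-to-end pipeline runs for checksum determinism.

## Known limitations

* No motion correction, drift registration, or watershed splitting of
  touching boutons.
* The clustering is fixed at two clusters; richer response taxonomies
  are out of scope.
* F/F0 is not converted to absolute calcium concentration (no
  calibration constants are assumed).
* Tile registration relies on the declared layout; misaligned stages
  would require an external registration step.
* The saturation cap is phenomenological; it does not model indicator
  binding kinetics.
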