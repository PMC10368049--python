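# Methods

## Scope and model

`opusmon` studies whether the depth of a thermal-ablation lesion can be
tracked from fibre-probe pulse-echo ultrasound alone.  The package closes
the loop entirely in software: a generative model produces RF A-lines with
the statistical structure such an experiment yields, the analysis chain
processes them into images and a depth trace, and the evaluation module
quantifies agreement between the tracked and the true depth.

### Generative model (M-mode)

Each A-line is a linear convolution model

```
a(t) = p(t) * r(t) + x(t) + n(t)
```

where `p` is a Gaussian-modulated sinusoid (centre 15 MHz, −6 dB fractional
bandwidth 0.6, chosen so its spectral support lies inside the 1.5–40 MHz
analysis band), `r` is a sparse reflectivity train, `x` is a static
early-time cross-talk/reverberation waveform, and `n` is white Gaussian
noise.  The reflectivity contains:

* a strong surface reflector (amplitude 1) at `surface_depth` (default 1 mm);
* speckle scatterers, uniformly positioned at 20/mm with zero-mean Gaussian
  amplitudes (std 0.1 relative to the surface echo);
* inside the current lesion interval, scatterer amplitudes multiplied by
  the echogenicity gain (default 2.5; the true echogenicity increase of
  ablated tissue is not quantified anywhere we know of, so this is a free,
  documented parameter — only its *recoverability* matters).

The lesion interval is centred on the fibre tip (7 mm below the tissue
surface) and its vertical extent follows a saturating exponential
`E(t) = E_max (1 − e^{−(t−t_on)/τ})` during the 60 s ablation (τ = 15 s),
zero beforehand and frozen after switch-off — a deliberately simple
stand-in for thermal lesion kinetics that reproduces the observed
behaviour (bidirectional growth, stable contrast after switch-off) without
any claim to bioheat realism.  Echo positions are deposited with linear
sub-sample interpolation, so echo times are exact to well below one sample.
Reflector amplitudes enter linearly, output is bit-reproducible for a fixed
config and seed, and the early cross-talk block is identical in every
acquisition — these are tested invariants.

Timeline defaults mirror the monitoring protocol: imaging starts 10 s
before the laser, runs through the 60 s ablation and 10 s beyond, at a
100 Hz pulse repetition frequency.  Sampling defaults: 125 MHz (Nyquist-safe
for 40 MHz content, enforced), sound speed 1540 m/s; both configurable.

Noise std defaults to 0.002 (≈34 dB below the speckle envelope): fibre-tip
optical resonator receivers reach mPa-scale noise-equivalent pressures
against MPa-scale transmitted pulses, so speckle, not electronic noise,
dominates a well-functioning probe.

### What the generator does *not* emulate

Full wave propagation (diffraction, refraction, multiple scattering),
frequency-dependent attenuation, transducer directivity, tissue motion, and
temporal decorrelation of the heated region (bubble "twinkling").  The last
point matters for interpretation: in this model the speckle pattern inside
the lesion is static over time, so its interference nulls are static too,
which is the worst case for intensity-threshold segmentation (a null never
averages out).  Passing tests therefore show that the chain recovers depth
from speckle statistics of the assumed form; they do not certify
performance on real tissue, where clutter is richer but lesion speckle also
decorrelates.

## Analysis chain

1. **Band-pass** 1.5–40 MHz Butterworth (order-4 band-pass design), applied
   forward-backward (`sosfiltfilt`) so the envelope timing is not skewed by
   filter group delay.  The same design serves M-mode and B-mode.
2. **GLM static-signal removal.**  The regressors are the mean pre-ablation
   A-line and its ±1-sample shifted copies (jitter absorption); each
   acquisition gets ordinary-least-squares coefficients and the fitted
   static component is subtracted.  The coefficients are *estimated* on the
   shallow block above the tissue surface (cross-talk, needle
   reverberation, surface echo — physically incapable of containing
   lesion), then the subtraction spans the whole A-line.  Fitting on the
   whole record instead lets the growing lesion bias the template gain
   (≈40 % on default data) and leak uncancelled static speckle across all
   depths; the windowed fit suppresses the static block by ≳35 dB while
   perturbing the lesion-band signal by ≲0.02 dB (both measured by the
   acceptance script on labelled data).
3. **Envelope + log compression.**  Magnitude of the analytic signal,
   normalised to the global maximum, expressed in dB and floored at the
   display dynamic range (default 40 dB).
4. **Segmentation.**  Standard FCM on pixel intensities (fuzziness m = 2,
   relative cost tolerance 1e−5, max 300 iterations).  Two clusters by
   default: after GLM cancellation the image has exactly two intensity
   populations — residual background and lesion — so a third (tissue)
   cluster would only split the lesion's wide Rayleigh-in-dB spread and
   cost the mask its dim half.  Initialisation draws c distinct pixel
   values as starting centroids (seeded); random *membership*
   initialisation is degenerate on large images, because every initial
   centroid then collapses to the image mean.  Coincident pixel/centroid
   distances get one-hot memberships.  The cost is asserted non-increasing
   at every iteration.  The lesion cluster is the one with the greatest
   centroid; hard assignment by maximum membership.
5. **Morphology.**  Opening with a 3×3 square removes isolated
   false-positive pixels; closing bridges the static interference nulls
   that cut the lesion into horizontal speckle bands.  The closing element
   is therefore sized physically — 0.22 mm half-extent, about twice the
   axial speckle cell — rather than in raw pixels (a 3×3 element spans
   18 µm on the native grid and cannot affect speckle-scale structure).
   Square-element erosion/dilation are computed as separable moving
   min/max filters, which is exact and fast.  Only the largest 4-connected
   component is kept.
6. **Depth trace.**  Per column, depth = (row_max − row_min + 1) × axial
   pitch over the retained component — the full vertical extent, matching
   bidirectional growth from the tip (not distance from the surface).  The
   reported depth is the median over the 10 columns after laser switch-off,
   where contrast is stable.

### B-mode

The scan chain runs band-pass → TGC (`10^(α f_ref 2d/20)`, α in
dB·cm⁻¹·MHz⁻¹, gain capped at 40 dB) → GLM (reference = all scan
positions; only laterally static content survives the averaging) → Stolt
f–k migration → envelope/log.  The migration uses the exploding-reflector
equivalence (propagation speed c/2), linear spectral interpolation, ×2
zero-padding in both axes against wrap-around, and implicit evanescent-
component rejection (the remap never samples `|f| < (c/2)|kx|`).  The
output grid is the native (axial sample, scan position) grid; no scan
conversion.  An independent delay-and-sum beamformer (per-pixel two-way
delay, linear interpolation, no apodization) serves as the reference
implementation: point-target peaks agree within one pixel and −6 dB
lateral widths within 30 %.

### Statistics

The paired two-tailed t-test uses the sample (n−1) standard deviation and
the Student tail computed from the regularized incomplete beta function,
`P(T>t) = I_{ν/(ν+t²)}(ν/2, ½)/2`; it agrees with reference tables to
better than 1e−10.  Zero-variance differences degenerate explicitly:
identical series give (t=0, p=1), a constant nonzero difference gives
infinite |t| and p=0.  The regression slope is reported both with an
intercept (default) and through the origin, since "slope of the linear
fit" is ambiguous between the two conventions.

## Problem sizes and numerical choices

Batch studies (tests and the acceptance script) simulate at a 25 Hz A-line
rate instead of 100 Hz — 2 000 instead of 8 000 columns per procedure —
keeping the timeline, depths and all other conditions unchanged; one
procedure is then ~4.4 M pixels and the full loop takes a few seconds.
The acceptance study runs 19 procedures (the protocol's repetition count)
with truth extents spanning 3.3–8.3 mm; the test suite runs 10.

Ties and degenerate inputs: all-constant images are rejected by FCM
(fewer distinct values than clusters); empty mask columns yield depth 0;
an all-zero record log-compresses to the dynamic-range floor; configs whose
lesion would outgrow the sampled window are rejected up front, as are
filter edges at or above Nyquist and non-uniform or too-short (<4
position) scans.

## Known limitations

* Depth accuracy is limited by edge-scatterer statistics: the outermost
  ~0.2 mm of a lesion edge is invisible when its scatterers happen to be
  weak, so individual procedures occasionally miss the truth by up to
  ~0.4 mm even though the batch mean error is ~0.06–0.1 mm and the
  bias is statistically indistinguishable from zero.
* The FCM threshold is global; depth-dependent gain (uncompensated in
  M-mode, where TGC is off by default) would shift it.
* The GLM assumes the static scene is truly static; probe motion would
  require the shifted-template regressors to do real work, which the
  simulator does not exercise.
* The Stolt implementation is validated against delay-and-sum, not against
  any particular published k-space variant; windowing/weighting details
  differ between formulations.
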