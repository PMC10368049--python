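# opusmon

Simulation and analysis of fibre-probe **all-optical ultrasound (OpUS)**
monitoring of **laser interstitial thermal therapy (LITT)**.

During interstitial laser ablation, heated tissue becomes more echogenic
(stiffness changes, bubble formation), so a thermal lesion appears on
pulse-echo ultrasound as a region of increased brightness growing
bidirectionally from the ablation-fibre tip.  `opusmon` implements the full
analysis loop needed to study image-based lesion-depth tracking for this
setting, for researchers working on interventional ultrasound monitoring:

* **`opusmon.simulate`** — synthetic RF A-line generation: band-limited
  Gaussian pulses convolved with point-scatterer reflectivity, a bright
  tissue-surface echo, static transmitter–receiver cross-talk and needle
  reverberation, white noise, and a lesion of increased echogenicity growing
  from a fibre tip ~7 mm below the surface during a 60 s ablation
  (M-mode), plus stepwise lateral scans over point targets (B-mode).
* **`opusmon.preprocess`** — zero-phase Butterworth band-pass (1.5–40 MHz),
  time gain compensation, general-linear-model (GLM) removal of
  time-invariant signal (cross-talk, reverberation, unablated tissue), and
  Hilbert-envelope log compression.
* **`opusmon.mmode`** — M-mode image assembly and lesion segmentation:
  fuzzy c-means (FCM) clustering of pixel intensities minimising
  `J = Σᵢⱼ uᵢⱼᵐ (xᵢ − vⱼ)²`, hard assignment to the brightest cluster,
  morphological opening/closing with a largest-component rule, and a
  per-acquisition depth trace (vertical lesion extent in mm).
* **`opusmon.bmode`** — synthetic-aperture reconstruction by Stolt (f–k)
  migration under the exploding-reflector model
  (`f = (c/2)·√(kx² + kz²)` with Jacobian weighting), validated against an
  independent delay-and-sum beamformer.
* **`opusmon.evaluate`** — agreement statistics between two depth
  measurement sets: two-tailed paired t-test (Student tail via the
  regularized incomplete beta function) and least-squares slope, plus probe
  geometry helpers (`beam_divergence_deg`, `scan_aperture_mm`) and the
  end-to-end depth-recovery study.
* **`opusmon.io` / CLI `opusmon`** — HDF5 record/image containers, YAML
  pipeline configuration with strict key checking, and `simulate`,
  `process-mmode`, `process-bmode`, `segment`, `evaluate`, `run`
  subcommands.

## Worked example

```python
import numpy as np
from opusmon import simulate_mmode, track_lesion_depth, FCMParams
from opusmon.evaluate import study_config, depth_recovery_study

# one monitoring procedure: 10 s lead-in, 60 s ablation, 10 s tail
cfg = study_config(final_extent_mm=5.8, rng_seed=1)
record, truth = simulate_mmode(cfg)
image, mask, trace = track_lesion_depth(
    record, laser_on_s=cfg.laser_on_time,
    laser_off_s=cfg.laser_on_time + cfg.laser_duration,
    fcm_params=FCMParams(seed=1), glm_fit_depth_mm=cfg.surface_depth + 0.5,
)
print(f"true lesion extent : {truth.final_extent_mm:.2f} mm")
print(f"tracked depth      : {trace.final_depth_mm:.2f} mm")

# a batch of procedures spanning the 3.3-8.3 mm lesion-size range
res = depth_recovery_study(np.linspace(3.3, 8.3, 10), seed=0)
r = res.report
print(f"10 procedures: mean |error| = {res.abs_error_mm.mean():.3f} mm, "
      f"max |error| = {res.abs_error_mm.max():.3f} mm")
print(f"paired t = {r.t_statistic:.2f}, p = {r.p_value:.2f}, slope = {r.ols_slope:.3f}")
```

This prints:

```
true lesion extent : 5.80 mm
tracked depth      : 5.85 mm
10 procedures: mean |error| = 0.055 mm, max |error| = 0.161 mm
paired t = 0.64, p = 0.54, slope = 1.023
```

The tracked post-ablation depth agrees with the generator's ground truth to
well under the axial speckle scale, and across the batch the paired t-test
shows no systematic bias (p ≫ 0.05) with a near-unity regression slope —
the image-based measurement tracks the true lesion depth.

The same loop from the shell:

```bash
opusmon run --seed 1 --out results/demo     # writes record, image, mask,
                                            # depth_trace.csv, report.json
```

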