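# radialtherm

Continuous, ungated golden-angle radial MR thermometry for monitoring
radiofrequency (RF) cardiac ablations, with simultaneous catheter
micro-coil tracking and intra-scan rigid motion correction.

RF ablation creates a thermal lesion at a catheter tip; proton resonance
frequency (PRF) shift thermometry reads the temperature change from the
phase of a gradient-echo acquisition, `ΔT = Δφ / (2π γ B₀ α TE)` with
`α ≈ −0.01 ppm/°C`.  In the beating heart this requires three things at
once: continuous acquisition that never waits for an ECG trigger,
knowledge of the cardiac/respiratory motion, and temperature maps faster
than 1 s.  `radialtherm` implements a complete pipeline for this setting:

1. **Golden-angle radial acquisition** — consecutive spokes rotated by
   180°/φ ≈ 111.25°, one spoke per TR, so *any* contiguous window of
   spokes has near-uniform angular coverage.
2. **Catheter micro-coil tracking** — two tiny receive coils in the
   catheter produce near-delta projection profiles; two consecutive
   projections localize each coil in 2D at a temporal resolution of
   2 TR ≈ 48 ms.  Gaussian filters at 0.883/0.377 Hz split the curves
   into filtered, respiratory and cardiac components; the peak intensity
   is a qualitative through-plane ("Z") surrogate usable for gating.
3. **Per-spoke rigid motion correction** — each projection is corrected
   by a k-space phase ramp
   `K·exp(i 2π k_r (Δx cos ρ + Δy sin ρ)/FoV)`, the exact Fourier-shift
   inverse of the tracked in-plane displacement.
4. **Motion-state multibaseline library** — pre-heating spokes are binned
   by motion state (10 amplitude bins, or 8 respiratory × 3 cardiac
   phases) and reconstructed into complex baseline images `x_b`.
5. **Direct k-space temperature fitting** — each undersampled window of
   20/30/40 spokes (0.48/0.72/0.97 s) is fitted with the hybrid
   multibaseline + referenceless model

   ```
   y = E[(Σ_b x_b w_b) · e^{i(Ac + θ)}] + ε
   min  ½‖y − model‖² + λ‖θ‖₁ + β θᵀDᵀDθ
   ```

   where `E` samples the image spectrum at the window's spoke locations,
   `A` is an orthonormal 6th-order polynomial basis absorbing B₀ drift,
   and `θ` is the sparse heating phase.  Per-resolution defaults
   `(λ, β)` are (0.1, 0.05) at 1 mm, (0.2, 0.05) at 2 mm, (0.5, 0.05) at
   3 mm; resolutions are produced by k-space readout truncation, giving
   radial acceleration factors from 2.88 to 17.28.

A fully synthetic acquisition simulator (known motion, heating, coil
sensitivities, background phase, noise) makes every stage testable from
scratch; it applies rigid motion *exactly* as a k-space phase ramp, so it
doubles as an analytic oracle for the correction operator.

Intended users: MR-physics researchers working on interventional
thermometry, radial reconstruction, or self-gated motion handling.

## Worked example

```python
import numpy as np
from radialtherm import *
from radialtherm.simulate import default_params
from radialtherm.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    scene={"matrix": 48, "fov_mm": 96.0,
           "motion": {"kind": "square_wave", "amplitude_mm": (26.0, 0.0),
                      "frequency_hz": 0.33}},
    seed=4, learning_s=20, stability_s=10, heating_s=15, post_s=2,
    resolutions_mm=(3.0,), windows=(40,), max_frames=18))
w = summary["resolutions"]["3mm"]["windows"]["40"]
print(w["frame_spacing_s"], w["acceleration"], w["roi_sd_mean_degC"],
      w["peak_delta_t_degC"])
```

prints

```
0.9656 1.26 0.036 9.76
```

i.e. 40-spoke frames every 0.9656 s (an acceleration of 1.26 at this
desk-scale 3 mm matrix), a background temperature uncertainty of
0.04 °C over the stability span, and a peak elevation of 9.8 °C reached
by the short 15 s heating ramp fitted here.  The same entry point scales
to the full protocol (60 s ramp, 2 mm/1 mm resolutions, 2D binning) —
see `radialtherm.experiments` for the ready-made study protocols.

A command-line interface mirrors the library stages:

```bash
radialtherm simulate --config scene.yaml --out sim.h5 --seed 7
radialtherm track sim.h5 --coils both --out motion.csv
radialtherm preprocess sim.h5 --motion motion.csv --variance 0.9 --out corr.h5
radialtherm recon corr.h5 --resolution 2 --out img.h5
radialtherm thermo corr.h5 --resolution 3 --window 40 --out temp.h5
radialtherm run --config run.yaml --out results/
```

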