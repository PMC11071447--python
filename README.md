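# capflow

Analytics for flow-rate paper-microfluidic immunoassays. The assay this
package supports measures a protein biomarker (e.g. eNAMPT, an
inflammatory marker relevant to ARDS) in diluted blood or plasma without
capturing anything on the strip: antibody-conjugated particles are
preloaded in wax-printed paper channels, the sample wicks through, and
antigen-mediated particle immunoagglutination changes the liquid
properties at the wetting front — so the *capillary flow rate itself* is
the signal. A smartphone video of the chip is the raw data.

`capflow` provides the full computational chain, locally and fully
tested:

- **`flow_tracking`** — wetting-front extraction from videos or image
  stacks: per-channel front position *L* (cm) versus frame.
- **`lw_model`** — Lucas–Washburn flow modeling. Horizontal imbibition
  follows *L* = √(*D t*) with *D* = *R γ*<sub>LG</sub> cos *θ* / 2*μ*;
  the module estimates *D* pointwise (*L*²/*t*) and by window fits, and
  picks the optimal detection frame (half the early/late crossover).
- **`agglutination`** — the five-species mass-action kinetic model
  (Abp, Ag, Abp·Ag, Abp₂·Ag, Abp·Ag₂) whose Abp₂·Ag output reproduces
  the rise–plateau–hook dose response and the curve shift with particle
  concentration.
- **`calibration`** — Welch t-tests, limit of detection, 4-parameter
  logistic calibration, linear-range search, low/middle/high tier
  classification, and diluted ↔ undiluted concentration arithmetic.
- **`synth`** — ground-truth generators (profiles, rendered videos,
  replicate assay tables) chaining agglutination → interfacial tension →
  diffusion coefficient → flow distance, so everything runs offline.
- **`capflow`** CLI — `track`, `fit`, `simulate`, `calibrate`,
  `classify`, `synth`, `run`.

## Worked example

```python
from dataclasses import replace
from capflow import synth, lw_model, calibration as cal

cfg = synth.SynthConfig(seed=0, noise_sd_cm=0.005)

# two-regime flow: high D in the early (agglutination-sensitive) stage
profile, truth = synth.gen_profile(cfg)
fit_early = lw_model.fit_lw(profile, (0, 50))
fit_all = lw_model.fit_lw(profile, (0, 299))

# pick the detection frame from a family of profiles
families = {c: [synth.gen_profile(replace(cfg, seed=c))[0]] for c in range(4)}
frame = lw_model.select_detection_frame(families, "halfway")

# a full replicate assay: signal = flow distance at the detection frame
dr, gt = synth.gen_assay(cfg, [0, 1, 5, 10, 20, 50, 100, 500, 1000],
                         n_replicates=8, detection_frame=frame)
lod = cal.find_lod(dr)
lin = cal.linear_range(dr)
```

This prints:

```
D (first 50 frames) = 1.002 cm^2/s
D (all 300 frames)  = 0.349 cm^2/s
ratio               = 2.87
detection frame     = 25
LOD                 = 1.0 pg/mL
linear range        = 0-50 pg/mL (R^2 = 0.978)
LOD in whole sample = 10 pg/mL (at 10% dilution)
```

Reading the numbers: the early-window diffusion coefficient is ~3×
higher than the all-frame fit, which is why the early flow stage carries
the concentration information; the crossover sits at frame 50, so the
detection frame lands at 25 (~1 s at 30 fps); on the synthetic assay the
lowest concentration distinguishable from the negative control (Welch
t-test, *P* < 0.05, *n* = 8) is 1 pg/mL, the response is linear up to
the hook peak at 50 pg/mL, and the dilution arithmetic converts the LOD
back to the undiluted specimen.

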