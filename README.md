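# aslquant

Arterial spin labelling (ASL) hemodynamic quantification with a venous twist:
voxel-wise cerebral blood flow (CBF) and bolus arrival time (BAT) mapping,
high-signal sagittal-sinus ROI analysis, and the group/oxygen-content/cognition
statistical stage — validated end to end on a synthetic digital-phantom cohort.

## Who this is for

Perfusion MRI researchers studying cerebrovascular stress in chronic anemia
(the motivating population is pediatric/young-adult sickle cell anemia, SCA).
In anemia, compensatory hyperperfusion shortens arterial transit, and abnormally
high ASL signal in the sagittal sinus suggests labelled blood shunting through
the microvasculature without exchanging with tissue. Quantifying venous ASL
signal — and relating it to arterial oxygen content and cognition — requires a
pipeline that does not clip the extreme apparent flows and late arrival times
seen in draining veins. That is what this package provides, together with a
simulator that generates fully analyzable synthetic cohorts for validation.

## Models

**Single-delay pCASL** (labelling duration τ = 1.8 s, post-labelling delay
PLD = 1.5 s, α = 0.85, λ = 0.9) uses the consensus quantification

```
CBF = 6000 · λ · ΔM · e^(PLD/T1b) / (2 · α · T1b · M0 · (1 − e^(−τ/T1b)))   [mL/100g/min]
```

**Multi-inflow-time PASL** (10 TIs, 350–2600 ms in 250 ms steps; Q2TIPS
saturation clips the bolus to τ = 0.7 s; α = 0.98, T1_tissue = 1.9 s) fits the
general kinetic model for a pulsed label jointly over (CBF, BAT) per voxel:

```
ΔM(t) = 0                                                     t < Δt
ΔM(t) = 2·M0b·f·α·(t−Δt)·e^(−t/T1b)·q_p(t)                    Δt ≤ t < Δt+τ
ΔM(t) = 2·M0b·f·α·τ·e^(−t/T1b)·q_s(t)                         t ≥ Δt+τ
```

with f = CBF/6000, 1/T1app = 1/T1_tissue + f/λ, k = 1/T1b − 1/T1app and the
usual q-factors; the k → 0 degeneracy is handled analytically, and a
quadrature convolution oracle (`pasl_kinetic_numeric`) verifies the closed
form. T1-blood is subject-specific, estimated from hematocrit and SpO₂
(anemic blood relaxes more slowly), and arterial oxygen content is
CaO₂ = 1.34·Hb·SaO₂ + 0.003·pO₂.

Downstream: ghost-free corner background statistics gate reliable voxels
(signal > mean + 1 SD on at least one volume), anatomical masks are eroded
with a width-2 box, the high-signal sinus ROI keeps voxels at or above the
90th percentile of the singleTI CBF map within the sinus mask, and the
statistics stage runs Shapiro-Wilk-gated t / Mann-Whitney comparisons,
age/sex-adjusted Pearson correlations with CaO₂, Benjamini-Hochberg FDR
within (group × map-family) strata, and covariate-adjusted cognition
regressions.

## Worked example

```python
import numpy as np
from aslquant import (AcquisitionSpec, PASLKineticParams, PCASLParams,
                      SubjectPhysiology, background_stats, fit_multiti,
                      make_phantom, mean_difference, quantify_singleti,
                      reliable_voxel_mask, simulate_series)

subject = SubjectPhysiology("demo", "SCA", age=16, sex="female",
                            hemoglobin=8.8, hematocrit=0.24, spo2=0.97)
print(f"CaO2 = {subject.cao2:.2f} mL/dL, T1_blood = {subject.t1_blood:.2f} s")

phantom = make_phantom(matrix=(32, 32, 6))
series = simulate_series(phantom, AcquisitionSpec.single_ti(matrix=(32, 32, 6)),
                         subject, noise_sd=0.5, seed=7)
maps = quantify_singleti(mean_difference(series), series.m0,
                         PCASLParams(t1_blood=subject.t1_blood),
                         mask=phantom.segmentation > 0)
gm = phantom.segmentation == 1
print(f"GM CBF: estimated {np.nanmean(maps.cbf[gm]):.1f} "
      f"vs planted {phantom.cbf_true[gm][0]:.1f} mL/100g/min")

multi = simulate_series(phantom, AcquisitionSpec.multi_ti(matrix=(32, 32, 6)),
                        subject, noise_sd=1.5, seed=8)
bg = background_stats(multi)
reliable = reliable_voxel_mask(multi, bg)
sinus = phantom.segmentation == 3
fit = fit_multiti(multi, multi.m0, PASLKineticParams(t1_blood=subject.t1_blood),
                  reliable & sinus, noise_floor=bg.threshold)
print(f"sinus BAT: median {np.nanmedian(fit.bat[sinus]):.2f} "
      f"vs planted {phantom.bat_true[sinus][0]:.2f} s")
```

Output:

```
CaO2 = 11.74 mL/dL, T1_blood = 1.99 s
GM CBF: estimated 54.0 vs planted 54.0 mL/100g/min
sinus BAT: median 1.16 vs planted 1.17 s
```

The anemic subject's oxygen content is low and their blood T1 long; the
single-delay map recovers the planted gray-matter perfusion, and the kinetic
fit recovers the late venous arrival time in the sinus tube.

A command-line surface mirrors the library:
`aslquant simulate|preprocess|quantify|extract|stats|run`, each with
`--seed`, `--out`, and an optional `--config` YAML.

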