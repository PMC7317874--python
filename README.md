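# mmtid

Voxel-wise diffusion **m**icrostructural-**m**odel vs **t**ime-**i**ndependent-**d**iffusion
model comparison for multi-diffusion-time PGSE MRI, with the **%MM**
biomarker and its in-silico technical validation.

## The problem

Diffusion-weighted MRI of tumors mixes qualitatively different
microenvironments: cellular tissue, where water is restricted inside
cells and the apparent diffusivity falls with diffusion time, and
necrotic or oedematous tissue, where diffusion is closer to free and
time-independent. A single model fitted everywhere is wrong somewhere.
`mmtid` fits **two** models to every voxel of a two-diffusion-time
pulsed-gradient spin-echo (PGSE) acquisition and asks which one the data
prefer:

* **MM** — a two-compartment microstructural model: water restricted in
  impermeable spheres of radius *R* (intracellular diffusivity *D<sub>i</sub>*,
  signal fraction *f<sub>i</sub>*) plus hindered extracellular water,

  *S(b, Δ) = f<sub>i</sub>·A<sub>sphere</sub>(R, D<sub>i</sub>; G, δ, Δ) + (1 − f<sub>i</sub>)·e<sup>−b·D<sub>e</sub></sup>*,

  where *A*<sub>sphere</sub> is the Gaussian-phase-distribution (GPD)
  attenuation for spheres (eigenvalues from roots of *j*₁′(x) = 0);
* **TID** — time-independent diffusion, *S = e<sup>−b·D′</sup>* across
  both diffusion times.

Fits use bounded multi-start Nelder–Mead after discarding signals below
twice the noise floor; per voxel the corrected Akaike criterion
(AICc, *k* = 4 vs *k* = 1) picks the preferred model. The fraction of
fittable ROI voxels preferring MM is the **%MM** biomarker, a proxy for
the non-necrotic tissue fraction. A *discrete-D<sub>i</sub>* strategy
(*D<sub>i</sub>* fixed in turn to 0.5…2.5 µm²/ms, best *R*² wins)
stabilizes the MM fit. Conventional ADC mapping, the ADC-threshold
classification sweep and Pearson correlation against an external
reference fraction (e.g. histology % necrosis) are included, as are the
two in-silico studies that quantify how well %MM and the parameter
estimates behave under Rician noise.

Intended users: quantitative-MRI researchers validating model-comparison
biomarkers, and anyone who needs a reproducible restricted-diffusion
sphere signal model with honest noise simulations.

## Worked example

```python
import numpy as np
from mmtid import (FitConfig, MMParams, add_rician_noise, fit_voxel_models,
                   mm_signal, rician_s_noise, select_model,
                   two_diffusion_time_protocol)

proto = two_diffusion_time_protocol()      # delta=4.65 ms, Delta=9.86/40 ms
truth = MMParams(R=10.0, Di=1.0, De=0.6, fi=0.41)
noisy = add_rician_noise(mm_signal(truth, proto), snr=54.0,
                         rng=np.random.default_rng(7))
mm_fit, tid_fit, mask = fit_voxel_models(
    noisy, proto, FitConfig(n_starts=25, seed=7),
    s_noise=rician_s_noise(54.0), strategy="discrete_di")
pref = select_model(mm_fit, tid_fit)
print(pref.name, mm_fit.params)
```

prints

```
MM MMParams(R=np.float64(6.769809604322162), Di=1.5, De=np.float64(0.6621038142588468), fi=np.float64(0.2287527839911719))
```

— the voxel is (correctly) classified as restricted diffusion. The
individual parameter estimates are noisy at this SNR (here *R* comes
back low and the discretized *D<sub>i</sub>* one step high — single-voxel
MM parameters are much less certain than the model label, which is
precisely what the fitting-accuracy study quantifies); the AICc scores
and retained-point count are on `pref` and the fits.
`examples/` has one short script per capability (protocols and
b-values, forward models, voxel fitting and selection, the %MM
validation study, the ADC threshold sweep); each prints the numbers it
computes and what they mean. The `mmtid` CLI (`fit`, `simulate`,
`adc-sweep`, `fixtures`) wraps the same functions for NIfTI volumes with
a JSON protocol sidecar.

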