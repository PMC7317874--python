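# Methods

## Signal models

**Acquisition.** Trapezoidal pulsed-gradient spin echo with gradient
amplitude G (mT/m), total lobe duration δ (ms, including both ramps of
length ε) and leading-edge separation Δ (ms). b-values are computed with
the rectangular-equivalent width δ_eff = δ − ε:

    b = γ² G² [ δ_eff² (Δ − δ_eff/3) + ε³/30 − δ_eff ε²/6 ],   γ = 2.6752219×10⁸ rad s⁻¹ T⁻¹ (¹H)

The built-in two-diffusion-time protocol (δ = 4.65 ms, Δ = 9.86/40.0 ms,
G = 0/113/207/293 mT/m, ε = 0.245 ms) yields b = 0/148.8/499.2/1000.2
and 0/683.2/2292.7/4593.5 s/mm², i.e. the nominal 150/500/1000 set after
rounding. Under this convention the ratio b(Δ₂)/b(Δ₁) at fixed G is
exactly constant (≈4.593). The residual ~0.8% gap at the weakest
gradient traces to the protocol's G values being printed as rounded
integers; the package always consumes its own computed b, so TID/ADC
fits and the MM extracellular term are internally consistent.

**MM (two-compartment microstructural model).**
S = f_i·A_sphere(R, D_i; measurement) + (1 − f_i)·exp(−b·D_e), with S = 1
at G = 0. The sphere attenuation uses the Gaussian-phase-distribution
(GPD) approximation with the impermeable-sphere eigenvalue expansion
(roots µ_m of j₁′(x) = 0; first three 2.08158, 5.94037, 9.20584):

    ln A = −2 γ²G² Σ_m  R⁶ / (D_i² µ_m⁶ (µ_m² − 2)) ·
            [ 2λ_m δ_eff − 2 + 2e^{−λ_m δ_eff} + 2e^{−λ_m Δ}
              − e^{−λ_m (Δ−δ_eff)} − e^{−λ_m (Δ+δ_eff)} ],     λ_m = D_i µ_m²/R²

The series is truncated at 30 roots (default); adding 10 more changes
the attenuation by <1e-8 on the built-in protocol. Two independent
codings exist — a numpy reference (`models.py`) and the compiled fitting
kernel (`_kernels.py`) — pinned to each other at 1e-12 by a unit test.

*Gradient ramps.* The closed form above treats each trapezoid as a
rectangle of width δ_eff. The exact trapezoidal-waveform GPD is also
implemented (`restricted_sphere_attenuation_waveform`): the correlation
integral I_m = ∫∫ g(t)g(t′)e^{−λ_m|t−t′|}dt dt′ is evaluated with an
exact exponential integrator for F′ = −λF + g on a grid aligned to the
waveform breakpoints, which is stable at arbitrarily large λ. At the
protocol's 0.245 ms ramps the two agree to ≤1.2e-4 attenuation
(<0.05%); the rectangular form is therefore the default in the fitting
path, where it is evaluated millions of times, and the waveform version
serves as the validation reference. Both sit within 2% of an independent
random-walk Monte-Carlo oracle (specular reflection inside a sphere,
phase accumulated under the true trapezoid) at the short diffusion time;
at the long diffusion time and strong attenuation the GPD approximation
itself drifts to ~2% absolute, a known regime limitation that affects
generator and fit identically and therefore cancels in model selection.

**TID.** S = exp(−b·D′) across both diffusion times; appropriate only
where diffusion is time-independent, which is exactly what the model
comparison tests.

**Conventional ADC.** On the single-diffusion-time protocol
(b = 150/500/1000 s/mm², no b = 0), S/S_ref = exp(−(b − b_ref)·ADC) with
the b≈150 measurement as reference so that perfusion-driven signal at
very low b cancels.

## Voxel pipeline

1. **Noise floor**: raw samples below 2·S_noise are discarded
   (multiplier configurable), where S_noise is the mean background
   magnitude; in a signal-free region magnitudes are Rayleigh with mean
   σ√(π/2), which also yields σ and SNR = mean b=0 ROI signal / σ.
2. **Normalization**: to the mean of the G = 0 measurements (TE is the
   same at both Δ). Both models are fitted to the identical retained
   point set, so their AICc values are comparable; b = 0 points are kept
   as residual points.
3. **Fitting**: unweighted SSE. MM uses multi-start Nelder–Mead (default
   100 starts; parameter/objective tolerances 1e-6, ≤2000 evaluations
   per start) run unconstrained in a sigmoid-transformed space, which
   enforces the bounds 0.1 ≤ R ≤ 25 µm, 0.1 ≤ D_i, D_e ≤ 3 µm²/ms,
   0.01 ≤ f_i ≤ 1. Start points are uniform over the box from a stream
   seeded by (seed, voxel index, start index): fits are bit-reproducible
   and best-of-starts is monotone in the start count. TID/ADC are 1-D:
   log-linear closed-form initialization plus bounded Brent refinement,
   keeping the better of the two — deterministic and globally optimal in
   practice (verified against dense grids).
4. **Strategies**: `fit_di` frees all four MM parameters; `discrete_di`
   fixes D_i in turn to {0.5, 1.0, 1.5, 2.0, 2.5} µm²/ms and keeps the
   fit with the highest R² (R² = 1 − RSS/TSS about the mean of the
   retained normalized signals; ties go to the lower D_i). Fixing D_i
   discretizes its map but stabilizes R, D_e, f_i.
5. **Extreme flagging**: a fit is "extreme" if any parameter lies within
   1% of a constraint. The margin is interpreted as a fraction of the
   parameter *range* (scale-free); a fraction-of-bound-value mode is
   also provided since the wording is ambiguous.
6. **Selection**: AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k = 4
   (MM) and k = 1 (TID) — the noise variance is not counted for either,
   so only the shared constant differs. MM wins on strictly lower AICc;
   exact ties and voxels where the MM correction is undefined
   (n ≤ k+1) go to the simpler TID model; voxels where neither model
   can be scored are "unfittable". An RSS floor of 1e-300 inside the
   log keeps numerically perfect noiseless fits comparable.
7. **%MM** = 100·#MM/(#MM + #TID) over the ROI (unfittable voxels
   excluded from both sides). Extreme MM fits still count toward %MM;
   they are excluded only from the MM parameter distributions and maps.

## Simulation studies

**Rician noise**: each sample is √((S+n₁)² + n₂²), n₁,n₂ ~ N(0, 1/SNR)
on signals normalized to unit b=0 expectation; SNR 54 is the default,
matching the mean in vivo value. Infinite SNR returns the clean signal
and disables the noise-floor screen.

**Fitting accuracy**: 96 microstructures (R = 5, 10 µm; D_i, D_e = 0.2,
1.1, 2.0, 2.9 µm²/ms; f_i = 0.25, 0.50, 0.75), by default 1500 noisy
repetitions each, both strategies; reports the median absolute
percentage parameter error and the accepted (non-extreme) fraction per
microstructure. Ground-truth D_i = 0.2 is below the discrete set, so
discrete-D_i carries an irreducible 150% D_i error there by
construction.

**%MM technical validation**: synthetic tumors at ground-truth %MM
10–90% (exact label counts), analysed with the identical pipeline;
reports mean ± SD and coefficient of variation of estimated %MM per
ground truth, plus confusion-matrix accuracy/sensitivity/specificity
with MM as the positive class. Full scale is 10 datasets × 200 voxels
per ground truth with 100 starts; the acceptance script and tests run a
desk-scale 3 × 200 with 10 starts (a few minutes on one CPU), which
this package's own measurements show reproduces the full-scale means
closely since 10 starts already find the discrete-D_i optima.

**Parameter pools.** The original in vivo voxel-level parameter
distributions are not available, so voxels are drawn from surrogate
pools built from the reported cohort summaries: R ~ N(10, 1²) µm,
f_i ~ N(0.41, 0.03²), D_e ~ N(0.6, 0.1²) µm²/ms (truncated to the fit
bounds), D_i uniform on the discrete set; TID D′ ~ U(1.0, 2.5) µm²/ms.
All pools are overridable (`ParameterPools`). These pools reproduce the
qualitative regime — exact identity at infinite SNR, very high
specificity and a noise-driven underestimation of %MM that grows with
the ground truth — but they are *narrower* than real voxel-level
spreads (they use the SDs of per-tumor medians), which places many
simulated MM voxels near the AICc decision boundary: with n = 8 points
an MM voxel needs roughly a tenfold RSS advantage to overcome the
k = 4 vs k = 1 penalty. Measured at SNR 54 this yields mean
sensitivity ≈ 48% and accuracy at 90% ground truth ≈ 52%, lower than
the ≥60% / ≈73% of a cohort with wider voxel-level contrast; the
pools were fixed before these measurements and are reported as is.
What passes here therefore validates the pipeline's correctness and the
direction and shape of the noise-induced %MM bias, not the exact bias
magnitude for any particular tissue.

**Synthetic data vs real data.** Voxels are independent (no spatial
correlation or partial volume), TE/T2 effects are ignored (f_i is a
signal fraction at fixed TE), noise is ideal Rician with known σ, and
the generator uses the same forward model family as the fit. Passing
tests therefore demonstrate pipeline correctness and noise behavior,
not robustness to model mismatch in tissue.

## Defaults and numerical choices

| Parameter | Default | Why |
|---|---|---|
| GPD roots | 30 | series converged far below fitting noise |
| starts (full / desk) | 100 / 10 | reference pipeline / verified sufficient for discrete-D_i |
| NM tolerances | 1e-6 (x and f), 2000 evals | bounded-simplex reference behavior |
| noise-floor multiplier | 2 | standard magnitude-bias mitigation |
| discrete D_i set | 0.5…2.5 µm²/ms step 0.5 | compromise between free and single fixed D_i |
| extreme margin | 1% of range | scale-free reading of "within 1% of the constraints" |
| SNR | 54 | mean in vivo b=0 SNR |
| ADC sweep grid | 0.10–3.00, step 0.01 µm²/ms | fit range; cut-off resolution of the in vivo analysis |

Degenerate inputs: protocols without a normalization reference are
rejected at load; voxels whose retained points cannot support a model
(n < free parameters + 1, or reference below the floor) are flagged
unfittable rather than guessed; confusion-matrix rates whose class is
absent are NaN, never 0.

## Known limitations

- GPD accuracy degrades (~2%) at long diffusion time × strong gradient;
  irrelevant for model selection here (shared by generator and fit) but
  relevant if absolute attenuations are compared to other simulators.
- The discrete-D_i map cannot represent D_i < 0.5 µm²/ms, and D_i is
  weakly identifiable from PGSE data generally.
- %MM depends on SNR by construction (the AICc penalty is fixed while
  the evidence scales with SNR); values from different SNRs are not
  comparable. The in vivo ADC cut-off (≈1.07 µm²/ms) is
  protocol- and cohort-specific and is not treated as reproducible.
- No compartmental T2, permeability, cylinders, oscillating gradients,
  IVIM perfusion, spatial regularization, or Rician-likelihood fitting.
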