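"""Fit one noisy voxel with both models and pick the winner by AICc.

An MM-generated voxel at the in vivo SNR of 54: signals below twice the
noise floor are discarded, both models are fitted to the retained
points, and the lower corrected Akaike score decides the label.
"""

import numpy as np

from mmtid import (FitConfig, MMParams, add_rician_noise, fit_voxel_models,
                   mm_signal, rician_s_noise, select_model,
                   two_diffusion_time_protocol)

proto = two_diffusion_time_protocol()
truth = MMParams(R=10.0, Di=1.0, De=0.6, fi=0.41)
rng = np.random.default_rng(7)
noisy = add_rician_noise(mm_signal(truth, proto), snr=54.0, rng=rng)

config = FitConfig(n_starts=25, seed=7)
mm_fit, tid_fit, mask = fit_voxel_models(
    noisy, proto, config, s_noise=rician_s_noise(54.0), strategy="discrete_di")
pref = select_model(mm_fit, tid_fit)

print(f"retained {mask.sum()}/{len(proto)} points above the noise floor")
print(f"MM  fit: {mm_fit.params}  rss={mm_fit.rss:.2e}  AICc={pref.aicc_mm:.1f}")
print(f"TID fit: {tid_fit.params}  rss={tid_fit.rss:.2e}  AICc={pref.aicc_tid:.1f}")
print(f"preferred model: {pref.name} (truth: MM)")
# The four-parameter MM must beat the one-parameter TID by a wide rss
# margin to overcome the AICc complexity penalty — with noise, true MM
# voxels are therefore sometimes labelled TID, the mechanism behind the
# %MM underestimation quantified in example 04.
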