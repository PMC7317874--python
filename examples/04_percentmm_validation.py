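"""Desk-scale %MM technical validation (bias, precision, confusion matrix).

Synthetic tumors mixing MM and TID voxels are generated at several
ground-truth %MM levels, with Rician noise at the in vivo SNR of 54, and
analysed with the same noise-floor / fit / AICc pipeline as real data.
This is a small, fast configuration; the full study uses ground truths
10-90%, 10 datasets of 200 voxels each, and 100 fit restarts.
"""

from mmtid import FitConfig, run_percentmm_validation

summary = run_percentmm_validation(
    ground_truths=(20, 50, 80),
    n_datasets=2,
    n_voxels=60,
    snr=54.0,
    config=FitConfig(n_starts=10),
    seed=3,
)
cols = ["ground_truth", "percent_mm_mean", "percent_mm_sd", "cov_percent",
        "accuracy_mean", "sensitivity_mean", "specificity_mean"]
print(summary.by_ground_truth[cols].round(2).to_string(index=False))
# Estimated %MM sits on the identity line without noise but is biased
# low at SNR 54, increasingly so at high ground truth: true TID voxels
# are rarely mislabelled (high specificity) while true MM voxels are
# often mislabelled TID (lower sensitivity).
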