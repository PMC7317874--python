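"""Synthetic NIfTI fixture sets for end-to-end runs and tests.

The default fixture is a small synthetic "tumor" with an MM rim and a
TID core — echoing the in vivo observation that the time-independent
model is preferred in central (necrotic) regions while restricted
diffusion dominates the rim — written as a 4-D NIfTI volume with a JSON
protocol sidecar, ROI/background masks and ground-truth label maps.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .models import mm_signal, tid_signal
from .protocol import save_protocol, two_diffusion_time_protocol
from .simulate import ParameterPools
from .selection import MM, TID


def make_fixtures(out_dir, shape=(16, 16, 3), snr: float = math.inf,
                  seed: int = 0, s0: float = 1000.0,
                  pools: ParameterPools | None = None) -> dict:
    """Write a rim/core synthetic tumor fixture set; returns the paths.

    The ROI is a centered square region; its inner third is TID
    ("necrotic core", D' drawn from the TID pool) and the surround is MM
    (parameters drawn from the MM pools). Signals are scaled to ``s0``
    arbitrary units; at finite SNR, Rician noise with
    sigma = s0/snr is added everywhere and the volume corners provide a
    signal-free background region for noise estimation.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pools = pools or ParameterPools()
    rng = np.random.default_rng(seed)
    protocol = two_diffusion_time_protocol()
    nx, ny, nz = shape

    roi = np.zeros(shape, dtype=bool)
    m = max(2, nx // 8)
    roi[m:nx - m, m:ny - m, :] = True
    core = np.zeros(shape, dtype=bool)
    c = max(3, nx // 3)
    core[c:nx - c, c:ny - c, :] = True
    core &= roi
    rim = roi & ~core

    background = np.zeros(shape, dtype=bool)
    background[:m, :m, :] = True
    background[-m:, -m:, :] = True

    signals = np.zeros(shape + (len(protocol),))
    truth = np.zeros(shape)
    true_params = {k: np.full(shape, np.nan) for k in ("R", "Di", "De", "fi", "Dprime")}
    for ijk in map(tuple, np.argwhere(roi)):
        if rim[ijk]:
            p = pools.sample_mm(rng)
            signals[ijk] = mm_signal(p, protocol)
            truth[ijk] = MM
            for k in ("R", "Di", "De", "fi"):
                true_params[k][ijk] = getattr(p, k)
        else:
            p = pools.sample_tid(rng)
            signals[ijk] = tid_signal(p, protocol)
            truth[ijk] = TID
            true_params["Dprime"][ijk] = p.Dprime
    signals *= s0
    if not math.isinf(snr):
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, signals.shape)
        n2 = rng.normal(0.0, sigma, signals.shape)
        signals = np.sqrt((signals + n1) ** 2 + n2**2)

    aff = np.eye(4)
    paths = {}

    def _save(name, arr):
        p = out / name
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff), str(p))
        paths[name] = p

    _save("dwi.nii.gz", signals)
    _save("roi.nii.gz", roi.astype(np.float64))
    _save("background.nii.gz", background.astype(np.float64))
    _save("truth_preference.nii.gz", truth)
    for k, arr in true_params.items():
        _save(f"truth_{k}.nii.gz", arr)
    save_protocol(protocol, out / "protocol.json")
    paths["protocol.json"] = out / "protocol.json"
    meta = {
        "seed": seed, "snr": None if math.isinf(snr) else snr, "s0": s0,
        "shape": list(shape), "n_roi": int(roi.sum()),
        "n_mm": int(rim.sum()), "n_tid": int(core.sum()),
        "ground_truth_percent_mm": 100.0 * rim.sum() / roi.sum(),
    }
    with open(out / "fixture.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    paths["fixture.json"] = out / "fixture.json"
    return paths
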