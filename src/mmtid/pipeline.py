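"""Whole-volume analysis: batch fitting, selection and map assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitConfig, Strategy, fit_adc, fit_voxel_models
from .protocol import DWIVolume, estimate_snr
from .selection import build_maps, summarize_roi


def _resolve_s_noise(dwi: DWIVolume, s_noise: float | None):
    """Explicit noise level wins; otherwise derive it from the background."""
    if s_noise is not None:
        return s_noise
    if dwi.background_mask is not None and dwi.background_mask.any():
        return estimate_snr(dwi).s_noise
    return None


def fit_volume(dwi: DWIVolume, config: FitConfig,
               strategy: Strategy = "discrete_di",
               s_noise: float | None = None) -> dict:
    """Voxel-wise MM/TID fitting and AICc selection over the ROI.

    Returns a dict with ``maps`` (R, Di, De, fi, Dprime, preference),
    ``summary`` (SubregionSummary), ``table`` (per-voxel DataFrame) and
    the ``s_noise`` actually used (None = no noise-floor screen).
    """
    s_noise = _resolve_s_noise(dwi, s_noise)
    from .selection import select_model  # local import keeps module deps one-way

    shape = dwi.signals.shape[:3]
    idxs = np.argwhere(dwi.roi_mask)
    mm_fits, tid_fits, prefs = {}, {}, {}
    rows = []
    for ijk in map(tuple, idxs):
        vox = int(np.ravel_multi_index(ijk, shape))
        raw = dwi.signals[ijk]
        mm_fit, tid_fit, mask = fit_voxel_models(
            raw, dwi.protocol, config, s_noise, strategy, voxel_index=vox)
        pref = select_model(mm_fit, tid_fit)
        mm_fits[ijk], tid_fits[ijk], prefs[ijk] = mm_fit, tid_fit, pref
        rows.append({
            "i": ijk[0], "j": ijk[1], "k": ijk[2],
            "preference": pref.name,
            "aicc_mm": pref.aicc_mm, "aicc_tid": pref.aicc_tid,
            "n_used": mm_fit.n_used if mm_fit.fittable else int(mask.sum()),
            "R": mm_fit.params.R if mm_fit.fittable else np.nan,
            "Di": mm_fit.params.Di if mm_fit.fittable else np.nan,
            "De": mm_fit.params.De if mm_fit.fittable else np.nan,
            "fi": mm_fit.params.fi if mm_fit.fittable else np.nan,
            "mm_extreme": mm_fit.extreme,
            "Dprime": tid_fit.params.Dprime if tid_fit.fittable else np.nan,
            "rss_mm": mm_fit.rss, "rss_tid": tid_fit.rss,
        })
    order = list(map(tuple, idxs))
    summary = summarize_roi([mm_fits[t] for t in order], [tid_fits[t] for t in order],
                            [prefs[t] for t in order])
    maps = build_maps(mm_fits, tid_fits, prefs, shape)
    return {"maps": maps, "summary": summary,
            "table": pd.DataFrame(rows), "s_noise": s_noise}


def adc_volume(dwi: DWIVolume, config: FitConfig,
               s_noise: float | None = None) -> dict:
    """Conventional ADC map over the ROI (single-diffusion-time data)."""
    s_noise = _resolve_s_noise(dwi, s_noise)
    shape = dwi.signals.shape[:3]
    adc_map = np.full(shape, np.nan)
    fits = {}
    for ijk in map(tuple, np.argwhere(dwi.roi_mask)):
        fit = fit_adc(dwi.signals[ijk], dwi.protocol, config, s_noise=s_noise)
        fits[ijk] = fit
        if fit.fittable:
            adc_map[ijk] = fit.params.adc
    return {"map": adc_map, "fits": fits, "s_noise": s_noise}
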