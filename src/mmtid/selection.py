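"""AICc model selection, the %MM biomarker and parameter-map assembly.

Each fittable voxel gets both an MM and a TID fit on the identical
retained points; the model with the lower small-sample-corrected Akaike
score is preferred (k = 4 for MM, k = 1 for TID; exact ties and voxels
where the MM score is undefined go to the simpler TID model). %MM is the
percentage of fittable ROI voxels preferring MM — extreme-valued MM fits
still count toward %MM, they are only excluded from the MM parameter
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import VoxelFit

#: preference-map codes
UNFITTABLE, TID, MM = 0, 1, 2
_LABELS = {UNFITTABLE: "unfittable", TID: "TID", MM: "MM"}

# floor keeps n*ln(rss/n) defined for numerically perfect fits; any rss
# at the floor dominates every realistic alternative by orders of magnitude
_RSS_FLOOR = 1e-300


def aicc(rss: float, n_points: int, k_params: int) -> float:
    """Corrected Akaike score n ln(rss/n) + 2k + 2k(k+1)/(n-k-1).

    Returns NaN when the correction is undefined (n <= k + 1); callers
    treat an undefined score as a loss against a defined one.
    """
    if n_points <= k_params + 1:
        return math.nan
    if not rss >= 0.0 or math.isnan(rss):
        return math.nan
    rss = max(rss, _RSS_FLOOR)
    n, k = n_points, k_params
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelPreference:
    """Per-voxel preferred model with both AICc scores."""

    label: int                  # UNFITTABLE, TID or MM
    aicc_mm: float
    aicc_tid: float

    @property
    def name(self) -> str:
        return _LABELS[self.label]


def select_model(mm_fit: VoxelFit, tid_fit: VoxelFit) -> ModelPreference:
    """AICc preference between MM (k=4) and TID (k=1) fits of one voxel.

    Both fits must have been computed on the identical retained point
    set. MM wins only with a strictly lower defined AICc; an undefined MM
    score (too few points for the correction) falls back to TID; if
    neither model could be scored the voxel is unfittable.
    """
    if mm_fit.fittable and tid_fit.fittable and mm_fit.n_used != tid_fit.n_used:
        raise ValueError(
            f"MM and TID fits used different point sets "
            f"(n={mm_fit.n_used} vs {tid_fit.n_used}); AICc comparison invalid"
        )
    a_mm = aicc(mm_fit.rss, mm_fit.n_used, 4) if mm_fit.fittable else math.nan
    a_tid = aicc(tid_fit.rss, tid_fit.n_used, 1) if tid_fit.fittable else math.nan
    if math.isnan(a_tid) and math.isnan(a_mm):
        return ModelPreference(UNFITTABLE, a_mm, a_tid)
    if math.isnan(a_mm):
        return ModelPreference(TID, a_mm, a_tid)
    if math.isnan(a_tid):
        # degenerate: TID unfittable but MM scored; keep the scored model
        return ModelPreference(MM, a_mm, a_tid)
    return ModelPreference(MM if a_mm < a_tid else TID, a_mm, a_tid)


def percent_mm(preferences) -> float:
    """%MM = 100 * #MM / (#MM + #TID); unfittable voxels excluded.

    Returns NaN when no voxel is fittable.
    """
    labels = np.array([p.label if isinstance(p, ModelPreference) else p
                       for p in preferences])
    n_mm = int(np.sum(labels == MM))
    n_tid = int(np.sum(labels == TID))
    if n_mm + n_tid == 0:
        return math.nan
    return 100.0 * n_mm / (n_mm + n_tid)


@dataclass(frozen=True)
class SubregionSummary:
    """ROI-level summary: %MM, bookkeeping counts and parameter medians."""

    percent_mm: float
    n_voxels: int
    n_mm: int
    n_tid: int
    n_unfittable: int
    n_excluded_extreme: int
    medians: dict


def summarize_roi(mm_fits: list[VoxelFit], tid_fits: list[VoxelFit],
                  preferences: list[ModelPreference],
                  adc_fits: list[VoxelFit] | None = None) -> SubregionSummary:
    """%MM plus parameter medians over accepted fits.

    MM medians come from MM-preferred voxels with non-extreme fits; the
    D' median from TID-preferred voxels; the ADC median from all fittable
    voxels of the conventional ADC analysis.
    """
    labels = np.array([p.label for p in preferences])
    accepted = [f for f, lab in zip(mm_fits, labels)
                if lab == MM and f.fittable and not f.extreme]
    n_excl = sum(1 for f, lab in zip(mm_fits, labels)
                 if lab == MM and f.fittable and f.extreme)
    med = {}
    if accepted:
        med["R"] = float(np.median([f.params.R for f in accepted]))
        med["Di"] = float(np.median([f.params.Di for f in accepted]))
        med["De"] = float(np.median([f.params.De for f in accepted]))
        med["fi"] = float(np.median([f.params.fi for f in accepted]))
    tid_ok = [f for f, lab in zip(tid_fits, labels) if lab == TID and f.fittable]
    if tid_ok:
        med["Dprime"] = float(np.median([f.params.Dprime for f in tid_ok]))
    if adc_fits is not None:
        vals = [f.params.adc for f in adc_fits if f.fittable]
        if vals:
            med["ADC"] = float(np.median(vals))
    return SubregionSummary(
        percent_mm=percent_mm(preferences),
        n_voxels=len(preferences),
        n_mm=int(np.sum(labels == MM)),
        n_tid=int(np.sum(labels == TID)),
        n_unfittable=int(np.sum(labels == UNFITTABLE)),
        n_excluded_extreme=n_excl,
        medians=med,
    )


def build_maps(mm_fits: dict, tid_fits: dict, preferences: dict,
               shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Assemble parameter and preference maps from per-voxel results.

    The inputs map voxel index triples to fits/preferences. MM maps
    (R, Di, De, fi) are populated only where MM is preferred and the fit
    is not extreme; the D' map where TID is preferred. The preference map
    is coded 0 = unfittable, 1 = TID, 2 = MM (NaN outside the ROI).
    """
    maps = {k: np.full(shape, np.nan) for k in ("R", "Di", "De", "fi", "Dprime")}
    pref_map = np.full(shape, np.nan)
    for idx, pref in preferences.items():
        pref_map[idx] = pref.label
        if pref.label == MM:
            fit = mm_fits[idx]
            if fit.fittable and not fit.extreme:
                maps["R"][idx] = fit.params.R
                maps["Di"][idx] = fit.params.Di
                maps["De"][idx] = fit.params.De
                maps["fi"][idx] = fit.params.fi
        elif pref.label == TID:
            fit = tid_fits[idx]
            if fit.fittable:
                maps["Dprime"][idx] = fit.params.Dprime
    maps["preference"] = pref_map
    return maps
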