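"""Conventional-ADC summaries and the ADC-threshold classification sweep.

An ADC threshold gives a simple necrosis-like classifier: the percentage
of ROI voxels with ADC below a cut-off. Sweeping the cut-off over the
fit range and correlating the resulting fractions against an external
reference fraction (e.g. histology-derived % necrosis) identifies the
threshold with the strongest association, the counterpart of the %MM
biomarker on conventional ADC maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: default sweep grid over the ADC fit range, um^2/ms
DEFAULT_THRESHOLDS = np.round(np.arange(0.10, 3.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class ReferenceFraction:
    """An external per-subject reference fraction in percent."""

    subject: str
    fraction: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 100.0:
            raise ValueError(f"fraction must be in [0, 100] (got {self.fraction})")


def fraction_below_threshold(adc_values, threshold: float) -> float:
    """Percentage of voxels with ADC strictly below ``threshold``.

    Strict inequality, so no voxel counts at the lower fit bound; at the
    top of the range callers should note that voxels can sit exactly on
    the upper bound (all voxels satisfy ADC <= upper bound).
    """
    v = np.asarray(adc_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty ADC value set")
    return 100.0 * float(np.count_nonzero(v < threshold)) / v.size


def pearson_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """Pearson rho with Fisher-z confidence interval and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    z = math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    se = 1.0 / math.sqrt(x.size - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    ci = (math.tanh(z - zc * se), math.tanh(z + zc * se))
    return float(r), ci, float(p)


@dataclass
class ThresholdSweepResult:
    """Fraction-below curves, the per-threshold correlation and its peak."""

    thresholds: np.ndarray
    fraction_below: np.ndarray        # (n_datasets, n_thresholds)
    correlation_curve: np.ndarray     # Pearson rho per threshold (NaN if undefined)
    best_threshold: float
    best_rho: float


def threshold_sweep(adc_datasets, references, thresholds=None) -> ThresholdSweepResult:
    """Correlate fraction-below-threshold against a reference fraction.

    ``adc_datasets`` is a sequence of per-subject ADC value arrays paired
    with ``references`` (ReferenceFraction or plain percentages). The best
    threshold maximizes |rho|; ties go to the lowest threshold, and
    thresholds where the fraction vector is constant are skipped.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if len(adc_datasets) != len(references):
        raise ValueError("datasets and references differ in length")
    if len(adc_datasets) < 3:
        raise ValueError("need >= 3 paired datasets for a correlation")
    ref = np.array([r.fraction if isinstance(r, ReferenceFraction) else float(r)
                    for r in references])
    frac = np.empty((len(adc_datasets), thresholds.size))
    for i, vals in enumerate(adc_datasets):
        for j, t in enumerate(thresholds):
            frac[i, j] = fraction_below_threshold(vals, t)
    rho = np.full(thresholds.size, np.nan)
    for j in range(thresholds.size):
        if np.ptp(frac[:, j]) == 0 or np.ptp(ref) == 0:
            continue
        rho[j], _ = stats.pearsonr(frac[:, j], ref)
    if np.all(np.isnan(rho)):
        raise ValueError("correlation undefined at every threshold")
    best_j = int(np.nanargmax(np.abs(rho)))
    return ThresholdSweepResult(
        thresholds=thresholds,
        fraction_below=frac,
        correlation_curve=rho,
        best_threshold=float(thresholds[best_j]),
        best_rho=float(rho[best_j]),
    )
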