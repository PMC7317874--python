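"""Voxel-wise least-squares estimation of MM, TID and ADC parameters.

Fitting follows the voxel pipeline used for model comparison: raw
signals are screened against the noise floor (discarding samples below
``noise_floor_multiplier * s_noise``), normalized to the mean of the
G = 0 measurements, and both models are fitted to the identical retained
point set so their AICc values are comparable.

MM fitting is bounded multi-start Nelder-Mead (an unconstrained simplex
on a sigmoid-transformed parameter space), with start points drawn
uniformly over the bounded box from a stream seeded by
``(seed, voxel_index, start_index)`` so fits are reproducible and the
best objective is monotone in the number of starts. Two strategies are
provided: ``fit_di`` (R, Di, De, fi all free) and ``discrete_di``
(Di fixed in turn to each value of a small set, keeping the fit with the
highest R^2, ties going to the lower Di).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from . import _kernels
from .models import (ADCParams, D_BOUNDS, FI_BOUNDS, MMParams, N_ROOTS,
                     R_BOUNDS, TIDParams, sphere_gpd_roots)
from .protocol import AcquisitionProtocol

Strategy = Literal["fit_di", "discrete_di"]

_DEFAULT_BOUNDS = {
    "R": R_BOUNDS, "Di": D_BOUNDS, "De": D_BOUNDS, "fi": FI_BOUNDS,
    "Dprime": D_BOUNDS, "adc": D_BOUNDS,
}


@dataclass(frozen=True)
class FitConfig:
    """Settings of the voxel-wise fitting pipeline.

    Defaults reproduce the reference pipeline: 100 starting values per
    fit, noise-floor multiplier 2, discrete Di set
    {0.5, 1.0, 1.5, 2.0, 2.5} um^2/ms, and extreme-value flagging at 1%
    of each parameter's range.
    """

    n_starts: int = 100
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    noise_floor_multiplier: float = 2.0
    discrete_di_values: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)
    seed: int = 0
    extreme_margin: float = 0.01
    extreme_mode: Literal["range", "value"] = "range"
    n_roots: int = N_ROOTS
    xatol: float = 1e-6
    fatol: float = 1e-6
    maxfev: int = 2000

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lo < hi")
        dlo, dhi = self.bounds["Di"]
        for v in self.discrete_di_values:
            if not dlo <= v <= dhi:
                raise ValueError(f"discrete Di value {v} outside Di bounds")


@dataclass
class VoxelFit:
    """Result of one voxel-wise model fit."""

    params: MMParams | TIDParams | ADCParams | None
    rss: float
    r2: float
    n_used: int
    extreme: bool
    converged: bool
    model: str

    @property
    def fittable(self) -> bool:
        return self.params is not None


def unfittable(model: str, n_used: int = 0) -> VoxelFit:
    return VoxelFit(params=None, rss=np.nan, r2=np.nan, n_used=n_used,
                    extreme=False, converged=False, model=model)


# ---------------------------------------------------------------------------
# building blocks


def noise_floor_mask(signals: np.ndarray, s_noise: float,
                     multiplier: float = 2.0) -> np.ndarray:
    """Retention mask: keep samples with signal >= multiplier * s_noise."""
    if s_noise <= 0:
        raise ValueError("s_noise must be > 0; for noiseless data skip masking")
    return np.asarray(signals) >= multiplier * s_noise


def is_extreme(values: dict[str, float], bounds: dict[str, tuple[float, float]],
               margin: float = 0.01, mode: str = "range") -> bool:
    """True iff any parameter lies within ``margin`` of either constraint.

    ``mode='range'`` (default) measures the margin as a fraction of the
    parameter range hi - lo; ``mode='value'`` as a fraction of the bound
    itself.
    """
    for name, v in values.items():
        lo, hi = bounds[name]
        if mode == "range":
            tol_lo = tol_hi = margin * (hi - lo)
        elif mode == "value":
            tol_lo, tol_hi = margin * abs(lo), margin * abs(hi)
        else:
            raise ValueError(f"unknown extreme mode {mode!r}")
        if v - lo < tol_lo or hi - v < tol_hi:
            return True
    return False


def normalize_to_b0(signals: np.ndarray, protocol: AcquisitionProtocol) -> np.ndarray:
    """Normalize to the mean of the G = 0 measurements (both diffusion times)."""
    idx = protocol.b0_indices
    if idx.size == 0:
        raise ValueError("protocol has no G=0 measurement to normalize to")
    ref = float(np.mean(np.asarray(signals)[idx]))
    if ref <= 0:
        raise ValueError("mean b=0 signal is not positive")
    return np.asarray(signals, dtype=float) / ref


def _start_points(config: FitConfig, voxel_index: int, n_starts: int) -> np.ndarray:
    """Uniform start points over the (R, Di, De, fi) box, one stream per start."""
    lo = np.array([config.bounds[k][0] for k in ("R", "Di", "De", "fi")])
    hi = np.array([config.bounds[k][1] for k in ("R", "Di", "De", "fi")])
    out = np.empty((n_starts, 4))
    for s in range(n_starts):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), int(voxel_index), s])
        )
        out[s] = lo + (hi - lo) * rng.random(4)
    return out


def _r2(rss: float, y: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:
        return 1.0 if rss <= 0.0 else -np.inf
    return 1.0 - rss / tss


# ---------------------------------------------------------------------------
# model fits


def fit_mm(signals: np.ndarray, protocol: AcquisitionProtocol, mask: np.ndarray,
           config: FitConfig, strategy: Strategy = "discrete_di",
           voxel_index: int = 0) -> VoxelFit:
    """Fit the two-compartment MM to normalized signals on retained points."""
    mask = np.asarray(mask, dtype=bool)
    y = np.asarray(signals, dtype=float)
    n_used = int(mask.sum())
    n_free = 3 if strategy == "discrete_di" else 4
    if n_used < n_free + 1:
        return unfittable("MM", n_used)

    pref2, idx_delta, u_delta, d_s, b1e3 = _kernels.protocol_arrays(protocol)
    mu = sphere_gpd_roots(config.n_roots)
    starts4 = _start_points(config, voxel_index, config.n_starts)
    lo4 = np.array([config.bounds[k][0] for k in ("R", "Di", "De", "fi")])
    hi4 = np.array([config.bounds[k][1] for k in ("R", "Di", "De", "fi")])
    yv = y[mask]

    if strategy == "fit_di":
        x, sse, conv = _kernels.fit_mm_multistart(
            starts4, lo4, hi4, False, 0.0, y, mask,
            pref2, idx_delta, u_delta, d_s, b1e3, mu,
            config.xatol, config.fatol, config.maxfev,
        )
        params = MMParams(R=x[0], Di=x[1], De=x[2], fi=x[3])
        rss, converged = float(sse), bool(conv)
    elif strategy == "discrete_di":
        sub = np.array([0, 2, 3])          # (R, De, fi) columns
        best = None
        for di in config.discrete_di_values:   # ascending; ties keep lower Di
            x, sse, conv = _kernels.fit_mm_multistart(
                starts4[:, sub], lo4[sub], hi4[sub], True, float(di), y, mask,
                pref2, idx_delta, u_delta, d_s, b1e3, mu,
                config.xatol, config.fatol, config.maxfev,
            )
            r2 = _r2(float(sse), yv)
            if best is None or r2 > best[0]:
                best = (r2, float(di), x, float(sse), bool(conv))
        _, di, x, rss, converged = best
        params = MMParams(R=x[0], Di=di, De=x[1], fi=x[2])
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    extreme = is_extreme(
        {"R": params.R, "Di": params.Di, "De": params.De, "fi": params.fi},
        {k: config.bounds[k] for k in ("R", "Di", "De", "fi")},
        config.extreme_margin, config.extreme_mode,
    )
    return VoxelFit(params=params, rss=rss, r2=_r2(rss, yv), n_used=n_used,
                    extreme=extreme, converged=converged, model="MM")


def _fit_exponential_1d(y: np.ndarray, x: np.ndarray, bounds: tuple[float, float],
                        xatol: float) -> tuple[float, float]:
    """Min-SSE D for y ~ exp(-x D): log-linear init, bounded refinement."""
    lo, hi = bounds

    def sse(d: float) -> float:
        return float(np.sum((np.exp(-x * d) - y) ** 2))

    pos = y > 0
    if pos.any() and float(np.sum(x[pos] ** 2)) > 0:
        d0 = float(np.sum(x[pos] * (-np.log(y[pos]))) / np.sum(x[pos] ** 2))
    else:
        d0 = 0.5 * (lo + hi)
    d0 = min(max(d0, lo), hi)
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    cands = [(sse(d0), d0), (float(res.fun), float(res.x))]
    f, d = min(cands)
    return d, f


def fit_tid(signals: np.ndarray, protocol: AcquisitionProtocol, mask: np.ndarray,
            config: FitConfig, voxel_index: int = 0) -> VoxelFit:
    """Fit the TID monoexponential exp(-b D') on retained points of both Delta."""
    mask = np.asarray(mask, dtype=bool)
    y = np.asarray(signals, dtype=float)[mask]
    n_used = int(mask.sum())
    if n_used < 2:
        return unfittable("TID", n_used)
    b = protocol.b_values[mask] * 1e-3
    d, rss = _fit_exponential_1d(y, b, config.bounds["Dprime"], config.xatol)
    params = TIDParams(Dprime=d)
    extreme = is_extreme({"Dprime": d}, {"Dprime": config.bounds["Dprime"]},
                         config.extreme_margin, config.extreme_mode)
    return VoxelFit(params=params, rss=rss, r2=_r2(rss, y), n_used=n_used,
                    extreme=extreme, converged=True, model="TID")


def fit_adc(signals: np.ndarray, protocol: AcquisitionProtocol,
            config: FitConfig, s_noise: float | None = None) -> VoxelFit:
    """Fit ADC on the single-diffusion-time protocol, normalized to b~150.

    Raw (un-normalized) signals are expected; the b~150 reference must be
    above the noise floor when ``s_noise`` is given.
    """
    if not protocol.is_single_diffusion_time:
        raise ValueError("ADC fitting applies to the single-diffusion-time protocol")
    ref = protocol.reference_index()
    y_raw = np.asarray(signals, dtype=float)
    if s_noise is not None:
        mask = noise_floor_mask(y_raw, s_noise, config.noise_floor_multiplier)
        if not mask[ref]:
            return unfittable("ADC", int(mask.sum()))
    else:
        mask = np.ones(len(protocol), dtype=bool)
    n_used = int(mask.sum())
    if n_used < 2 or y_raw[ref] <= 0:
        return unfittable("ADC", n_used)
    y = (y_raw / y_raw[ref])[mask]
    db = (protocol.b_values - protocol.b_values[ref])[mask] * 1e-3
    d, rss = _fit_exponential_1d(y, db, config.bounds["adc"], config.xatol)
    params = ADCParams(adc=d)
    extreme = is_extreme({"adc": d}, {"adc": config.bounds["adc"]},
                         config.extreme_margin, config.extreme_mode)
    return VoxelFit(params=params, rss=rss, r2=_r2(rss, y), n_used=n_used,
                    extreme=extreme, converged=True, model="ADC")


# ---------------------------------------------------------------------------
# voxel pipeline


def fit_voxel_models(raw_signals: np.ndarray, protocol: AcquisitionProtocol,
                     config: FitConfig, s_noise: float | None,
                     strategy: Strategy = "discrete_di",
                     voxel_index: int = 0) -> tuple[VoxelFit, VoxelFit, np.ndarray]:
    """Noise-floor screen, normalize to b=0, fit MM and TID on the same points.

    ``s_noise`` on the raw signal scale; ``None`` disables the screen
    (noiseless data). Returns (mm_fit, tid_fit, retained mask).
    """
    raw = np.asarray(raw_signals, dtype=float)
    if s_noise is not None:
        mask = noise_floor_mask(raw, s_noise, config.noise_floor_multiplier)
    else:
        mask = np.ones(raw.shape[0], dtype=bool)
    b0 = protocol.b0_indices
    if b0.size == 0 or not mask[b0].any() or float(np.mean(raw[b0])) <= 0:
        return unfittable("MM"), unfittable("TID"), mask
    y = normalize_to_b0(raw, protocol)
    mm = fit_mm(y, protocol, mask, config, strategy, voxel_index)
    tid = fit_tid(y, protocol, mask, config, voxel_index)
    return mm, tid, mask
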