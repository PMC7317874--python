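"""PGSE acquisition protocols, b-values, image I/O and SNR estimation.

Conventions
-----------
Gradient amplitude ``G`` is in mT/m, all timings (``delta``, ``Delta``,
``rise``, ``TE``, ``TR``) are in ms, and b-values are in s/mm^2.

The quoted pulse duration ``delta`` is the TOTAL duration of the
trapezoidal gradient lobe, including both ramps of length ``rise``.
b-values are computed with the rectangular-equivalent width
``delta_eff = delta - rise`` plus the standard trapezoid correction::

    b = gamma^2 G^2 [ delta_eff^2 (Delta - delta_eff/3)
                      + rise^3/30 - delta_eff rise^2/6 ]

This convention reproduces the nominal b = 150/500/1000 s/mm^2 of the
short-diffusion-time protocol to within the rounding of the printed
gradient amplitudes, and leaves the ratio b(Delta_2)/b(Delta_1) at fixed
G exactly constant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

#: Gyromagnetic ratio of 1H, rad s^-1 T^-1.
GAMMA_H = 2.6752219e8


class ProtocolError(ValueError):
    """Raised for non-physical timing or malformed protocol files."""


def compute_b_value(G: float, delta: float, Delta: float, rise: float) -> float:
    """b-value of a trapezoidal PGSE measurement, in s/mm^2.

    Parameters
    ----------
    G : float
        Gradient amplitude, mT/m.
    delta : float
        Total gradient lobe duration including both ramps, ms.
    Delta : float
        Leading-edge separation of the two lobes, ms.
    rise : float
        Ramp (rise) time, ms.
    """
    if G < 0:
        raise ProtocolError(f"gradient amplitude must be >= 0 (got G={G})")
    if not 0 < rise < delta:
        raise ProtocolError(
            f"rise time must satisfy 0 < rise < delta (got rise={rise}, delta={delta})"
        )
    if delta > Delta:
        raise ProtocolError(
            f"pulse duration cannot exceed separation (got delta={delta}, Delta={Delta})"
        )
    if G == 0:
        return 0.0
    g = G * 1e-3          # T/m
    d = (delta - rise) * 1e-3  # effective rectangular width, s
    D = Delta * 1e-3
    e = rise * 1e-3
    b = GAMMA_H**2 * g**2 * (d**2 * (D - d / 3.0) + e**3 / 30.0 - d * e**2 / 6.0)
    return b * 1e-6       # s/m^2 -> s/mm^2


@dataclass(frozen=True)
class PGSEMeasurement:
    """One diffusion-weighted volume's gradient waveform timing.

    ``b`` is derived from ``(G, delta, Delta, rise)`` at construction and
    never stored independently of the waveform.
    """

    G: float
    delta: float
    Delta: float
    rise: float
    TE: float | None = None
    TR: float | None = None
    b: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", compute_b_value(self.G, self.delta, self.Delta, self.rise))

    @property
    def delta_eff(self) -> float:
        """Rectangular-equivalent pulse width, ms."""
        return self.delta - self.rise


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered set of PGSE measurements sharing pulse duration and rise time.

    A protocol must contain a normalization reference: a ``G = 0``
    measurement for multi-diffusion-time (model-comparison) protocols, or
    a measurement with b close to 150 s/mm^2 for the single-diffusion-time
    (conventional ADC) protocol, which deliberately omits b = 0 so that
    capillary-flow effects cancel in the normalization.
    """

    measurements: tuple[PGSEMeasurement, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise ProtocolError("protocol contains no measurements")
        deltas = {m.delta for m in self.measurements}
        rises = {m.rise for m in self.measurements}
        if len(deltas) > 1 or len(rises) > 1:
            raise ProtocolError(
                "all measurements must share delta and rise "
                f"(got delta={sorted(deltas)}, rise={sorted(rises)})"
            )
        if self.n_b0 == 0 and self.reference_index(required=False) is None:
            raise ProtocolError(
                "protocol has no normalization reference: need a G=0 measurement, "
                "or a b~150 s/mm^2 measurement for a single-diffusion-time protocol"
            )

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def b_values(self) -> np.ndarray:
        return np.array([m.b for m in self.measurements])

    @property
    def n_b0(self) -> int:
        return sum(1 for m in self.measurements if m.G == 0)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero([m.G == 0 for m in self.measurements])

    @property
    def diffusion_times(self) -> np.ndarray:
        """Distinct gradient separations Delta, ms, in ascending order."""
        return np.array(sorted({m.Delta for m in self.measurements}))

    @property
    def is_single_diffusion_time(self) -> bool:
        return len(self.diffusion_times) == 1

    def reference_index(self, target_b: float = 150.0, tol: float = 50.0,
                        required: bool = True) -> int | None:
        """Index of the b~150 normalization reference for ADC fitting."""
        b = self.b_values
        nonzero = np.flatnonzero(b > 0)
        if nonzero.size:
            j = nonzero[np.argmin(np.abs(b[nonzero] - target_b))]
            if abs(b[j] - target_b) <= tol:
                return int(j)
        if required:
            raise ProtocolError(f"protocol has no measurement with b within {tol} of {target_b}")
        return None


def two_diffusion_time_protocol(TE: float = 50.1, TR: float = 2550.0) -> AcquisitionProtocol:
    """The two-diffusion-time PGSE protocol used for model comparison.

    delta = 4.65 ms, Delta = 9.86 and 40.0 ms, G = 0, 113, 207, 293 mT/m,
    rise = 0.245 ms; nominal b = 0, 150, 500, 1000 / 0, 689, 2296, 4592 s/mm^2.
    """
    ms = [
        PGSEMeasurement(G=G, delta=4.65, Delta=Delta, rise=0.245, TE=TE, TR=TR)
        for Delta in (9.86, 40.0)
        for G in (0.0, 113.0, 207.0, 293.0)
    ]
    return AcquisitionProtocol(tuple(ms), label="two diffusion time")


def single_diffusion_time_protocol(TE: float = 20.4, TR: float = 2550.0) -> AcquisitionProtocol:
    """The single-diffusion-time PGSE protocol used for conventional ADC.

    delta = 4.65 ms, Delta = 9.86 ms, G = 113, 207, 293 mT/m,
    nominal b = 150, 500, 1000 s/mm^2 (no b = 0; signals are normalized
    to the b = 150 s/mm^2 measurement).
    """
    ms = [
        PGSEMeasurement(G=G, delta=4.65, Delta=9.86, rise=0.245, TE=TE, TR=TR)
        for G in (113.0, 207.0, 293.0)
    ]
    return AcquisitionProtocol(tuple(ms), label="single diffusion time")


# ---------------------------------------------------------------------------
# protocol sidecar I/O

_REQUIRED_FIELDS = ("G", "delta", "Delta", "rise")


def load_protocol(path) -> AcquisitionProtocol:
    """Read a JSON protocol sidecar; b-values are recomputed on load."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "measurements" not in doc:
        raise ProtocolError(f"{path}: protocol sidecar must contain a 'measurements' list")
    records = doc["measurements"]
    if not records:
        raise ProtocolError(f"{path}: protocol contains no measurements")
    ms = []
    for i, rec in enumerate(records):
        missing = [k for k in _REQUIRED_FIELDS if k not in rec]
        if missing:
            raise ProtocolError(f"{path}: measurement {i} missing fields {missing}")
        ms.append(
            PGSEMeasurement(
                G=float(rec["G"]), delta=float(rec["delta"]), Delta=float(rec["Delta"]),
                rise=float(rec["rise"]), TE=rec.get("TE"), TR=rec.get("TR"),
            )
        )
    return AcquisitionProtocol(tuple(ms), label=doc.get("label", ""))


def save_protocol(protocol: AcquisitionProtocol, path) -> None:
    """Write a JSON protocol sidecar (b included for readability only)."""
    doc = {
        "label": protocol.label,
        "measurements": [
            {"G": m.G, "delta": m.delta, "Delta": m.Delta, "rise": m.rise,
             "TE": m.TE, "TR": m.TR, "b": m.b}
            for m in protocol.measurements
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def write_bval(protocol: AcquisitionProtocol, path) -> None:
    """Export FSL-style .bval/.bvec; bvecs are zeros (isotropic model)."""
    path = str(path)
    stem = path[:-5] if path.endswith(".bval") else path
    with open(stem + ".bval", "w") as fh:
        fh.write(" ".join(f"{m.b:.6g}" for m in protocol.measurements) + "\n")
    with open(stem + ".bvec", "w") as fh:
        for _ in range(3):
            fh.write(" ".join("0" for _ in protocol.measurements) + "\n")


# ---------------------------------------------------------------------------
# volumes, masks, SNR


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signals bound to a protocol plus masks."""

    signals: np.ndarray
    protocol: AcquisitionProtocol
    roi_mask: np.ndarray
    background_mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError(f"signals must be 4-D (got shape {self.signals.shape})")
        if self.signals.shape[3] != len(self.protocol):
            raise ValueError(
                f"4th dimension ({self.signals.shape[3]}) does not match "
                f"protocol length ({len(self.protocol)})"
            )
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.roi_mask.shape != self.signals.shape[:3]:
            raise ValueError("ROI mask does not share the signal grid")
        if self.background_mask is not None:
            self.background_mask = np.asarray(self.background_mask, dtype=bool)
            if self.background_mask.shape != self.signals.shape[:3]:
                raise ValueError("background mask does not share the signal grid")
        if self.affine is None:
            self.affine = np.eye(4)


@dataclass(frozen=True)
class NoiseEstimate:
    """Background-derived noise level and ROI-mean b=0 SNR."""

    s_noise: float
    sigma_rician: float
    snr: float


def estimate_snr(dwi: DWIVolume) -> NoiseEstimate:
    """Estimate Rician sigma and SNR from the background mask.

    ``s_noise`` is the mean background magnitude; in a signal-free region
    magnitudes are Rayleigh distributed with mean sigma*sqrt(pi/2), which
    yields ``sigma_rician``. SNR is the ROI-mean b=0 signal divided by
    sigma.
    """
    if dwi.background_mask is None or not dwi.background_mask.any():
        raise ValueError(
            "background mask is empty; pass an explicit noise sigma instead"
        )
    b0 = dwi.protocol.b0_indices
    if b0.size == 0:
        raise ProtocolError("protocol has no G=0 measurement; SNR at b=0 undefined")
    s_noise = float(dwi.signals[dwi.background_mask].mean())
    if s_noise <= 0:
        raise ValueError("background mean signal is not positive; cannot derive sigma")
    sigma = s_noise / math.sqrt(math.pi / 2.0)
    mean_b0 = float(dwi.signals[dwi.roi_mask][:, b0].mean())
    return NoiseEstimate(s_noise=s_noise, sigma_rician=sigma, snr=mean_b0 / sigma)


def load_dwi(dwi_path, protocol_path, roi_path, background_path=None) -> DWIVolume:
    """Load a 4-D NIfTI volume, its JSON protocol sidecar and masks."""
    import nibabel as nib

    img = nib.load(str(dwi_path))
    protocol = load_protocol(protocol_path)
    roi = np.asarray(nib.load(str(roi_path)).dataobj) > 0
    bg = None
    if background_path is not None:
        bg = np.asarray(nib.load(str(background_path)).dataobj) > 0
    return DWIVolume(
        signals=np.asarray(img.dataobj, dtype=float),
        protocol=protocol,
        roi_mask=roi,
        background_mask=bg,
        affine=img.affine,
    )


def save_map(data: np.ndarray, affine: np.ndarray | None, path) -> None:
    """Write a 3-D parameter map as NIfTI."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                             np.eye(4) if affine is None else affine), str(path))
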