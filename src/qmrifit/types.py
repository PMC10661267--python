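"""Shared domain types for quantitative multiparametric MRI analysis.

All internal times are seconds. Rate constants (Ktrans, kep, PS) are held in
min^-1 because those are the units the field reports and the fitters consume
AIF/tissue curves with time converted internally; plasma flow Fp is
mL/min/100mL. Diffusivities are mm^2/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "FitResult",
    "PKParams",
    "DWParams",
    "MetadataError",
]


class MetadataError(ValueError):
    """Acquisition metadata inconsistent with the image data."""


@dataclass
class AcquisitionMeta:
    """Per-series acquisition parameters.

    Parameters
    ----------
    tr : float, optional
        Repetition time in seconds.
    flip_angles_deg : list of float, optional
        Flip angles in degrees (one per frame for a VFA series, or a single
        angle for a dynamic series).
    echo_times : list of float, optional
        Echo times in seconds, ascending.
    b_values : list of float, optional
        Diffusion weightings in s/mm^2, ascending.
    frame_times : list of float, optional
        DCE frame mid-point times in seconds, t=0 at the first frame,
        strictly increasing.
    relaxivity_r1 : float, optional
        Contrast-agent longitudinal relaxivity in mM^-1 s^-1.
    field_note : str
        Free-text note (field strength, scanner, ...).
    """

    tr: Optional[float] = None
    flip_angles_deg: Optional[list] = None
    echo_times: Optional[list] = None
    b_values: Optional[list] = None
    frame_times: Optional[list] = None
    relaxivity_r1: Optional[float] = None
    field_note: str = ""

    def __post_init__(self):
        if self.tr is not None and self.tr <= 0:
            raise MetadataError(f"TR must be positive, got {self.tr}")
        if self.relaxivity_r1 is not None and self.relaxivity_r1 <= 0:
            raise MetadataError("relaxivity_r1 must be positive")
        for name in ("b_values", "echo_times"):
            vals = getattr(self, name)
            if vals is not None:
                arr = np.asarray(vals, dtype=float)
                if np.any(arr < 0):
                    raise MetadataError(f"{name} must be non-negative")
                if np.any(np.diff(arr) < 0):
                    raise MetadataError(f"{name} must be sorted ascending")
                setattr(self, name, list(arr))
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if t[0] < 0 or np.any(np.diff(t) <= 0):
                raise MetadataError("frame_times must be >=0 and strictly increasing")
            self.frame_times = list(t)
        if self.flip_angles_deg is not None:
            fa = np.asarray(self.flip_angles_deg, dtype=float)
            if np.any(fa <= 0) or np.any(fa >= 180):
                raise MetadataError("flip angles must lie in (0, 180) degrees")
            self.flip_angles_deg = list(fa)

    def n_frames_for(self, kind: str) -> int:
        """Expected frame count for a series of the given kind
        (``'dce'``, ``'dw'``, ``'vfa'`` or ``'me'``)."""
        key = {
            "dce": "frame_times",
            "dw": "b_values",
            "vfa": "flip_angles_deg",
            "me": "echo_times",
        }[kind]
        vals = getattr(self, key)
        if vals is None:
            raise MetadataError(f"meta has no {key}")
        return len(vals)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FitResult:
    """Per-voxel parameter estimates plus a goodness-of-fit bundle."""

    params: dict
    rss: float
    n_points: int
    k_params: int
    r2: float = np.nan
    aic: float = np.nan
    aicc: float = np.nan
    bic: float = np.nan
    converged: bool = True
    n_iter: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.rss < 0:
            raise ValueError("rss must be non-negative")
        if self.k_params < 1:
            raise ValueError("k_params must be >= 1")

    def with_criteria(self, tss: Optional[float] = None) -> "FitResult":
        """Fill the information criteria from (rss, n, k); returns self."""
        from .selection import aic as _aic, aicc as _aicc, bic as _bic, r2 as _r2

        self.aic = _aic(self.rss, self.n_points, self.k_params)
        self.bic = _bic(self.rss, self.n_points, self.k_params)
        if self.n_points > self.k_params + 1:
            self.aicc = _aicc(self.rss, self.n_points, self.k_params)
        if tss is not None and tss > 0:
            self.r2 = _r2(self.rss, tss)
        return self


@dataclass
class PKParams:
    """DCE pharmacokinetic parameters.

    ktrans and ps in min^-1, fp in mL/min/100mL, ve/vp fractions,
    tau_i (mean intracellular water lifetime, 1/kie) in seconds,
    r1i/r10e pre-contrast R1 of intracellular space / EES in s^-1.
    """

    ktrans: float = 0.0
    ve: float = 0.1
    vp: float = 0.0
    fp: float = 0.0
    ps: float = 0.0
    tau_i: float = 0.5
    r1i: float = np.nan
    r10e: float = np.nan

    def __post_init__(self):
        if not (0.0 <= self.ve <= 1.0) or not (0.0 <= self.vp <= 1.0):
            raise ValueError("ve and vp must be fractions in [0, 1]")
        if self.ve + self.vp > 1.0 + 1e-12:
            raise ValueError("ve + vp must not exceed 1")
        if min(self.ktrans, self.fp, self.ps) < 0:
            raise ValueError("rate parameters must be non-negative")
        if self.tau_i <= 0:
            raise ValueError("tau_i must be positive")

    @property
    def kep(self) -> float:
        """Efflux rate Ktrans/ve in min^-1."""
        if self.ve == 0:
            raise ValueError("kep undefined for ve = 0")
        return self.ktrans / self.ve


@dataclass
class DWParams:
    """Diffusion model parameters (diffusivities in mm^2/s)."""

    s0: float = 1.0
    adc: float = np.nan
    d: float = np.nan
    dstar: float = np.nan
    f: float = 0.0
    dapp: float = np.nan
    kapp: float = np.nan
    k: float = np.nan

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("perfusion fraction f must be in [0, 1]")
        for name in ("adc", "d", "dstar", "dapp"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")
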