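"""DCE signal-to-concentration conversion.

The dynamic T1-weighted signal is converted to tissue contrast-agent (CA)
concentration through the SPGR steady-state equation: the pre-contrast
baseline mean anchors the signal scale, each frame's signal ratio is inverted
for R1(t), and

    dR1(t) = R1(t) - R10,      Ct(t) = dR1(t) / r1

with r1 the CA longitudinal relaxivity. The ratio inversion is invariant to a
global scanner gain. Frames whose inversion falls outside the achievable
signal range (noise above the SPGR maximum) are clamped to the R1 domain
bounds and flagged rather than set to NaN, preserving map continuity while
recording unreliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AcquisitionMeta

__all__ = [
    "ConcentrationSeries",
    "signal_to_concentration",
    "concentration_to_signal",
    "spgr_ratio",
    "invert_spgr_ratio",
]

# R1 clamp domain for out-of-range inversions, s^-1
R1_MIN, R1_MAX = 1e-4, 100.0


@dataclass
class ConcentrationSeries:
    """Tissue CA concentration for one voxel."""

    ct: np.ndarray          # mM per frame
    delta_r1: np.ndarray    # s^-1 per frame
    r10: float              # s^-1
    baseline_frames: int
    valid: bool = True
    clamped: np.ndarray = field(default=None)  # per-frame QC flag

    def __post_init__(self):
        self.ct = np.asarray(self.ct, dtype=float)
        self.delta_r1 = np.asarray(self.delta_r1, dtype=float)
        if self.clamped is None:
            self.clamped = np.zeros(self.ct.shape, dtype=bool)


def spgr_ratio(r1, fa_deg, tr):
    """SPGR signal per unit S0: sin(a)(1-E1)/(1-cos(a)E1), E1=exp(-TR*R1)."""
    a = np.deg2rad(fa_deg)
    e1 = np.exp(-tr * np.asarray(r1, dtype=float))
    return np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def invert_spgr_ratio(s_rel, fa_deg, tr):
    """Invert s_rel = spgr_ratio(R1)/spgr_ratio(R10-ref) ... for R1.

    Takes the absolute SPGR ratio value (signal / S0, including sin(a)) and
    returns (r1, clamped) with out-of-domain values clamped to [R1_MIN, R1_MAX].
    """
    a = np.deg2rad(fa_deg)
    s = np.asarray(s_rel, dtype=float) / np.sin(a)
    c = np.cos(a)
    # s = (1-E1)/(1-c E1)  =>  E1 = (1-s)/(1-c s)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - s) / (1.0 - c * s)
    e1_lo, e1_hi = np.exp(-tr * R1_MAX), np.exp(-tr * R1_MIN)
    clamped = (e1 < e1_lo) | (e1 > e1_hi) | ~np.isfinite(e1)
    e1 = np.clip(np.nan_to_num(e1, nan=e1_hi), e1_lo, e1_hi)
    r1 = -np.log(e1) / tr
    return r1, clamped


def signal_to_concentration(signal, r10: float, meta: AcquisitionMeta,
                            baseline_frames: int = 5) -> ConcentrationSeries:
    """Convert one voxel's DCE signal time-course to CA concentration.

    Parameters
    ----------
    signal : array, shape (n_frames,)
    r10 : float
        Pre-contrast longitudinal relaxation rate 1/T10, s^-1.
    meta : AcquisitionMeta
        Must carry the DCE flip angle, TR and relaxivity_r1.
    baseline_frames : int
        Number of pre-bolus frames averaged as the S(R10) reference.
    """
    signal = np.asarray(signal, dtype=float)
    if r10 <= 0:
        raise ValueError("r10 must be positive")
    if baseline_frames < 1:
        raise ValueError("need at least one baseline frame")
    fa = meta.flip_angles_deg[0] if meta.flip_angles_deg else None
    if fa is None or meta.tr is None or meta.relaxivity_r1 is None:
        raise ValueError("meta must provide DCE flip angle, TR and relaxivity_r1")
    s_base = signal[:baseline_frames].mean()
    if s_base <= 0:
        return ConcentrationSeries(
            ct=np.zeros_like(signal), delta_r1=np.zeros_like(signal),
            r10=r10, baseline_frames=baseline_frames, valid=False,
        )
    # baseline-anchored: signal/S0 = (signal/s_base) * spgr_ratio(R10)
    s_rel = signal / s_base * spgr_ratio(r10, fa, meta.tr)
    r1t, clamped = invert_spgr_ratio(s_rel, fa, meta.tr)
    delta_r1 = r1t - r10
    ct = delta_r1 / meta.relaxivity_r1
    return ConcentrationSeries(ct=ct, delta_r1=delta_r1, r10=r10,
                               baseline_frames=baseline_frames, clamped=clamped)


def signal_to_concentration_batch(X, r10, meta: AcquisitionMeta,
                                  baseline_frames: int = 5):
    """Vectorised conversion for an (n_voxels, n_frames) signal array.

    ``r10`` may be a scalar or per-voxel array. Returns (ct, clamped, valid).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r10 = np.broadcast_to(np.asarray(r10, dtype=float), (X.shape[0],))
    fa, tr = meta.flip_angles_deg[0], meta.tr
    s_base = X[:, :baseline_frames].mean(axis=1)
    valid = s_base > 0
    s_base_safe = np.where(valid, s_base, 1.0)
    s_rel = X / s_base_safe[:, None] * spgr_ratio(r10, fa, tr)[:, None]
    r1t, clamped = invert_spgr_ratio(s_rel, fa, tr)
    ct = (r1t - r10[:, None]) / meta.relaxivity_r1
    ct[~valid] = 0.0
    return ct, clamped, valid


def concentration_to_signal(ct, r10: float, meta: AcquisitionMeta, s0: float = 1000.0):
    """Forward-simulate the SPGR DCE signal for a known Ct(t) (DRO rendering)."""
    ct = np.asarray(ct, dtype=float)
    fa = meta.flip_angles_deg[0]
    r1t = r10 + meta.relaxivity_r1 * ct
    return s0 * spgr_ratio(r1t, fa, meta.tr)
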