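"""Arterial input function (AIF) handling.

The pharmacokinetic models consume the plasma CA concentration Cp(t) of the
feeding artery. Three sources are supported: a literature population curve
(bolus ramp followed by biexponential washout, parameters configurable), an
automatically detected individual AIF (voxel-wise normalised cross-correlation
against an idealised gamma-variate bolus), or a user-supplied curve (CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .concentration import invert_spgr_ratio, spgr_ratio
from .types import AcquisitionMeta

__all__ = [
    "AIFCurve",
    "population_aif",
    "auto_detect_aif",
    "gamma_variate",
    "POPULATION_AIF_PARAMS",
]

#: Default population-AIF parameters: bolus arrival and rise (s), biexponential
#: washout amplitudes (mM) and decay rates (s^-1). Peak Cp = dose*(a1+a2).
POPULATION_AIF_PARAMS = {
    "onset": 60.0,    # bolus arrival time, s
    "rise": 4.0,      # linear upslope duration, s
    "a1": 4.5,        # fast-washout amplitude, mM
    "m1": 4.0e-3,     # fast decay rate, s^-1
    "a2": 1.5,        # slow-washout amplitude, mM
    "m2": 1.7e-4,     # slow decay rate, s^-1
    "dose": 1.0,      # dimensionless dose scale
}


@dataclass
class AIFCurve:
    """Plasma CA concentration versus time."""

    times: np.ndarray   # s
    cp: np.ndarray      # mM
    source: str = "user"
    hematocrit: float = 0.45
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape:
            raise ValueError("times and cp must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("AIF times must be strictly increasing")

    def resample(self, times) -> "AIFCurve":
        times = np.asarray(times, dtype=float)
        cp = np.interp(times, self.times, self.cp, left=0.0, right=self.cp[-1])
        return AIFCurve(times=times, cp=cp, source=self.source,
                        hematocrit=self.hematocrit, meta=dict(self.meta))

    def to_csv(self, path):
        np.savetxt(path, np.column_stack([self.times, self.cp]),
                   delimiter=",", header="time_s,cp_mM", comments="")

    @classmethod
    def from_csv(cls, path, source="user", hematocrit=0.45):
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(times=arr[:, 0], cp=arr[:, 1], source=source, hematocrit=hematocrit)


def population_aif(times, params: dict | None = None, hematocrit: float = 0.45) -> AIFCurve:
    """Evaluate the population AIF on a time grid (seconds).

    Cp = 0 before bolus arrival, rises linearly over ``rise`` seconds to the
    peak dose*(a1+a2), then decays as dose*(a1*exp(-m1*t') + a2*exp(-m2*t'))
    with t' measured from the peak.
    """
    p = dict(POPULATION_AIF_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown population-AIF parameters: {sorted(unknown)}")
        p.update(params)
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t_peak = p["onset"] + p["rise"]
    peak = p["a1"] + p["a2"]
    cp = np.zeros_like(t)
    rising = (t >= p["onset"]) & (t < t_peak)
    cp[rising] = peak * (t[rising] - p["onset"]) / p["rise"]
    after = t >= t_peak
    tp = t[after] - t_peak
    cp[after] = p["a1"] * np.exp(-p["m1"] * tp) + p["a2"] * np.exp(-p["m2"] * tp)
    return AIFCurve(times=t, cp=p["dose"] * cp, source="population",
                    hematocrit=hematocrit, meta={"params": p})


def gamma_variate(t, t0: float = 0.0, alpha: float = 3.0, tp: float = 6.0):
    """Peak-normalised gamma-variate bolus shape, peak at t0 + tp."""
    t = np.asarray(t, dtype=float)
    x = (t - t0) / tp
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = x[pos] ** alpha * np.exp(alpha * (1.0 - x[pos]))
    return out


def idealized_bolus(t, t0: float = 0.0, alpha: float = 3.0, tp: float = 6.0,
                    tail: float = 0.4, tau_tail: float = 15.0):
    """Idealised arterial bolus reference: a gamma-variate first pass plus a
    recirculation plateau rising with time constant ``tau_tail`` to ``tail``
    of the peak. Used as the cross-correlation template for AIF detection."""
    t = np.asarray(t, dtype=float)
    gv = gamma_variate(t, t0=t0, alpha=alpha, tp=tp)
    plateau = np.where(t > t0, tail * (1.0 - np.exp(-(t - t0) / tau_tail)), 0.0)
    return gv + plateau


def _ncc(a, b):
    """Normalised (Pearson) cross-correlation of two curves."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def auto_detect_aif(series, blood_t10: float, meta: AcquisitionMeta,
                    n_voxels: int = 10, baseline_frames: int = 5,
                    hematocrit: float = 0.45, enhancement_threshold: float = 0.2,
                    gamma_alpha: float = 3.0, gamma_tp: float = 6.0,
                    return_indices: bool = False):
    """Detect arterial voxels and extract an individual AIF.

    Every voxel's baseline-subtracted curve is scored by its maximal
    normalised cross-correlation against an idealised gamma-variate bolus
    swept over candidate onset times. Candidates (top decile of correlation)
    are filtered for early peak time (no later than the median candidate
    peak) and high peak amplitude (upper quartile). The mean signal of the
    top ``n_voxels`` surviving voxels is converted to whole-blood
    concentration via the blood T10 SPGR inversion and to plasma
    concentration by division by (1 - hematocrit).
    """
    from .io import ImageSeries4D

    if isinstance(series, ImageSeries4D):
        X = series.data.reshape(-1, series.n_frames)
    else:
        X = np.atleast_2d(np.asarray(series, dtype=float))
    times = np.asarray(meta.frame_times, dtype=float)
    n_frames = X.shape[1]
    if n_frames < 20:
        raise ValueError("AIF detection requires >= 20 DCE frames")

    base = X[:, :baseline_frames].mean(axis=1)
    peak = X.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        enh = np.where(base > 0, (peak - base) / base, 0.0)
    if not np.any(enh > enhancement_threshold):
        raise ValueError(
            "no voxel enhances above threshold; no bolus visible - "
            "use a population or user-supplied AIF"
        )

    # reference bank: idealised boluses (gamma variate + recirculation
    # plateau) swept over candidate onsets
    onsets = times[baseline_frames:max(baseline_frames + 1, n_frames // 2):2]
    refs = [idealized_bolus(times, t0=t0, alpha=gamma_alpha, tp=gamma_tp)
            for t0 in onsets]

    cand_pool = np.flatnonzero(enh > enhancement_threshold)
    curves = X[cand_pool] - base[cand_pool, None]
    scores = np.array([max(_ncc(c, r) for r in refs) for c in curves])

    top = scores >= np.quantile(scores, 0.9)
    cand = cand_pool[top]
    peak_t = times[np.argmax(X[cand], axis=1)]
    amp = peak[cand] - base[cand]
    keep = (peak_t <= np.median(peak_t)) & (amp >= np.quantile(amp, 0.75))
    if not np.any(keep):
        keep = amp >= np.quantile(amp, 0.75)
    cand = cand[keep]
    order = np.argsort(-(peak[cand] - base[cand]))
    chosen = cand[order[:n_voxels]]

    mean_sig = X[chosen].mean(axis=0)
    fa, tr = meta.flip_angles_deg[0], meta.tr
    r10b = 1.0 / blood_t10
    s_base = mean_sig[:baseline_frames].mean()
    s_rel = mean_sig / s_base * spgr_ratio(r10b, fa, tr)
    r1t, _ = invert_spgr_ratio(s_rel, fa, tr)
    cb = (r1t - r10b) / meta.relaxivity_r1          # whole-blood CA, mM
    cp = np.clip(cb, 0.0, None) / (1.0 - hematocrit)
    curve = AIFCurve(times=times, cp=cp, source="auto", hematocrit=hematocrit,
                     meta={"n_voxels": int(len(chosen))})
    if return_indices:
        return curve, chosen
    return curve
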