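"""T1 and T2 relaxometry.

Pre-contrast T1 is mapped from multi-flip-angle spoiled-gradient-recalled
(SPGR/VFA) acquisitions; T2 from multi-echo spin-echo decays S = S0 exp(-TE/T2).

The SPGR steady-state signal is

    S(alpha) = S0 * sin(alpha) * (1 - E1) / (1 - cos(alpha) * E1),
    E1 = exp(-TR / T1),

fitted per voxel by bounded nonlinear least squares initialised from the
DESPOT1 linearisation (S/sin(alpha) against S/tan(alpha), slope = E1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._base import VoxelwiseFitter, bounded_least_squares
from .types import FitResult

__all__ = [
    "spgr_signal",
    "T1FitInput",
    "T2FitInput",
    "VFAT1Fitter",
    "MultiEchoT2Fitter",
    "fit_t1_vfa",
    "fit_t2_me",
]

# physiological plausibility bounds, seconds; organ presets may override
T1_BOUNDS = (0.05, 10.0)
T2_BOUNDS = (0.005, 3.0)


def spgr_signal(s0, t1, fa_deg, tr):
    """SPGR steady-state signal intensity.

    Parameters are broadcast; ``t1`` and ``tr`` in seconds, ``fa_deg`` in
    degrees. Raises for non-positive T1/TR or flip angles outside (0, 180).
    """
    t1 = np.asarray(t1, dtype=float)
    fa = np.asarray(fa_deg, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    if tr <= 0:
        raise ValueError("TR must be positive")
    if np.any(fa <= 0) or np.any(fa >= 180):
        raise ValueError("flip angle must lie in (0, 180) degrees")
    a = np.deg2rad(fa)
    e1 = np.exp(-tr / t1)
    return s0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


@dataclass
class T1FitInput:
    """Signals acquired at multiple flip angles with a common TR."""

    signals: np.ndarray
    flip_angles_deg: np.ndarray
    tr: float

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.flip_angles_deg = np.asarray(self.flip_angles_deg, dtype=float)
        if len(np.unique(self.flip_angles_deg)) < 2:
            raise ValueError("need >= 2 distinct flip angles")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")


@dataclass
class T2FitInput:
    """Signals acquired at multiple echo times."""

    signals: np.ndarray
    echo_times: np.ndarray

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if len(np.unique(self.echo_times)) < 2:
            raise ValueError("need >= 2 distinct echo times")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")


def despot1_linear(signals, flip_angles_deg, tr):
    """Closed-form DESPOT1 estimate (s0, t1) from the linearised SPGR model.

    Returns (nan, nan) for degenerate input (zero or constant-over-sin data).
    """
    a = np.deg2rad(np.asarray(flip_angles_deg, float))
    s = np.asarray(signals, float)
    x = s / np.tan(a)
    y = s / np.sin(a)
    vx = np.sum((x - x.mean()) ** 2)
    if vx <= 0 or np.all(s == 0):
        return np.nan, np.nan
    slope = np.sum((x - x.mean()) * (y - y.mean())) / vx
    intercept = y.mean() - slope * x.mean()
    if not (0 < slope < 1):
        return np.nan, np.nan
    t1 = -tr / np.log(slope)
    s0 = intercept / (1.0 - slope)
    return s0, t1


class VFAT1Fitter(VoxelwiseFitter):
    """Voxel-wise T1 mapping from variable-flip-angle SPGR data.

    Parameters
    ----------
    flip_angles_deg : sequence of float
    tr : float
        Repetition time, seconds.
    t1_bounds : (float, float)
        T1 search interval in seconds; default [0.05, 10].
    refine : bool
        Run bounded nonlinear least squares after the DESPOT1 linearisation
        (default True; False returns the linearised estimate).
    """

    param_names = ("s0", "t10")

    def __init__(self, flip_angles_deg=(2, 5, 10, 15, 25), tr=0.005,
                 t1_bounds=T1_BOUNDS, refine=True, max_nfev=100):
        self.flip_angles_deg = flip_angles_deg
        self.tr = tr
        self.t1_bounds = t1_bounds
        self.refine = refine
        self.max_nfev = max_nfev

    def _forward(self, theta):
        return spgr_signal(theta[0], theta[1], np.asarray(self.flip_angles_deg, float), self.tr)

    def _fit_voxel(self, y):
        fas = np.asarray(self.flip_angles_deg, float)
        if np.all(y == 0) or np.ptp(y) == 0:
            # non-identifiable: flat or empty voxel
            return np.array([np.nan, np.nan]), np.zeros_like(y), False, 0
        s0_lin, t1_lin = despot1_linear(y, fas, self.tr)
        lo, hi = self.t1_bounds
        if not np.isfinite(t1_lin):
            t1_lin = np.sqrt(lo * hi)
            s0_lin = y.max() * 10.0
        t1_lin = np.clip(t1_lin, lo, hi)
        if not self.refine:
            th = np.array([s0_lin, t1_lin])
            return th, self._forward(th), True, 0

        def resid(th):
            return spgr_signal(th[0], th[1], fas, self.tr) - y

        sol = bounded_least_squares(resid, [max(s0_lin, 1e-9), t1_lin],
                                    ([0.0, lo], [np.inf, hi]), max_nfev=self.max_nfev)
        return sol.x, self._forward(sol.x), sol.success, sol.nfev


class MultiEchoT2Fitter(VoxelwiseFitter):
    """Voxel-wise T2 mapping from multi-echo spin-echo decays.

    Log-linear fit of ln S against TE, with optional nonlinear refinement and
    optional exclusion of the first echo (stimulated-echo contamination).
    Voxels with non-positive signal fall back to the nonlinear path.
    """

    param_names = ("s0", "t2")

    def __init__(self, echo_times=(0.01, 0.02, 0.04, 0.08), t2_bounds=T2_BOUNDS,
                 refine=False, exclude_first_echo=False, max_nfev=100):
        self.echo_times = echo_times
        self.t2_bounds = t2_bounds
        self.refine = refine
        self.exclude_first_echo = exclude_first_echo
        self.max_nfev = max_nfev

    def _forward(self, theta):
        te = np.asarray(self.echo_times, float)
        return theta[0] * np.exp(-te / theta[1])

    def _loglinear(self, te, y):
        A = np.vstack([np.ones_like(te), -te]).T
        coef, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
        s0 = np.exp(coef[0])
        r2rate = coef[1]
        return s0, r2rate

    def _fit_voxel(self, y):
        te = np.asarray(self.echo_times, float)
        if self.exclude_first_echo and len(te) > 2:
            te_fit, y_fit = te[1:], y[1:]
        else:
            te_fit, y_fit = te, y
        lo, hi = self.t2_bounds
        if np.ptp(y_fit) == 0:
            # constant signal: no decay resolvable, T2 pinned at upper bound
            th = np.array([y_fit.mean(), hi])
            return th, self._forward(th), False, 0
        nonlinear = self.refine
        s0 = t2 = np.nan
        if np.all(y_fit > 0):
            s0, r2rate = self._loglinear(te_fit, y_fit)
            if r2rate > 0:
                t2 = np.clip(1.0 / r2rate, lo, hi)
            else:
                t2 = hi
                nonlinear = True
        else:
            nonlinear = True
        if not np.isfinite(t2):
            t2, s0 = np.sqrt(lo * hi), max(y_fit.max(), 1e-9)
            nonlinear = True
        if nonlinear:
            def resid(th):
                return th[0] * np.exp(-te_fit / th[1]) - y_fit

            sol = bounded_least_squares(resid, [max(s0, 1e-9), t2],
                                        ([0.0, lo], [np.inf, hi]),
                                        max_nfev=self.max_nfev)
            s0, t2 = sol.x
            th = np.array([s0, t2])
            return th, self._forward(th), sol.success, sol.nfev
        th = np.array([s0, t2])
        return th, self._forward(th), True, 0


def fit_t1_vfa(input: T1FitInput, **kwargs) -> FitResult:
    """Fit the SPGR VFA model for one voxel; params {s0, t10} (T10 seconds)."""
    est = VFAT1Fitter(flip_angles_deg=input.flip_angles_deg, tr=input.tr, **kwargs)
    return est.fit_voxel(input.signals)


def fit_t2_me(input: T2FitInput, **kwargs) -> FitResult:
    """Fit the mono-exponential T2 decay for one voxel; params {s0, t2}."""
    est = MultiEchoT2Fitter(echo_times=input.echo_times, **kwargs)
    res = est.fit_voxel(input.signals)
    if res.params["t2"] >= est.t2_bounds[1] - 1e-12:
        res.flags.append("t2_upper_bound")
    return res
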