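"""Multi-b-value diffusion-weighted signal models and fits.

Four trace-weighted models form a nesting lattice:

* mono    — S = S0 exp(-b ADC)
* DKI     — S = S0 exp(-b Dapp + (1/6) Kapp (b Dapp)^2)
* IVIM    — S = S0 [f exp(-b D*) + (1-f) exp(-b D)]
* NG-IVIM — S = S0 [f exp(-b D*) + (1-f) exp(-b D + (1/6) K (b D)^2)]

so NG-IVIM contains IVIM (K=0) and DKI (f=0), each of which contains the
mono-exponential. Diffusivities are mm^2/s, b in s/mm^2. ADC comes from a
log-linear regression; the others from bounded nonlinear least squares with
staged initialisation (IVIM segmented over a configurable b threshold).
"""

from __future__ import annotations

import warnings

import numpy as np

from ._base import VoxelwiseFitter, bounded_least_squares
from .types import FitResult

__all__ = [
    "mono_signal", "dki_signal", "ivim_signal", "ngivim_signal",
    "ADCFitter", "DKIFitter", "IVIMFitter", "NGIVIMFitter",
    "fit_adc", "fit_dki", "fit_ivim", "fit_ngivim",
    "DW_DEFAULT_BOUNDS",
]

DW_DEFAULT_BOUNDS = {
    "adc": (1e-6, 4e-3),
    "d": (1e-6, 4e-3),
    "dstar": (1e-3, 0.5),     # pseudo-diffusion, mm^2/s
    "f": (0.0, 1.0),
    "dapp": (1e-6, 4e-3),
    "kapp": (0.0, 3.0),
    "k": (0.0, 3.0),
    "s0": (0.0, np.inf),
}


def mono_signal(s0, adc, b):
    """Mono-exponential DW signal."""
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-b * adc)


def dki_signal(s0, dapp, kapp, b):
    """Diffusion-kurtosis DW signal (second-order cumulant expansion)."""
    b = np.asarray(b, dtype=float)
    bd = b * dapp
    return s0 * np.exp(-bd + kapp * bd ** 2 / 6.0)


def ivim_signal(s0, f, dstar, d, b):
    """Biexponential intravoxel-incoherent-motion signal."""
    b = np.asarray(b, dtype=float)
    return s0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * d))


def ngivim_signal(s0, f, dstar, d, k, b):
    """Non-Gaussian IVIM: perfusion branch plus kurtosis tissue branch."""
    b = np.asarray(b, dtype=float)
    bd = b * d
    return s0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-bd + k * bd ** 2 / 6.0))


def _loglinear_adc(b, y):
    """(s0, adc) from linear regression of ln S on b; None if degenerate."""
    pos = y > 0
    if pos.sum() < 2 or len(np.unique(b[pos])) < 2:
        return None
    coef = np.polyfit(b[pos], np.log(y[pos]), 1)
    return float(np.exp(coef[1])), float(max(-coef[0], 0.0))


class _DWFitterBase(VoxelwiseFitter):
    def __init__(self, b_values=(0, 30, 80, 200, 500, 800, 1500, 2000),
                 bounds=None, max_nfev=200):
        self.b_values = b_values
        self.bounds = bounds
        self.max_nfev = max_nfev

    def _b(self):
        return np.asarray(self.b_values, dtype=float)

    def _bounds_arrays(self, names):
        b = dict(DW_DEFAULT_BOUNDS)
        if self.bounds:
            b.update(self.bounds)
        lo = np.array([b[n][0] for n in names], float)
        hi = np.array([b[n][1] for n in names], float)
        return lo, hi


class ADCFitter(_DWFitterBase):
    """Log-linear ADC mapping: regression of ln S on b.

    Non-positive signals are excluded from the log fit; voxels with fewer
    than two usable points are flagged invalid.
    """

    param_names = ("s0", "adc")

    def _forward(self, theta):
        return mono_signal(theta[0], theta[1], self._b())

    def _fit_voxel(self, y):
        b = self._b()
        res = _loglinear_adc(b, y)
        if res is None:
            return np.array([np.nan, np.nan]), np.zeros_like(y), False, 0
        s0, adc = res
        th = np.array([s0, adc])
        return th, self._forward(th), True, 0


class DKIFitter(_DWFitterBase):
    """Bounded nonlinear kurtosis fit, initialised from a quadratic
    polynomial fit of ln S in b."""

    param_names = ("s0", "dapp", "kapp")

    def __init__(self, b_values=(0, 30, 80, 200, 500, 800, 1500, 2000),
                 bounds=None, max_nfev=200, min_high_b=1000.0):
        super().__init__(b_values, bounds, max_nfev)
        self.min_high_b = min_high_b

    def _forward(self, theta):
        return dki_signal(theta[0], theta[1], theta[2], self._b())

    def _init(self, b, y):
        pos = y > 0
        if pos.sum() >= 3:
            c2, c1, c0 = np.polyfit(b[pos], np.log(y[pos]), 2)
            dapp = max(-c1, 1e-6)
            kapp = max(6.0 * c2 / dapp ** 2, 0.0) if dapp > 0 else 0.5
            return np.exp(c0), dapp, kapp
        return max(y.max(), 1e-9), 1e-3, 0.5

    def _fit_voxel(self, y):
        b = self._b()
        if b.max() < self.min_high_b:
            warnings.warn("DKI fit without b >= 1000 s/mm^2 is poorly conditioned")
        lo, hi = self._bounds_arrays(self.param_names)
        hi = hi.copy()
        hi[0] = max(10.0 * y.max(), 1.0)
        x0 = np.clip(self._init(b, y), lo, hi)

        def resid(th):
            return dki_signal(th[0], th[1], th[2], b) - y

        sol = bounded_least_squares(resid, x0, (lo, hi), max_nfev=self.max_nfev)
        return sol.x, self._forward(sol.x), sol.success, sol.nfev


class IVIMFitter(_DWFitterBase):
    """IVIM fit, segmented (default) or simultaneous.

    Segmented: D and the tissue intercept from a mono-exponential fit over
    b >= ``b_threshold``; then (s0, f, D*) by bounded least squares on all b
    with D held fixed; the pseudo-diffusion contribution remaining above the
    threshold is then subtracted and the two stages repeated
    (``n_segmented_iter`` passes, which removes the D bias a slow D* leaks
    into the high-b segment). Simultaneous: all four parameters jointly.
    """

    param_names = ("s0", "f", "dstar", "d")

    def __init__(self, b_values=(0, 30, 80, 200, 500, 800, 1500, 2000),
                 bounds=None, max_nfev=200, method="segmented", b_threshold=200.0,
                 n_segmented_iter=3):
        super().__init__(b_values, bounds, max_nfev)
        self.method = method
        self.b_threshold = b_threshold
        self.n_segmented_iter = n_segmented_iter

    def _forward(self, theta):
        return ivim_signal(theta[0], theta[1], theta[2], theta[3], self._b())

    def _fit_voxel(self, y):
        b = self._b()
        lo, hi = self._bounds_arrays(self.param_names)
        hi = hi.copy()
        hi[0] = max(10.0 * y.max(), 1.0)

        high = b >= self.b_threshold
        seg = _loglinear_adc(b[high], y[high]) if high.sum() >= 2 else None
        if seg is None:
            seg = _loglinear_adc(b, y)
        if seg is None:
            return np.full(4, np.nan), np.zeros_like(y), False, 0
        s_int, d0 = seg
        d0 = float(np.clip(d0, lo[3], hi[3]))
        s_b0 = y[np.argmin(b)]
        f0 = float(np.clip(1.0 - s_int / s_b0 if s_b0 > 0 else 0.1, 0.0, 0.6))
        s00 = s_b0 if s_b0 > 0 else max(y.max(), 1e-9)

        if self.method == "segmented":
            x = [s00, f0, 2e-2]
            for it in range(max(self.n_segmented_iter, 1)):
                def resid(th, d=d0):  # th = (s0, f, dstar); D fixed
                    return ivim_signal(th[0], th[1], th[2], d, b) - y

                sol = bounded_least_squares(resid, x, (lo[:3], hi[:3]),
                                            max_nfev=self.max_nfev)
                x = list(sol.x)
                if it == self.n_segmented_iter - 1:
                    break
                # subtract the remaining perfusion signal and re-fit D
                y_corr = y - x[0] * x[1] * np.exp(-b * x[2])
                seg = _loglinear_adc(b[high], y_corr[high])
                if seg is None:
                    break
                d0 = float(np.clip(seg[1], lo[3], hi[3]))
            th = np.array([*x, d0])
        elif self.method == "simultaneous":
            def resid(th):
                return ivim_signal(*th, b) - y

            sol = bounded_least_squares(resid, [s00, f0, 2e-2, d0],
                                        (lo, hi), max_nfev=self.max_nfev)
            th = sol.x
        else:
            raise ValueError("method must be 'segmented' or 'simultaneous'")
        return th, self._forward(th), sol.success, sol.nfev


class NGIVIMFitter(_DWFitterBase):
    """Non-Gaussian IVIM fit.

    Staged: kurtosis branch (D, K) on b >= ``b_threshold`` with the perfusion
    term neglected, perfusion branch (f, D*) with the tissue branch fixed,
    then a joint bounded refinement of all five parameters.
    """

    param_names = ("s0", "f", "dstar", "d", "k")

    def __init__(self, b_values=(0, 30, 80, 200, 500, 800, 1500, 2000),
                 bounds=None, max_nfev=300, b_threshold=200.0):
        super().__init__(b_values, bounds, max_nfev)
        self.b_threshold = b_threshold

    def _forward(self, theta):
        return ngivim_signal(theta[0], theta[1], theta[2], theta[3], theta[4],
                             self._b())

    def _fit_voxel(self, y):
        b = self._b()
        lo, hi = self._bounds_arrays(self.param_names)
        hi = hi.copy()
        hi[0] = max(10.0 * y.max(), 1.0)

        # stage 1: kurtosis branch on high b
        high = b >= self.b_threshold
        pos = high & (y > 0)
        if pos.sum() >= 3:
            c2, c1, c0 = np.polyfit(b[pos], np.log(y[pos]), 2)
            d0 = float(np.clip(max(-c1, 1e-6), lo[3], hi[3]))
            k0 = float(np.clip(6.0 * c2 / d0 ** 2, lo[4], hi[4]))
            s_int = float(np.exp(c0))
        else:
            d0, k0, s_int = 1e-3, 0.5, max(y.max(), 1e-9)
        # stage 2: perfusion branch
        s_b0 = y[np.argmin(b)]
        f0 = float(np.clip(1.0 - s_int / s_b0 if s_b0 > 0 else 0.1, 0.0, 0.6))
        s00 = s_b0 if s_b0 > 0 else max(y.max(), 1e-9)
        # stage 3: joint refinement
        def resid(th):
            return ngivim_signal(*th, b) - y

        sol = bounded_least_squares(resid, [s00, f0, 2e-2, d0, k0],
                                    (lo, hi), max_nfev=self.max_nfev)
        return sol.x, self._forward(sol.x), sol.success, sol.nfev


def _single(est, signals) -> FitResult:
    return est.fit_voxel(np.asarray(signals, dtype=float))


def fit_adc(signals, b_values, **kw) -> FitResult:
    """Log-linear mono-exponential ADC fit for one voxel."""
    return _single(ADCFitter(b_values=b_values, **kw), signals)


def fit_dki(signals, b_values, **kw) -> FitResult:
    """Kurtosis fit (s0, Dapp, Kapp) for one voxel."""
    return _single(DKIFitter(b_values=b_values, **kw), signals)


def fit_ivim(signals, b_values, method="segmented", **kw) -> FitResult:
    """IVIM fit (s0, f, D*, D) for one voxel."""
    return _single(IVIMFitter(b_values=b_values, method=method, **kw), signals)


def fit_ngivim(signals, b_values, **kw) -> FitResult:
    """NG-IVIM fit (s0, f, D*, D, K) for one voxel."""
    return _single(NGIVIMFitter(b_values=b_values, **kw), signals)
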