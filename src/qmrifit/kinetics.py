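"""DCE pharmacokinetic forward models and voxel-wise fitting.

Six tracer-kinetic models are provided:

* TM    — Tofts model, Ct = Ktrans * exp(-kep t) (x) Cp, kep = Ktrans/ve
* ETM   — extended Tofts, TM + vp*Cp
* PM    — Patlak, Ktrans * int Cp dt + vp*Cp (no backflux)
* FXR   — shutter-speed (two-site water exchange), fitted in signal space
* CTUM  — compartmental tissue uptake (Fp, PS, vp; irreversible uptake)
* 2CXM  — two-compartment exchange (Fp, PS, ve, vp)

All convolutions use an exponential integrator that treats Cp as piecewise
linear between frames — exact for exponential kernels and robust to
non-uniform frame timing. Rate constants are carried in the field-standard
min^-1 (Fp in mL/min/100mL) and converted to s^-1 internally against the
frame clock.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from ._base import VoxelwiseFitter, bounded_least_squares
from .aif import AIFCurve
from .concentration import spgr_ratio
from .types import PKParams

__all__ = [
    "conv_exp",
    "tm_conc",
    "etm_conc",
    "pm_conc",
    "ctum_conc",
    "twocxm_conc",
    "fxr_r1",
    "two_site_exchange_r1",
    "DCEFitter",
    "fit_dce",
    "DCE_MODELS",
    "DEFAULT_BOUNDS",
]

PER_MIN = 1.0 / 60.0  # min^-1 -> s^-1

#: default parameter bounds (field-standard units); organ presets override
DEFAULT_BOUNDS = {
    "ktrans": (0.0, 5.0),        # min^-1
    "ve": (1e-3, 1.0),
    "vp": (0.0, 0.5),
    "fp": (0.0, 500.0),          # mL/min/100mL
    "ps": (0.0, 5.0),            # min^-1
    "tau_i": (0.05, 3.0),        # s
}

DCE_MODELS = {
    "tm": ("ktrans", "ve"),
    "etm": ("ktrans", "ve", "vp"),
    "pm": ("ktrans", "vp"),
    "fxr": ("ktrans", "ve", "tau_i"),
    "ctum": ("fp", "ps", "vp"),
    "2cxm": ("fp", "ps", "ve", "vp"),
}


def conv_exp(cp, times, rate):
    """Causal convolution of Cp(t) with exp(-rate*t) on the frame grid.

    ``rate`` is in s^-1 (callers convert from min^-1); ``rate=0`` yields the
    running trapezoidal integral of Cp. Cp is assumed piecewise linear
    between frames, for which the per-interval integrals have closed forms;
    the recursion is evaluated with an IIR filter on uniform grids.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    cp = np.asarray(cp, dtype=float)
    t = np.asarray(times, dtype=float)
    dt = np.diff(t)
    kd = rate * dt
    ek = np.exp(-kd)
    with np.errstate(divide="ignore", invalid="ignore"):
        i0 = np.where(kd > 1e-8, -np.expm1(-kd) / rate, dt * (1.0 - kd / 2.0))
        small = kd < 1e-4
        i1 = np.empty_like(dt)
        i1[small] = dt[small] ** 2 * (0.5 - kd[small] / 3.0 + kd[small] ** 2 / 8.0)
        big = ~small
        i1[big] = (1.0 - (1.0 + kd[big]) * ek[big]) / rate ** 2
    c0, c1 = cp[:-1], cp[1:]
    contrib = c1 * i0 + (c0 - c1) * i1 / dt
    x = np.concatenate([[0.0], contrib])
    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        # uniform grid: y[n] = ek*y[n-1] + x[n] is a first-order IIR filter
        return lfilter([1.0], [1.0, -ek[0]], x)
    y = np.empty_like(cp)
    y[0] = 0.0
    for n in range(1, len(cp)):
        y[n] = y[n - 1] * ek[n - 1] + x[n]
    return y


def _tm(kt, ve, aif):
    kep_s = (kt / ve) * PER_MIN if kt > 0 else 0.0
    return kt * PER_MIN * conv_exp(aif.cp, aif.times, kep_s)


def tm_conc(params: PKParams, aif: AIFCurve):
    """Tofts model tissue concentration (mM)."""
    return _tm(params.ktrans, params.ve, aif)


def etm_conc(params: PKParams, aif: AIFCurve):
    """Extended Tofts model tissue concentration (mM)."""
    return _tm(params.ktrans, params.ve, aif) + params.vp * aif.cp


def pm_conc(params: PKParams, aif: AIFCurve):
    """Patlak model: irreversible uptake plus vascular term."""
    return params.ktrans * PER_MIN * conv_exp(aif.cp, aif.times, 0.0) + params.vp * aif.cp


def _ctum(fp, ps, vp, aif):
    fp_s = fp / 100.0 * PER_MIN   # mL/min/100mL -> s^-1 per unit tissue
    ps_s = ps * PER_MIN
    if vp <= 0:
        raise ValueError("CTUM requires vp > 0")
    if fp_s + ps_s == 0:
        return np.zeros_like(aif.cp)
    e = ps_s / (ps_s + fp_s)
    inv_tp = (fp_s + ps_s) / vp
    out = fp_s * (1.0 - e) * conv_exp(aif.cp, aif.times, inv_tp)
    if e > 0:
        out = out + fp_s * e * conv_exp(aif.cp, aif.times, 0.0)
    return out


def ctum_conc(params: PKParams, aif: AIFCurve):
    """Compartmental tissue uptake model (Fp, PS, vp; irreversible uptake).

    Impulse response Fp*[(1-E) exp(-t/Tp) + E] with extraction E=PS/(PS+Fp)
    and plasma transit time Tp = vp/(Fp+PS).
    """
    return _ctum(params.fp, params.ps, params.vp, aif)


def _twocxm_exponents(fp_s, ps_s, ve, vp):
    """Amplitudes and rates of the biexponential 2CXM impulse response.

    Returns (a1, lam1, a2, lam2) with H(t) = a1 exp(-lam1 t) + a2 exp(-lam2 t).
    """
    if vp <= 0 or ve <= 0:
        raise ValueError("2CXM requires ve > 0 and vp > 0")
    k11 = (fp_s + ps_s) / vp
    k12 = ps_s / vp
    k21 = ps_s / ve
    s = k11 + k21
    p = k11 * k21 - k12 * k21
    disc = max(s * s - 4.0 * p, 0.0)
    root = np.sqrt(disc)
    lam1 = 0.5 * (s + root)
    lam2 = 0.5 * (s - root)
    u0 = fp_s / vp
    # solve u(t) = c1 v1 e^{-lam1 t} + c2 v2 e^{-lam2 t} for u(0)=(u0, 0)
    # with system du/dt = -M u; eigenvectors of M = [[k11,-k12],[-k21,k21]]
    if root < 1e-14 * max(s, 1.0):
        root = 1e-14 * max(s, 1.0)  # guard against the defective (equal-root) case
        lam1 = lam2 + root
    if k12 == 0.0:
        # PS=0: compartments decouple, eigenvalues are exactly (k11, k21)
        v1, v2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    else:
        # eigenvector for lam: (k11-lam) x1 - k12 x2 = 0 -> x = (k12, k11-lam)
        v1 = np.array([k12, k11 - lam1])
        v2 = np.array([k12, k11 - lam2])
    V = np.column_stack([v1, v2])
    c = np.linalg.solve(V, np.array([u0, 0.0]))
    w = np.array([vp, ve])  # Ct = vp C1 + ve C2
    a1 = c[0] * (w @ v1)
    a2 = c[1] * (w @ v2)
    return a1, lam1, a2, lam2


def _twocxm(fp, ps, ve, vp, aif):
    fp_s = fp / 100.0 * PER_MIN
    ps_s = ps * PER_MIN
    if fp_s == 0:
        return np.zeros_like(aif.cp)
    a1, lam1, a2, lam2 = _twocxm_exponents(fp_s, ps_s, ve, vp)
    return (a1 * conv_exp(aif.cp, aif.times, lam1)
            + a2 * conv_exp(aif.cp, aif.times, lam2))


def twocxm_conc(params: PKParams, aif: AIFCurve):
    """Two-compartment exchange model tissue concentration (mM)."""
    return _twocxm(params.fp, params.ps, params.ve, params.vp, aif)


def two_site_exchange_r1(ce, r1i, r10e, kie, kei, r1_relax):
    """Smaller-eigenvalue longitudinal relaxation rate of the two-site
    (ICS/EES) water-exchange system, per the shutter-speed model."""
    ce = np.asarray(ce, dtype=float)
    a = r1i + kie + r10e + r1_relax * ce + kei
    d = r1i + kie - r10e - r1_relax * ce - kei
    return 0.5 * (a - np.sqrt(d * d + 4.0 * kie * kei))


def _fxr(kt, ve, tau_i, aif, r10, r1_relax, r1i=np.nan, r10e=np.nan):
    if ve <= 0:
        raise ValueError("FXR requires ve > 0")
    ce = _tm(kt, ve, aif) / ve
    kie = 1.0 / tau_i
    pe, pi = ve, 1.0 - ve
    kei = kie * pi / pe
    r1i = r1i if np.isfinite(r1i) else r10
    r10e = r10e if np.isfinite(r10e) else r10
    return two_site_exchange_r1(ce, r1i, r10e, kie, kei, r1_relax)


def fxr_r1(params: PKParams, aif: AIFCurve, r10: float, r1_relax: float):
    """Shutter-speed (FXR) R1(t) series, s^-1.

    EES concentration Ce = Ct/ve with Ct from the Tofts model; exchange rates
    kie = 1/tau_i and kei from two-site population balance
    kie*(1-ve) = kei*ve (vascular water ignored). Pre-contrast R1 of both
    sites defaults to the tissue R10 when not set in ``params``.
    """
    return _fxr(params.ktrans, params.ve, params.tau_i, aif, r10, r1_relax,
                params.r1i, params.r10e)


def _forward_conc(model, theta, aif):
    # raw parameter vectors: no box validation (optimizer iterates may sit
    # transiently outside the joint-feasibility region, e.g. ve + vp > 1)
    if model == "tm":
        return _tm(theta[0], theta[1], aif)
    if model == "etm":
        return _tm(theta[0], theta[1], aif) + theta[2] * aif.cp
    if model == "pm":
        return (theta[0] * PER_MIN * conv_exp(aif.cp, aif.times, 0.0)
                + theta[1] * aif.cp)
    if model == "ctum":
        return _ctum(theta[0], theta[1], theta[2], aif)
    if model == "2cxm":
        return _twocxm(theta[0], theta[1], theta[2], theta[3], aif)
    raise ValueError(f"unknown concentration-space model '{model}'")


class DCEFitter(VoxelwiseFitter):
    """Voxel-wise bounded nonlinear least-squares DCE model fitting.

    TM/ETM/PM/CTUM/2CXM are fitted in concentration space (X rows are Ct
    curves in mM); FXR is fitted in signal space (X rows are raw SPGR signal
    curves) because the model is intrinsically nonlinear in R1.

    Parameters
    ----------
    model : str
        One of ``tm, etm, pm, fxr, ctum, 2cxm``.
    aif : AIFCurve
        Plasma concentration on the DCE frame grid.
    bounds : dict, optional
        Per-parameter (lo, hi) overrides of the defaults.
    n_starts : int
        Multi-start count for the harder models (2CXM, FXR); log-spaced
        deterministic grid seeded from ``seed``.
    r10, r1_relax, fa_deg, tr, baseline_frames :
        Signal-space settings, used by FXR only.
    """

    def __init__(self, model="etm", aif=None, bounds=None, n_starts=5, seed=0,
                 r10=1.0, r1_relax=4.5, fa_deg=25.0, tr=0.005,
                 baseline_frames=5, max_nfev=200):
        self.model = model
        self.aif = aif
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed
        self.r10 = r10
        self.r1_relax = r1_relax
        self.fa_deg = fa_deg
        self.tr = tr
        self.baseline_frames = baseline_frames
        self.max_nfev = max_nfev

    @property
    def param_names(self):
        return DCE_MODELS[self.model]

    def _bounds_arrays(self):
        b = dict(DEFAULT_BOUNDS)
        if self.bounds:
            b.update(self.bounds)
        names = self.param_names
        lo = np.array([b[n][0] for n in names], float)
        hi = np.array([b[n][1] for n in names], float)
        # ve/vp lower bounds: exchange models need strictly positive volumes
        if self.model in ("ctum", "2cxm"):
            lo[names.index("vp")] = max(lo[names.index("vp")], 1e-4)
        return lo, hi

    def _forward(self, theta):
        if self.model == "fxr":
            return self._fxr_signal(theta)
        return _forward_conc(self.model, theta, self.aif)

    def _fxr_signal(self, theta):
        r1t = _fxr(theta[0], theta[1], theta[2], self.aif, self.r10, self.r1_relax)
        # baseline-normalised signal: scale drops out
        return spgr_ratio(r1t, self.fa_deg, self.tr) / spgr_ratio(
            self.r10, self.fa_deg, self.tr)

    def _starts(self, y, lo, hi):
        names = self.param_names
        mid = {"ktrans": 0.1, "ve": 0.2, "vp": 0.02, "fp": 30.0, "ps": 0.3,
               "tau_i": 0.3}
        x0 = np.array([np.clip(mid[n], lo[i] + 1e-9, hi[i] - 1e-9)
                       for i, n in enumerate(names)])
        starts = [x0]
        if self.model in ("tm", "etm", "pm"):
            # Patlak linear seed: regress y on [int Cp, Cp]
            icp = conv_exp(self.aif.cp, self.aif.times, 0.0)
            A = np.column_stack([icp * PER_MIN, self.aif.cp])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            kt0 = float(np.clip(coef[0], 1e-4, hi[names.index("ktrans")]))
            seed = dict(zip(names, x0))
            seed["ktrans"] = kt0
            if "vp" in names:
                seed["vp"] = float(np.clip(coef[1], 0.0, hi[names.index("vp")]))
            starts.insert(0, np.array([seed[n] for n in names]))
        if self.model in ("2cxm", "fxr") and self.n_starts > 1:
            rng = np.random.default_rng(self.seed)
            # deterministic log-grid jitter across the bound box interior
            for _ in range(self.n_starts - 1):
                frac = rng.uniform(0.15, 0.85, size=len(names))
                span = np.where(np.isfinite(hi), hi - lo, 1.0)
                starts.append(lo + frac * span)
        return starts

    def _fit_voxel(self, y):
        lo, hi = self._bounds_arrays()
        s_base = 1.0
        if self.model == "fxr":
            s_base = y[: self.baseline_frames].mean()
            if s_base <= 0:
                th = np.full(len(lo), np.nan)
                return th, np.zeros_like(y), False, 0
            y = y / s_base
        if self.model != "fxr" and np.allclose(y, 0.0, atol=1e-12):
            # no enhancement: Ktrans/Fp pinned to zero, flagged unconverged
            th = lo.copy()
            return th, self._forward(th), False, 0

        def resid(th):
            return self._forward(th) - y

        best = None
        for x0 in self._starts(y, lo, hi):
            sol = bounded_least_squares(resid, x0, (lo, hi), max_nfev=self.max_nfev)
            if best is None or sol.cost < best.cost:
                best = sol
            if best.cost <= 1e-24 * max(float(y @ y), 1e-30):
                break
        # yhat reported on the scale of the input row (FXR rows are raw signal)
        return best.x, self._forward(best.x) * s_base, best.success, best.nfev


def fit_dce(series, aif: AIFCurve, model: str = "etm", bounds=None, **kwargs):
    """Fit one DCE model to curves.

    ``series`` is ``(n_voxels, n_frames)`` (or a single curve) of tissue
    concentration — raw signal for FXR. Returns the fitted
    :class:`DCEFitter`, or a single :class:`~qmrifit.types.FitResult` when a
    1-D curve is given.
    """
    est = DCEFitter(model=model, aif=aif, bounds=bounds, **kwargs)
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        return est.fit_voxel(arr)
    return est.fit(arr)
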