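"""Digital reference object (DRO) synthesis.

DROs are synthetic image series with known ground-truth parameter maps,
used to validate every fitting routine end-to-end: generate -> fit ->
compare against truth. Four kinds are provided:

* ``dce``    — patch grid of pharmacokinetic parameter combinations driven by
  a shared AIF and rendered to SPGR signal, with an arterial strip carrying
  the blood signal (emulates the public QIBA-style perfusion phantom layout;
  661 frames by default).
* ``dw``     — patch grid over diffusion parameters rendered through the
  NG-IVIM signal equation (covers the whole nesting lattice).
* ``vfa_t1`` / ``me_t2`` — relaxometry grids.

Noise (Gaussian or Rician) and DICOM-style 12-bit integer scaling are applied
last; a fixed seed makes the output bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .aif import AIFCurve, population_aif
from .concentration import concentration_to_signal, signal_to_concentration_batch
from .diffusion import ngivim_signal
from .io import ImageSeries4D, ParametricMap
from .kinetics import PKParams, etm_conc, pm_conc, tm_conc, ctum_conc, twocxm_conc, fxr_r1
from .concentration import spgr_ratio
from .relaxometry import spgr_signal
from .types import AcquisitionMeta

__all__ = [
    "DROSpec", "DROBundle", "generate_dce_dro", "generate_dw_dro",
    "generate_relaxometry_dro", "generate_dro", "add_noise", "score_maps",
    "repeatability_coefficient",
    "DEFAULT_DCE_GRID", "DEFAULT_DW_GRID", "DEFAULT_B_VALUES",
]

#: QIBA-emulating DCE parameter lattice (documented emulation defaults)
DEFAULT_DCE_GRID = {
    "ktrans": [0.01, 0.02, 0.05, 0.1, 0.2, 0.35],   # min^-1
    "ve": [0.01, 0.05, 0.1, 0.2, 0.5],
}
DEFAULT_B_VALUES = [0, 30, 80, 200, 500, 800, 1500, 2000]  # s/mm^2
DEFAULT_DW_GRID = {
    "d": [0.6e-3, 1.0e-3, 1.6e-3],
    "f": [0.05, 0.12, 0.25],
    "dstar": [10e-3, 20e-3],
    "k": [0.5, 0.9, 1.5],
}

_DCE_FORWARD = {
    "tm": tm_conc, "etm": etm_conc, "pm": pm_conc,
    "ctum": ctum_conc, "2cxm": twocxm_conc,
}


@dataclass
class DROSpec:
    """Ground-truth grid, acquisition settings and noise description."""

    kind: str = "dce"
    param_grid: Optional[dict] = None
    patch_size: int = 4
    frames: int = 661
    dt: float = 0.5                       # DCE frame spacing, s
    noise: Optional[dict] = None          # {"model": "gaussian"|"rician", "sigma": x}
    seed: int = 0
    scaling: bool = False                 # DICOM-style 12-bit quantisation
    model: str = "etm"                    # DCE generating model
    aif: Optional[AIFCurve] = None
    b_values: list = field(default_factory=lambda: list(DEFAULT_B_VALUES))
    flip_angles_deg: list = field(default_factory=lambda: [2, 5, 10, 15, 25])
    echo_times: list = field(default_factory=lambda: [0.01, 0.02, 0.04, 0.08,
                                                      0.12, 0.16, 0.24, 0.32])
    tr: float = 0.005                     # s
    fa_deg: float = 25.0                  # DCE flip angle
    t10: float = 1.0                      # tissue pre-contrast T1, s
    blood_t10: float = 1.44               # s
    relaxivity_r1: float = 4.5            # mM^-1 s^-1
    s0: float = 1000.0
    hematocrit: float = 0.45
    include_artery: bool = True
    max_elements: int = 500_000_000       # memory guard on rendered array size

    def grid(self) -> dict:
        if self.param_grid is not None:
            return self.param_grid
        if self.kind == "dce":
            g = dict(DEFAULT_DCE_GRID)
            if self.model in ("etm", "pm"):
                g["vp"] = [0.05]
            if self.model in ("ctum", "2cxm"):
                g = {"fp": [10.0, 30.0, 60.0], "ps": [0.05, 0.15, 0.3],
                     "vp": [0.05]}
                if self.model == "2cxm":
                    g["ve"] = [0.2, 0.4]
            if self.model == "fxr":
                g = {"ktrans": DEFAULT_DCE_GRID["ktrans"][:4],
                     "ve": [0.1, 0.2, 0.4], "tau_i": [0.3]}
            return g
        if self.kind == "dw":
            return dict(DEFAULT_DW_GRID)
        if self.kind == "vfa_t1":
            return {"t10": [0.4, 0.8, 1.2, 1.6, 2.4]}
        if self.kind == "me_t2":
            return {"t2": [0.04, 0.08, 0.12, 0.2]}
        raise ValueError(f"unknown DRO kind '{self.kind}'")


@dataclass
class DROBundle:
    """Rendered synthetic series plus aligned ground-truth maps."""

    series: ImageSeries4D
    truth_maps: dict                    # parameter -> ParametricMap
    spec: DROSpec
    tissue_mask: np.ndarray = None
    artery_mask: np.ndarray = None
    aif: Optional[AIFCurve] = None
    scaling_slope: float = 1.0
    scaling_intercept: float = 0.0

    def truth(self, name: str) -> np.ndarray:
        return self.truth_maps[name].values

    def tissue_curves(self):
        """(n_voxels, n_frames) signal curves of the tissue patches plus the
        flat truth-parameter vectors in the same voxel order."""
        mask = self.tissue_mask
        X, _ = self.series.voxel_curves(mask)
        flat = {k: m.values[mask] for k, m in self.truth_maps.items()}
        return X, flat

    def tissue_concentration(self, baseline_frames: int = 5):
        """Tissue Ct curves recovered from the rendered signal via the SPGR
        baseline-anchored inversion."""
        X, flat = self.tissue_curves()
        ct, _, _ = signal_to_concentration_batch(
            X, 1.0 / self.spec.t10, self.series.meta, baseline_frames)
        return ct, flat


def add_noise(data, model: str = "gaussian", sigma: float = 0.0, seed=None):
    """Add Gaussian or Rician (magnitude) noise; ``seed`` may be an int or a
    numpy Generator. sigma = 0 returns the input unchanged."""
    data = np.asarray(data, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return data.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if model == "gaussian":
        return data + rng.normal(0.0, sigma, size=data.shape)
    if model == "rician":
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        return np.sqrt((data + n1) ** 2 + n2 ** 2)
    raise ValueError("noise model must be 'gaussian' or 'rician'")


def _patch_layout(n_patches: int):
    ncols = int(math.ceil(math.sqrt(n_patches)))
    nrows = int(math.ceil(n_patches / ncols))
    return nrows, ncols


def _combos(grid: dict):
    names = list(grid)
    combos = [dict(zip(names, vals)) for vals in itertools.product(*grid.values())]
    return names, combos


def _assemble(spec: DROSpec, names, combos, curves, extra_rows=None):
    """Tile per-combo curves into a patch image plus truth maps."""
    ps = spec.patch_size
    nrows, ncols = _patch_layout(len(combos))
    ny, nx = nrows * ps, ncols * ps
    n_extra = 0 if extra_rows is None else extra_rows.shape[0]
    n_frames = curves.shape[1]
    if (ny + n_extra) * nx * n_frames > spec.max_elements:
        raise ValueError(
            "DRO grid exceeds the memory guard; reduce patch_size or frames")
    data = np.zeros((nx, ny + n_extra, 1, n_frames))
    truth = {k: np.full((nx, ny + n_extra, 1), np.nan) for k in names}
    tissue = np.zeros((nx, ny + n_extra, 1), dtype=bool)
    for idx, combo in enumerate(combos):
        r, c = divmod(idx, ncols)
        xs, ys = slice(c * ps, (c + 1) * ps), slice(r * ps, (r + 1) * ps)
        data[xs, ys, 0, :] = curves[idx]
        tissue[xs, ys, 0] = True
        for k in names:
            truth[k][xs, ys, 0] = combo[k]
    artery = np.zeros_like(tissue)
    if n_extra:
        for j in range(n_extra):
            data[:, ny + j, 0, :] = extra_rows[j]
        artery[:, ny:, 0] = True
    return data, truth, tissue, artery


def _finalise(spec: DROSpec, data, truth, tissue, artery, meta, aif=None):
    rng = np.random.default_rng(spec.seed)
    slope, intercept = 1.0, 0.0
    if spec.noise:
        data = add_noise(data, spec.noise.get("model", "gaussian"),
                         spec.noise.get("sigma", 0.0), seed=rng)
    if spec.scaling:
        lo, hi = float(data.min()), float(data.max())
        slope = max((hi - lo) / 4095.0, 1e-12)
        intercept = lo
        data = np.round((data - intercept) / slope) * slope + intercept
    series = ImageSeries4D(data=data, affine=np.eye(4), meta=meta)
    maps = {k: ParametricMap(values=v, affine=np.eye(4), parameter_name=k,
                             model_name=spec.model if spec.kind == "dce" else spec.kind,
                             units=_UNITS.get(k, ""))
            for k, v in truth.items()}
    return DROBundle(series=series, truth_maps=maps, spec=spec,
                     tissue_mask=tissue, artery_mask=artery, aif=aif,
                     scaling_slope=slope, scaling_intercept=intercept)


_UNITS = {
    "ktrans": "min^-1", "ve": "fraction", "vp": "fraction", "fp": "mL/min/100mL",
    "ps": "min^-1", "tau_i": "s", "adc": "mm^2/s", "d": "mm^2/s",
    "dstar": "mm^2/s", "f": "fraction", "k": "", "kapp": "", "dapp": "mm^2/s",
    "t10": "s", "t2": "s",
}


def generate_dce_dro(spec: DROSpec) -> DROBundle:
    """Render the DCE perfusion phantom: tissue patches over the parameter
    grid plus an arterial strip carrying the AIF signal."""
    if spec.kind != "dce":
        raise ValueError("spec.kind must be 'dce'")
    times = np.arange(spec.frames) * spec.dt
    aif = spec.aif.resample(times) if spec.aif is not None else population_aif(
        times, hematocrit=spec.hematocrit)
    meta = AcquisitionMeta(tr=spec.tr, flip_angles_deg=[spec.fa_deg],
                           frame_times=list(times), relaxivity_r1=spec.relaxivity_r1)
    r10 = 1.0 / spec.t10
    names, combos = _combos(spec.grid())
    forward = _DCE_FORWARD.get(spec.model)
    curves = np.empty((len(combos), spec.frames))
    for i, combo in enumerate(combos):
        p = PKParams(**combo)
        if spec.model == "fxr":
            r1t = fxr_r1(p, aif, r10, spec.relaxivity_r1)
            curves[i] = spec.s0 * spgr_ratio(r1t, spec.fa_deg, spec.tr)
        else:
            ct = forward(p, aif)
            curves[i] = concentration_to_signal(ct, r10, meta, s0=spec.s0)

    extra = None
    if spec.include_artery:
        cb = aif.cp * (1.0 - spec.hematocrit)     # whole-blood concentration
        r1b = 1.0 / spec.blood_t10 + spec.relaxivity_r1 * cb
        blood = spec.s0 * spgr_ratio(r1b, spec.fa_deg, spec.tr)
        extra = np.tile(blood, (spec.patch_size, 1))
    data, truth, tissue, artery = _assemble(spec, names, combos, curves, extra)
    return _finalise(spec, data, truth, tissue, artery, meta, aif=aif)


def generate_dw_dro(spec: DROSpec) -> DROBundle:
    """Render the multi-b-value diffusion phantom through the NG-IVIM signal
    equation (f=0 and/or K=0 rows reduce to the nested models)."""
    if spec.kind != "dw":
        raise ValueError("spec.kind must be 'dw'")
    b = np.asarray(spec.b_values, dtype=float)
    meta = AcquisitionMeta(b_values=list(b))
    names, combos = _combos(spec.grid())
    curves = np.empty((len(combos), len(b)))
    for i, combo in enumerate(combos):
        curves[i] = ngivim_signal(spec.s0, combo.get("f", 0.0),
                                  combo.get("dstar", 10e-3), combo.get("d", 1e-3),
                                  combo.get("k", 0.0), b)
    data, truth, tissue, artery = _assemble(spec, names, combos, curves)
    return _finalise(spec, data, truth, tissue, artery, meta)


def generate_relaxometry_dro(spec: DROSpec) -> DROBundle:
    """VFA T1 or multi-echo T2 grid phantoms."""
    names, combos = _combos(spec.grid())
    if spec.kind == "vfa_t1":
        fas = np.asarray(spec.flip_angles_deg, dtype=float)
        meta = AcquisitionMeta(tr=spec.tr, flip_angles_deg=list(fas))
        curves = np.vstack([spgr_signal(spec.s0, c["t10"], fas, spec.tr)
                            for c in combos])
    elif spec.kind == "me_t2":
        tes = np.asarray(spec.echo_times, dtype=float)
        meta = AcquisitionMeta(echo_times=list(tes))
        curves = np.vstack([spec.s0 * np.exp(-tes / c["t2"]) for c in combos])
    else:
        raise ValueError("spec.kind must be 'vfa_t1' or 'me_t2'")
    data, truth, tissue, artery = _assemble(spec, names, combos, curves)
    return _finalise(spec, data, truth, tissue, artery, meta)


def generate_dro(spec: DROSpec) -> DROBundle:
    """Dispatch on spec.kind."""
    if spec.kind == "dce":
        return generate_dce_dro(spec)
    if spec.kind == "dw":
        return generate_dw_dro(spec)
    return generate_relaxometry_dro(spec)


def two_model_phantom(frames: int = 661, dt: float = 0.5, patch_size: int = 5,
                      snr: Optional[float] = 50.0, seed: int = 0,
                      vp: float = 0.05, baseline_frames: int = 100):
    """Two-model DCE phantom for the model-selection study.

    One half of the voxels is generated under the Tofts model, the other
    under the extended Tofts model (vp > 0), over the default (Ktrans, ve)
    lattice, rendered to SPGR signal, degraded with Gaussian noise at the
    given baseline SNR (None = noise-free), and converted back to
    concentration. Returns ``(ct, labels, aif)`` with ``labels`` the
    generating model name per voxel.

    The concentration conversion averages (nearly) the whole pre-bolus
    window as its baseline anchor: with a short anchor, baseline noise
    induces a correlated curve-shaped error that the richer model can
    absorb, biasing selection away from the generating model.
    """
    curves, labels = [], []
    aif = None
    for half, model in enumerate(["tm", "etm"]):
        grid = dict(DEFAULT_DCE_GRID)
        if model == "etm":
            grid["vp"] = [vp]
        spec = DROSpec(kind="dce", model=model, param_grid=grid,
                       patch_size=patch_size, frames=frames, dt=dt,
                       seed=seed + half, include_artery=False)
        if snr is not None:
            base = spec.s0 * spgr_ratio(1.0 / spec.t10, spec.fa_deg, spec.tr)
            spec.noise = {"model": "gaussian", "sigma": float(base / snr)}
        bundle = generate_dce_dro(spec)
        aif = bundle.aif
        ct, _ = bundle.tissue_concentration(baseline_frames)
        curves.append(ct)
        labels.extend([model] * ct.shape[0])
    return np.vstack(curves), np.array(labels), aif


def repeatability_coefficient(map_a, map_b) -> float:
    """Test-retest repeatability coefficient RC = 1.96*sqrt(2)*wSD, with the
    within-subject SD from paired replicates: wSD = sqrt(mean(d^2)/2)."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    wsd = np.sqrt(np.mean(d ** 2) / 2.0)
    return float(1.96 * np.sqrt(2.0) * wsd)


def score_maps(fitted: dict, truth: dict, retest: Optional[dict] = None) -> dict:
    """Per-parameter accuracy report: bias, RMSE, and (when a seeded retest
    replicate is given) the repeatability coefficient.

    ``fitted``/``truth``/``retest`` map parameter name -> array (or
    ParametricMap); only parameters present in both fitted and truth are
    scored. NaNs (masked voxels) are ignored pairwise.
    """
    def _values(x):
        return x.values if isinstance(x, ParametricMap) else np.asarray(x, float)

    report = {}
    for name in fitted:
        if name not in truth:
            continue
        fv, tv = _values(fitted[name]).ravel(), _values(truth[name]).ravel()
        ok = np.isfinite(fv) & np.isfinite(tv)
        d = fv[ok] - tv[ok]
        entry = {
            "bias": float(np.mean(d)) if d.size else np.nan,
            "rmse": float(np.sqrt(np.mean(d ** 2))) if d.size else np.nan,
            "n": int(d.size),
        }
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(d) / np.abs(tv[ok])
        rel = rel[np.isfinite(rel)]
        entry["max_rel_err"] = float(rel.max()) if rel.size else np.nan
        entry["median_rel_err"] = float(np.median(rel)) if rel.size else np.nan
        if retest is not None and name in retest:
            entry["rc"] = repeatability_coefficient(fv, _values(retest[name]))
        report[name] = entry
    return report
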