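"""Voxel-wise optimal model mapping (OMM).

Candidate models fitted on identical data points are arbitrated per voxel by
an information criterion (AICc default, BIC, chi-square, R-square) or by an
F-test cascade up the declared nesting lattice. Criteria use the Gaussian-
likelihood forms

    AIC  = n ln(RSS/n) + 2k
    AICc = AIC + 2k(k+1)/(n-k-1)
    BIC  = n ln(RSS/n) + k ln(n)
    R^2  = 1 - RSS/TSS

Numerical choices: residual sums below a floor tied to the data scale
(``rss_floor``) are treated as machine-identical, so that a noise-free voxel
does not hand the win to whichever model's optimizer terminated a few ulps
lower; criterion ties within 1e-9 go to the model with fewest parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "aic", "aicc", "bic", "r2", "chi2", "f_test",
    "NESTING", "OMMResult", "omm_select", "estimate_noise_sigma",
]

#: static nesting lattice: model -> set of models it is nested within
NESTING = {
    "pm": {"etm", "2cxm"},
    "tm": {"etm", "2cxm"},
    "etm": {"2cxm"},
    "ctum": {"2cxm"},
    "mono": {"dki", "ivim", "ngivim"},
    "adc": {"dki", "ivim", "ngivim"},
    "dki": {"ngivim"},
    "ivim": {"ngivim"},
}


def aic(rss, n, k):
    """Akaike information criterion, Gaussian likelihood."""
    rss = np.asarray(rss, dtype=float)
    with np.errstate(divide="ignore"):
        return n * np.log(rss / n) + 2.0 * k


def aicc(rss, n, k):
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return aic(rss, n, k) + 2.0 * k * (k + 1) / (n - k - 1)


def bic(rss, n, k):
    """Bayesian information criterion, Gaussian likelihood."""
    rss = np.asarray(rss, dtype=float)
    with np.errstate(divide="ignore"):
        return n * np.log(rss / n) + k * np.log(n)


def r2(rss, tss):
    """Coefficient of determination."""
    tss = np.asarray(tss, dtype=float)
    if np.any(tss <= 0):
        raise ValueError("r2 requires tss > 0")
    return 1.0 - np.asarray(rss, dtype=float) / tss


def chi2(residuals, sigma):
    """Chi-square statistic sum(r^2)/sigma^2 for a known noise level."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * r) / sigma ** 2)


def estimate_noise_sigma(residuals):
    """Robust noise-sigma estimate: scaled median absolute deviation of the
    residuals (late-frame / high-b residuals of the richest model)."""
    r = np.asarray(residuals, dtype=float).ravel()
    return float(stats.median_abs_deviation(r, scale="normal"))


def f_test(rss_reduced, k_reduced, rss_full, k_full, n, alpha=0.05):
    """Nested-model F-test.

    Returns a dict with the F statistic, its p-value (survival function of
    the F distribution at (k_full-k_reduced, n-k_full) dof) and the decision
    ``prefer_full`` (p < alpha). A full model with RSS above the reduced
    model's is rejected immediately.
    """
    if k_full <= k_reduced:
        raise ValueError("full model must have more parameters than reduced")
    if rss_full > rss_reduced:
        return {"prefer_full": False, "p": 1.0, "F": 0.0}
    d1, d2 = k_full - k_reduced, n - k_full
    if d2 <= 0:
        raise ValueError("n must exceed k_full")
    if rss_full == 0.0:
        return {"prefer_full": rss_reduced > 0, "p": 0.0 if rss_reduced > 0 else 1.0,
                "F": np.inf if rss_reduced > 0 else 0.0}
    F = ((rss_reduced - rss_full) / d1) / (rss_full / d2)
    p = float(stats.f.sf(F, d1, d2))
    return {"prefer_full": p < alpha, "p": p, "F": float(F)}


@dataclass
class OMMResult:
    """Outcome of voxel-wise model arbitration."""

    model_names: list
    model_index: np.ndarray            # winning model per voxel; -1 = masked
    criterion: str
    criterion_values: np.ndarray       # (n_models, n_voxels)
    params: dict = field(default_factory=dict)  # optimal maps; NaN where the
                                                # winning model lacks the param

    @property
    def winning_model(self) -> np.ndarray:
        return np.array([self.model_names[i] if i >= 0 else ""
                         for i in self.model_index])


def _criterion_matrix(names, fitters, criterion, sigma, rss_floor_rel):
    n_vox = len(fitters[names[0]].rss_)
    n = fitters[names[0]].n_points_
    vals = np.empty((len(names), n_vox))
    # scale-tied floor: residual RMS below rss_floor_rel of the signal RMS is
    # considered machine-identical
    tss = np.nanmax(np.vstack([fitters[m].tss_ for m in names]), axis=0)
    floor = rss_floor_rel ** 2 * np.maximum(tss, 1e-300)
    for j, m in enumerate(names):
        f = fitters[m]
        rss_eff = np.maximum(f.rss_, floor)
        k = f.k_params
        if criterion == "aicc":
            vals[j] = aicc(rss_eff, n, k)
        elif criterion == "bic":
            vals[j] = bic(rss_eff, n, k)
        elif criterion == "chi2":
            vals[j] = rss_eff / sigma ** 2
        elif criterion == "r2":
            vals[j] = -(1.0 - rss_eff / np.maximum(tss, 1e-300))  # negated: min wins
        else:
            raise ValueError(f"unknown criterion '{criterion}'")
    return vals


def _ftest_select(names, fitters, alpha):
    """Cascade up the nesting lattice from the most parsimonious model."""
    order = sorted(names, key=lambda m: fitters[m].k_params)
    n = fitters[order[0]].n_points_
    n_vox = len(fitters[order[0]].rss_)
    idx = np.full(n_vox, names.index(order[0]))
    for i in range(n_vox):
        current = order[0]
        for cand in order[1:]:
            if cand not in NESTING.get(current, set()):
                continue
            res = f_test(fitters[current].rss_[i], fitters[current].k_params,
                         min(fitters[cand].rss_[i], fitters[current].rss_[i]),
                         fitters[cand].k_params, n, alpha=alpha)
            if res["prefer_full"]:
                current = cand
        idx[i] = names.index(current)
    return idx


def omm_select(candidates: dict, criterion: str = "aicc", alpha: float = 0.05,
               sigma: Optional[float] = None, rss_floor_rel: float = 1e-6,
               tie_tol: float = 1e-9) -> OMMResult:
    """Pick the best model per voxel.

    Parameters
    ----------
    candidates : dict
        model name -> fitted :class:`~qmrifit._base.VoxelwiseFitter` (all on
        identical data points).
    criterion : str
        ``aicc`` (default), ``bic``, ``chi2``, ``r2`` or ``ftest``.
    sigma : float, optional
        Noise sigma for chi2; estimated robustly from the richest model's
        residual spread if omitted (requires equal fits; pass explicitly for
        control).
    """
    names = list(candidates)
    if len(names) < 1:
        raise ValueError("need at least one candidate model")
    fitters = candidates
    n_pts = {fitters[m].n_points_ for m in names}
    if len(n_pts) != 1:
        raise ValueError("candidates were fitted on differing numbers of points")
    n = n_pts.pop()
    n_vox = len(fitters[names[0]].rss_)

    if criterion == "ftest":
        if len(names) < 2:
            idx = np.zeros(n_vox, dtype=int)
        else:
            idx = _ftest_select(names, fitters, alpha)
        crit_vals = np.vstack([aic(np.maximum(fitters[m].rss_, 1e-300), n,
                                   fitters[m].k_params) for m in names])
    else:
        if criterion == "chi2" and sigma is None:
            richest = max(names, key=lambda m: fitters[m].k_params)
            sigma = max(np.sqrt(np.nanmedian(fitters[richest].rss_) / n), 1e-300)
        crit_vals = _criterion_matrix(names, fitters, criterion, sigma, rss_floor_rel)
        safe = np.where(np.isfinite(crit_vals), crit_vals, np.inf)
        best = np.min(safe, axis=0)
        k_arr = np.array([fitters[m].k_params for m in names])
        # tie within tolerance -> fewest parameters wins
        idx = np.empty(n_vox, dtype=int)
        for i in range(n_vox):
            tied = np.flatnonzero(safe[:, i] <= best[i] + tie_tol)
            idx[i] = tied[np.argmin(k_arr[tied])]

    # mask voxels where every candidate failed to converge
    all_bad = np.ones(n_vox, dtype=bool)
    for m in names:
        all_bad &= ~fitters[m].converged_
    idx = np.where(all_bad, -1, idx)

    all_params = sorted({p for m in names for p in fitters[m].param_names})
    params = {}
    for pname in all_params:
        out = np.full(n_vox, np.nan)
        for j, m in enumerate(names):
            if pname in fitters[m].param_names:
                sel = idx == j
                out[sel] = fitters[m].params_[pname][sel]
        params[pname] = out
    return OMMResult(model_names=names, model_index=idx, criterion=criterion,
                     criterion_values=crit_vals, params=params)
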