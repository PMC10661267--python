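"""Shared voxel-wise fitting machinery.

Every mapping routine in this package is an sklearn-style estimator: hyper-
parameters (acquisition grid, bounds, solver options) are constructor
arguments, ``fit(X)`` consumes an ``(n_voxels, n_frames)`` array of signal or
concentration curves, and the per-voxel estimates land in trailing-underscore
attributes (``params_["ktrans"]``, ``rss_``, ``aicc_``, ...). Voxels are
independent, so any execution order yields identical results.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from scipy.optimize import least_squares

from .types import FitResult

__all__ = ["VoxelwiseFitter", "bounded_least_squares"]


def bounded_least_squares(residual_fn, x0, bounds, max_nfev=200, **kwargs):
    """Thin wrapper around scipy trust-region-reflective least squares that
    clips the start point into the open interior of the bounds."""
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    x0 = np.asarray(x0, float)
    span = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
    x0 = np.clip(x0, lo + 1e-12 * np.maximum(span, 1e-6), hi - 1e-12 * np.maximum(span, 1e-6))
    return least_squares(residual_fn, x0, bounds=(lo, hi), method="trf",
                         max_nfev=max_nfev, **kwargs)


class VoxelwiseFitter(BaseEstimator):
    """Base class for voxel-wise curve fitters.

    Subclasses define ``param_names`` plus ``_fit_voxel(y)`` returning
    ``(theta, yhat, converged, n_iter)`` and may override ``_validate_X``.
    """

    #: ordered fitted-parameter names; set by subclasses
    param_names: tuple = ()

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be (n_voxels, n_frames)")
        return X

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    def _fit_voxel(self, y: np.ndarray):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        """Fit every row of X; populates per-voxel result arrays."""
        X = self._validate_X(X)
        n_vox, n_pts = X.shape
        k = self.k_params
        theta = np.full((n_vox, k), np.nan)
        rss = np.full(n_vox, np.nan)
        tss = np.full(n_vox, np.nan)
        conv = np.zeros(n_vox, dtype=bool)
        nit = np.zeros(n_vox, dtype=int)
        for i in range(n_vox):
            y_i = X[i]
            th, yhat, ok, it = self._fit_voxel(y_i)
            theta[i] = th
            resid = y_i - yhat
            rss[i] = float(resid @ resid)
            tss[i] = float(np.sum((y_i - y_i.mean()) ** 2))
            conv[i] = ok
            nit[i] = it
        self.n_points_ = n_pts
        self.params_ = {name: theta[:, j] for j, name in enumerate(self.param_names)}
        self.theta_ = theta
        self.rss_ = rss
        self.tss_ = tss
        self.converged_ = conv
        self.n_iter_ = nit
        self._fill_criteria()
        return self

    def _fill_criteria(self):
        from .selection import aic, aicc, bic

        n, k = self.n_points_, self.k_params
        with np.errstate(divide="ignore", invalid="ignore"):
            self.r2_ = np.where(self.tss_ > 0, 1.0 - self.rss_ / self.tss_, np.nan)
        self.aic_ = aic(self.rss_, n, k)
        self.bic_ = bic(self.rss_, n, k)
        self.aicc_ = aicc(self.rss_, n, k) if n > k + 1 else np.full_like(self.rss_, np.nan)

    def predict(self, X=None) -> np.ndarray:
        """Model-predicted curves for the fitted voxels."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "theta_")
        return np.vstack([self._forward(self.theta_[i]) for i in range(len(self.theta_))])

    def _forward(self, theta: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit_voxel(self, y: np.ndarray, tss: Optional[float] = None) -> FitResult:
        """Fit a single curve and return a :class:`~qmrifit.types.FitResult`."""
        y = np.asarray(y, dtype=float)
        self.fit(y[np.newaxis, :])
        res = FitResult(
            params={name: float(self.params_[name][0]) for name in self.param_names},
            rss=float(self.rss_[0]),
            n_points=self.n_points_,
            k_params=self.k_params,
            r2=float(self.r2_[0]),
            aic=float(self.aic_[0]),
            aicc=float(self.aicc_[0]),
            bic=float(self.bic_[0]),
            converged=bool(self.converged_[0]),
            n_iter=int(self.n_iter_[0]),
        )
        return res
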