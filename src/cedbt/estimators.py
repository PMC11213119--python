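"""Estimator-style front ends for the reconstruction chain.

Each stage is exposed as a scikit-learn-compatible estimator
(``get_params``/``set_params``, ``fit`` producing trailing-underscore
attributes) so stages can be configured, cloned and composed
programmatically; the module-level functions in :mod:`cedbt.dtv`,
:mod:`cedbt.fbp`, :mod:`cedbt.postprocess` and :mod:`cedbt.dual_energy`
remain the thin functional interface over the same code.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import ScanGeometry, VolumeGrid
from .filtering import RampFilterSpec
from .dtv import ReconParams, solve_dtv
from .fbp import fbp
from .postprocess import IRLSControls, process_volume
from .dual_energy import select_weight, weighted_subtraction

__all__ = [
    "DirectionalTVReconstructor",
    "FBPReconstructor",
    "BackgroundNormalizer",
    "DualEnergySubtractor",
]


class DirectionalTVReconstructor(BaseEstimator):
    """Directional-TV reconstruction of one projection stack.

    Parameters mirror :class:`cedbt.dtv.ReconParams`; ``fit`` solves the
    constrained problem and stores the result in ``volume_`` with solver
    diagnostics in ``diagnostics_``.
    """

    def __init__(
        self,
        geometry: ScanGeometry | None = None,
        grid: VolumeGrid | None = None,
        alpha: float = 1.75,
        beta: float = 0.1,
        epsilon_rmse: float = 0.01,
        n_iterations: int = 500,
        step_ratio: float = 1.0,
        seed: int = 0,
        filter_spec: RampFilterSpec | None = None,
    ):
        self.geometry = geometry
        self.grid = grid
        self.alpha = alpha
        self.beta = beta
        self.epsilon_rmse = epsilon_rmse
        self.n_iterations = n_iterations
        self.step_ratio = step_ratio
        self.seed = seed
        self.filter_spec = filter_spec

    def _params(self) -> ReconParams:
        return ReconParams(
            alpha=self.alpha,
            beta=self.beta,
            epsilon_rmse=self.epsilon_rmse,
            n_iterations=self.n_iterations,
            step_ratio=self.step_ratio,
            seed=self.seed,
        )

    def fit(self, X: np.ndarray, y=None) -> "DirectionalTVReconstructor":
        if self.geometry is None or self.grid is None:
            raise ValueError("geometry and grid must be set before fitting")
        self.volume_, self.diagnostics_ = solve_dtv(
            X, self.geometry, self.grid, self._params(), self.filter_spec
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Reconstruct a (possibly new) projection stack."""
        vol, _ = solve_dtv(X, self.geometry, self.grid, self._params(), self.filter_spec)
        return vol

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).volume_


class FBPReconstructor(BaseEstimator):
    """Filtered back-projection reference reconstruction."""

    def __init__(
        self,
        geometry: ScanGeometry | None = None,
        grid: VolumeGrid | None = None,
        filter_spec: RampFilterSpec | None = None,
    ):
        self.geometry = geometry
        self.grid = grid
        self.filter_spec = filter_spec

    def fit(self, X: np.ndarray, y=None) -> "FBPReconstructor":
        if self.geometry is None or self.grid is None:
            raise ValueError("geometry and grid must be set before fitting")
        self.volume_ = fbp(X, self.geometry, self.grid, self.filter_spec)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return fbp(X, self.geometry, self.grid, self.filter_spec)

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).volume_


class BackgroundNormalizer(BaseEstimator, TransformerMixin):
    """Slice-wise robust polynomial background removal.

    ``fit_transform`` returns the normalized volume fd and stores the
    fitted background ``background_`` and support mask ``mask_``.
    """

    def __init__(
        self,
        degree: int = 8,
        mask_method: str = "fraction_of_median",
        mask_param: float = 0.2,
        irls_max_iter: int = 50,
        irls_tol: float = 1e-8,
        background_floor: float = 0.05,
    ):
        self.degree = degree
        self.mask_method = mask_method
        self.mask_param = mask_param
        self.irls_max_iter = irls_max_iter
        self.irls_tol = irls_tol
        self.background_floor = background_floor

    def _run(self, X):
        return process_volume(
            X,
            degree=self.degree,
            mask_method=self.mask_method,
            mask_param=self.mask_param,
            irls=IRLSControls(max_iter=self.irls_max_iter, tol=self.irls_tol),
            background_floor=self.background_floor,
        )

    def fit(self, X: np.ndarray, y=None) -> "BackgroundNormalizer":
        self.normalized_, self.background_, self.mask_ = self._run(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        fd, _, _ = self._run(X)
        return fd

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).normalized_


class DualEnergySubtractor(BaseEstimator):
    """Weighted high/low-energy subtraction with optional weight sweep.

    ``fit`` receives ``X = (fd_HE, fd_LE)``; when ``sweep`` and a
    background mask are given the weight is chosen by background-variance
    minimization, otherwise the configured ``w`` is used.  The selected
    weight lands in ``weight_`` and the iodine image in ``iodine_``.
    """

    def __init__(
        self,
        w: float = 0.5,
        sweep: tuple[float, ...] | None = None,
        background_mask: np.ndarray | None = None,
        allow_unnormalized: bool = False,
    ):
        self.w = w
        self.sweep = sweep
        self.background_mask = background_mask
        self.allow_unnormalized = allow_unnormalized

    def fit(self, X, y=None) -> "DualEnergySubtractor":
        fd_he, fd_le = X
        if self.sweep is not None and self.background_mask is not None:
            self.weight_, self.score_curve_ = select_weight(
                fd_he,
                fd_le,
                np.asarray(self.sweep, dtype=float),
                self.background_mask,
                allow_unnormalized=self.allow_unnormalized,
            )
        else:
            self.weight_ = float(self.w)
            self.score_curve_ = None
        self.iodine_ = weighted_subtraction(
            fd_he, fd_le, self.weight_, allow_unnormalized=self.allow_unnormalized
        )
        return self

    def transform(self, X) -> np.ndarray:
        fd_he, fd_le = X
        w = getattr(self, "weight_", self.w)
        return weighted_subtraction(fd_he, fd_le, w, allow_unnormalized=self.allow_unnormalized)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).iodine_
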