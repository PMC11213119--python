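"""Slice-wise removal of low-frequency limited-angle artifacts.

Reconstructions from a partial arc carry smooth shading that differs
between the two beam energies, so raw volumes cannot simply be
subtracted.  Per in-plane (x-y) slice this module

1. estimates the object support by thresholding,
2. fits a low-order 2D polynomial background b = P c to the masked slice
   by minimizing the l1 residual ||m . (s - P c)||_1 with iteratively
   reweighted least squares (IRLS) — the l1 norm makes the fit robust, so
   small high-contrast structures are preserved rather than absorbed
   into the background, and
3. normalizes: fd = m . s / b, which centres artifact-free tissue on 1.

The slice results are stacked into a background volume fb, a mask volume
fm, and the displayed volume fd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PolyBasis",
    "IRLSControls",
    "build_poly_basis",
    "estimate_support_mask",
    "robust_polyfit_slice",
    "normalize_volume",
    "process_volume",
]


@dataclass(frozen=True)
class PolyBasis:
    """2D monomial basis x^i y^j (i + j <= degree) on [-1, 1]^2 coordinates.

    ``matrix`` has shape (n_pixels, n_terms) with pixels in C order of the
    slice; ``exponents`` lists the (i, j) pair of each column.
    """

    degree: int
    slice_shape: tuple[int, int]
    matrix: np.ndarray
    exponents: tuple[tuple[int, int], ...]

    @property
    def n_terms(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class IRLSControls:
    """IRLS settings: weights w_i = 1 / max(|r_i|, delta) with
    delta = delta_scale * median(|s| on mask); stop after ``max_iter``
    reweightings or when the relative coefficient change drops below
    ``tol``."""

    max_iter: int = 50
    tol: float = 1e-8
    delta_scale: float = 1e-6


def n_poly_terms(degree: int) -> int:
    """Number of 2D monomials of total degree <= degree."""
    return (degree + 1) * (degree + 2) // 2


def build_poly_basis(slice_shape: tuple[int, int], degree: int) -> PolyBasis:
    """All monomials x^i y^j with i + j <= degree on normalized coordinates.

    A singleton slice axis (quasi-2D volumes) drops the corresponding
    exponent, reducing to a 1D polynomial basis along the other axis.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    n0, n1 = slice_shape
    x = np.linspace(-1.0, 1.0, n0) if n0 > 1 else np.zeros(1)
    y = np.linspace(-1.0, 1.0, n1) if n1 > 1 else np.zeros(1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    cols = []
    exps = []
    for total in range(degree + 1):
        for i in range(total + 1):
            j = total - i
            if (n0 == 1 and i > 0) or (n1 == 1 and j > 0):
                continue
            cols.append((xx**i * yy**j).ravel())
            exps.append((i, j))
    return PolyBasis(degree, tuple(slice_shape), np.stack(cols, axis=1), tuple(exps))


def estimate_support_mask(
    s: np.ndarray,
    method: str = "fraction_of_median",
    threshold_param: float = 0.2,
) -> np.ndarray:
    """Binary object-support mask of an image slice.

    Thresholds the slice (``fraction_of_median`` and ``fraction_of_mean``
    use threshold_param times the median of positive values or the mean;
    ``otsu`` ignores threshold_param), keeps the largest connected
    component and fills holes.  Deterministic.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("slice contains non-finite values")
    if method == "fraction_of_median":
        pos = s[s > 0]
        if pos.size == 0:
            warnings.warn("slice has no positive values; returning empty mask")
            return np.zeros_like(s, dtype=bool)
        thresh = threshold_param * np.median(pos)
    elif method == "fraction_of_mean":
        thresh = threshold_param * s.mean()
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(s) == 0:
            return np.ones_like(s, dtype=bool) if s.flat[0] > 0 else np.zeros_like(s, dtype=bool)
        thresh = threshold_otsu(s)
    else:
        raise ValueError(f"unknown mask method {method!r}")

    mask = s > thresh
    if not mask.any():
        # uniform positive slice: threshold equals the constant value
        if np.ptp(s) == 0 and s.flat[0] > 0 and method != "fraction_of_median":
            return np.ones_like(s, dtype=bool)
        if (s >= thresh).all() and thresh > 0:
            return np.ones_like(s, dtype=bool)
        warnings.warn("support threshold left an empty mask")
        return mask
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def robust_polyfit_slice(
    s: np.ndarray,
    m: np.ndarray,
    basis: PolyBasis,
    irls: IRLSControls | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """l1 polynomial fit of a masked slice via IRLS.

    Returns (coefficients c, background b) where c approximately solves
    argmin_c ||m . (s - P c)||_1 and b = P c evaluated on the full slice.
    """
    irls = irls or IRLSControls()
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=bool)
    if s.shape != basis.slice_shape or m.shape != basis.slice_shape:
        raise ValueError("slice/mask shape does not match basis")
    idx = m.ravel()
    n_mask = int(idx.sum())
    if n_mask < basis.n_terms:
        raise ValueError(
            f"mask covers {n_mask} pixels; need at least {basis.n_terms} for degree {basis.degree}"
        )
    P = basis.matrix[idx]
    target = s.ravel()[idx]

    # column scaling for conditioning of the high-degree Vandermonde system
    col_scale = np.linalg.norm(P, axis=0)
    col_scale[col_scale == 0] = 1.0
    Ps = P / col_scale

    delta = irls.delta_scale * max(np.median(np.abs(target)), np.finfo(float).tiny)
    sqw = np.ones(n_mask)
    c_scaled = np.zeros(basis.n_terms)
    for _ in range(irls.max_iter):
        A = Ps * sqw[:, None]
        rhs = target * sqw
        sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
        if rank < basis.n_terms:
            raise np.linalg.LinAlgError(
                f"masked design is rank-deficient (rank {rank} < {basis.n_terms} terms)"
            )
        change = np.linalg.norm(sol - c_scaled) / max(np.linalg.norm(sol), 1e-300)
        c_scaled = sol
        if change < irls.tol:
            break
        r = target - Ps @ c_scaled
        sqw = 1.0 / np.sqrt(np.maximum(np.abs(r), delta))
    c = c_scaled / col_scale
    b = (basis.matrix @ c).reshape(basis.slice_shape)
    return c, b


def normalize_volume(f: np.ndarray, fb: np.ndarray, fm: np.ndarray) -> np.ndarray:
    """Displayed volume fd = fm . (f / fb); zero off the mask."""
    f = np.asarray(f, dtype=float)
    fb = np.asarray(fb, dtype=float)
    fm = np.asarray(fm, dtype=bool)
    if f.shape != fb.shape or f.shape != fm.shape:
        raise ValueError("volume, background and mask shapes must match")
    if np.any(fb[fm] <= 0):
        raise ValueError("background must be positive on the mask (apply the floor upstream)")
    fd = np.zeros_like(f)
    fd[fm] = f[fm] / fb[fm]
    return fd


def process_volume(
    f: np.ndarray,
    degree: int = 8,
    mask_method: str = "fraction_of_median",
    mask_param: float = 0.2,
    irls: IRLSControls | None = None,
    background_floor: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mask, fit and normalize every in-plane slice of a volume.

    The fitted background of each slice is floored at ``background_floor``
    times its on-mask median before division, so the normalization is
    well-defined near the support edge.  Returns (fd, fb, fm).
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 3 or f.size == 0:
        raise ValueError("expected a nonempty (nx, ny, nz) volume")
    basis = build_poly_basis(f.shape[:2], degree)
    fd = np.zeros_like(f)
    fb = np.zeros_like(f)
    fm = np.zeros(f.shape, dtype=bool)
    for iz in range(f.shape[2]):
        s = f[:, :, iz]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = estimate_support_mask(s, mask_method, mask_param)
        if int(m.sum()) < basis.n_terms:
            continue  # slice outside the object: fd stays zero
        _, b = robust_polyfit_slice(s, m, basis, irls)
        floor = background_floor * np.median(b[m]) if np.median(b[m]) > 0 else np.finfo(float).tiny
        b = np.maximum(b, floor)
        fb[:, :, iz] = b
        fm[:, :, iz] = m
        fd[:, :, iz][m] = s[m] / b[m]
    return fd, fb, fm
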