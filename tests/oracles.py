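"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: dense matrices are
built column-by-column from unit vectors, the constrained-TV reference
solution comes from an ADMM splitting with direct linear solves (a
different algorithm family from the package's primal-dual solver), and
the robust l1 polynomial fit is cross-checked against a linear program.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla
from scipy.optimize import linprog


def dense_operator(apply_fn, in_shape, out_size):
    """Materialize a linear operator column by column."""
    n = int(np.prod(in_shape))
    M = np.zeros((out_size, n))
    e = np.zeros(n)
    for k in range(n):
        e[k] = 1.0
        M[:, k] = np.asarray(apply_fn(e.reshape(in_shape))).ravel()
        e[k] = 0.0
    return M


def admm_constrained_tv(
    Ds: list[np.ndarray],
    RX: np.ndarray,
    rg: np.ndarray,
    weights,
    beta: float,
    eps: float,
    rho: float = 10.0,
    n_iterations: int = 8000,
) -> np.ndarray:
    """Reference solution of the weighted-gradient-l1 + l1 problem.

    Solves min sum_i w_i ||D_i f||_1 + beta ||f||_1 subject to
    ||RX f - rg|| <= eps and f >= 0 by ADMM over the stacked splitting
    z = [f; D_1 f; ...; RX f], with a cached Cholesky factorization for
    the f-update.  Returns the primal iterate (clipped non-negative).
    """
    n = Ds[0].shape[1]
    m = rg.size
    A = np.vstack([np.eye(n)] + Ds + [RX])
    cho = sla.cho_factor(A.T @ A)
    slices = [slice(0, n)]
    start = n
    for D in Ds:
        slices.append(slice(start, start + D.shape[0]))
        start += D.shape[0]
    sl_data = slice(start, start + m)

    z = np.zeros(A.shape[0])
    u = np.zeros_like(z)
    for _ in range(n_iterations):
        f = sla.cho_solve(cho, A.T @ (z - u))
        Af = A @ f
        v = Af + u
        parts = [np.maximum(0.0, v[slices[0]] - beta / rho)]
        for w, sl in zip(weights, slices[1:]):
            seg = v[sl]
            parts.append(np.sign(seg) * np.maximum(np.abs(seg) - w / rho, 0.0))
        d = v[sl_data] - rg
        nd = np.linalg.norm(d)
        parts.append(rg + (d * min(1.0, eps / nd) if nd > 0 else d))
        z = np.concatenate(parts)
        u = u + Af - z
    return np.maximum(z[slices[0]], 0.0)


def l1_polyfit_lp(P: np.ndarray, target: np.ndarray):
    """Exact l1 polynomial fit min_c ||target - P c||_1 via linear programming.

    Returns (coefficients, optimal objective).  Variables are c (free)
    and per-pixel slack t with -t <= target - P c <= t.
    """
    npix, nterms = P.shape
    # variables: [c, t]
    c_obj = np.concatenate([np.zeros(nterms), np.ones(npix)])
    A_ub = np.block([[P, -np.eye(npix)], [-P, -np.eye(npix)]])
    b_ub = np.concatenate([target, -target])
    bounds = [(None, None)] * nterms + [(0, None)] * npix
    res = linprog(c_obj, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP oracle failed: {res.message}")
    return res.x[:nterms], res.fun
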