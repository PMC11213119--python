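"""Forward finite differences along the volume axes and their adjoints.

The directional-TV objective penalizes the l1 norms of these differences
with per-axis weights.  The scheme is a forward difference with a Neumann
(zero-difference) boundary on the last plane; its exact adjoint is the
negative backward difference, which is what the solver applies.
"""

from __future__ import annotations

import numpy as np

__all__ = ["directional_diff", "directional_diff_adjoint", "AXES"]

AXES = {"x": 0, "y": 1, "z": 2}


def _axis_index(axis: str | int) -> int:
    if isinstance(axis, str):
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(AXES)}")
        return AXES[axis]
    if axis not in (0, 1, 2):
        raise ValueError(f"unknown axis index {axis}; expected 0, 1 or 2")
    return axis


def directional_diff(f: np.ndarray, axis: str | int) -> np.ndarray:
    """Forward difference along ``axis`` with a zero last plane."""
    ax = _axis_index(axis)
    d = np.zeros_like(f, dtype=float)
    sl_lo = [slice(None)] * f.ndim
    sl_hi = [slice(None)] * f.ndim
    sl_lo[ax] = slice(0, -1)
    sl_hi[ax] = slice(1, None)
    d[tuple(sl_lo)] = f[tuple(sl_hi)] - f[tuple(sl_lo)]
    return d


def directional_diff_adjoint(d: np.ndarray, axis: str | int) -> np.ndarray:
    """Exact transpose of :func:`directional_diff` (negative backward difference)."""
    ax = _axis_index(axis)
    out = np.zeros_like(d, dtype=float)
    sl_lo = [slice(None)] * d.ndim
    sl_hi = [slice(None)] * d.ndim
    sl_lo[ax] = slice(0, -1)
    sl_hi[ax] = slice(1, None)
    out[tuple(sl_lo)] -= d[tuple(sl_lo)]
    out[tuple(sl_hi)] += d[tuple(sl_lo)]
    return out
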