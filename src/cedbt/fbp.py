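"""Filtered back-projection reference reconstruction.

A deliberately plain baseline for comparison with the directional-TV
solver: ramp-filter each projection along the source-travel axis, apply
the matched back-projector, and scale by pi / n_views.  No depth-dependent
weighting is applied, so the reconstruction shows the depth elongation
characteristic of limited-angle tomosynthesis.
"""

from __future__ import annotations

import numpy as np

from .geometry import ScanGeometry, VolumeGrid
from .filtering import RampFilterSpec, filter_pitch_cm, ramp_filter
from .projector import back_project

__all__ = ["fbp"]


def fbp(
    g: np.ndarray,
    geom: ScanGeometry,
    grid: VolumeGrid,
    filter_spec: RampFilterSpec | None = None,
) -> np.ndarray:
    """Reconstruct (pi / n_views) * X^T (R g); linear in g."""
    g = np.asarray(g, dtype=float)
    spec = filter_spec or RampFilterSpec()
    filtered = ramp_filter(g, spec, filter_pitch_cm(geom))
    vol = back_project(filtered, geom, grid)
    return (np.pi / geom.n_views) * vol
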