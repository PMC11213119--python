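"""Resolution and accuracy metrics for reconstructed volumes.

The headline question for limited-angle reconstruction is depth blur:
how elongated an object is along z (the detector normal) compared with
its in-plane extent.  ``profile_fwhm`` quantifies this as the full width
at half maximum of a 1D profile through an object; ``resolution_report``
applies it per contrast insert and adds contrast and (when truth is
available) RMSE.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import VolumeGrid
from .gradients import AXES

__all__ = ["FWHMUndefinedError", "profile_fwhm", "resolution_report"]


class FWHMUndefinedError(RuntimeError):
    """The profile has no half-maximum crossing inside the volume."""


def _crossing(profile: np.ndarray, half: float, peak_idx: int, direction: int) -> float:
    """Fractional index where the profile falls through ``half``."""
    i = peak_idx
    n = profile.size
    while 0 <= i + direction < n:
        j = i + direction
        if profile[j] < half:
            # linear interpolation between samples i and j
            frac = (profile[i] - half) / (profile[i] - profile[j])
            return i + direction * frac
        i = j
    raise FWHMUndefinedError("profile does not fall below half maximum inside the volume")


def profile_fwhm(
    volume: np.ndarray,
    grid: VolumeGrid,
    center_mm: tuple[float, float, float],
    axis: str | int,
) -> float:
    """FWHM (mm) of the 1D profile through ``center_mm`` along ``axis``.

    The profile is the line of voxels nearest the centre; the peak is the
    profile maximum nearest the requested centre and half-maximum
    crossings are located by linear interpolation between samples.
    """
    ax = AXES[axis] if isinstance(axis, str) else axis
    volume = np.asarray(volume, dtype=float)
    idx = [
        int(round((center_mm[a] - grid.origin[a]) / grid.voxel_size))
        for a in range(3)
    ]
    for a in range(3):
        idx[a] = min(max(idx[a], 0), grid.shape[a] - 1)
    sl = [idx[0], idx[1], idx[2]]
    sl[ax] = slice(None)
    profile = volume[tuple(sl)]
    if profile.max() <= 0:
        raise FWHMUndefinedError("profile has no positive peak")
    # local peak: climb from the nominal centre to the nearest maximum
    peak = idx[ax]
    while True:
        left = profile[peak - 1] if peak > 0 else -np.inf
        right = profile[peak + 1] if peak < profile.size - 1 else -np.inf
        if left <= profile[peak] >= right:
            break
        peak = peak - 1 if left > right else peak + 1
    if profile[peak] <= 0:
        raise FWHMUndefinedError("profile has no positive peak at the requested centre")
    half = profile[peak] / 2.0
    lo = _crossing(profile, half, peak, -1)
    hi = _crossing(profile, half, peak, +1)
    return float((hi - lo) * grid.voxel_size)


def resolution_report(
    volume: np.ndarray,
    grid: VolumeGrid,
    inserts: list,
    truth_volume: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
) -> list[dict]:
    """Per-insert FWHM along x/y/z plus contrast against local background.

    ``inserts`` is the phantom truth metadata (dicts with ``center_mm``,
    ``diameter_mm``, ``concentration_mgml``).  FWHM entries are NaN when
    undefined (no detectable peak).
    """
    volume = np.asarray(volume, dtype=float)
    if background_mask is not None and background_mask.any():
        bg = float(np.median(volume[background_mask]))
        bg_sd = float(volume[background_mask].std())
    else:
        bg, bg_sd = 0.0, float("nan")
    report = []
    for ins in inserts:
        cx, cy, cz = ins["center_mm"]
        entry = {
            "center_mm": [cx, cy, cz],
            "diameter_mm": ins["diameter_mm"],
            "concentration_mgml": ins.get("concentration_mgml"),
        }
        idx = tuple(
            min(max(int(round((c - grid.origin[a]) / grid.voxel_size)), 0), grid.shape[a] - 1)
            for a, c in enumerate((cx, cy, cz))
        )
        entry["peak_value"] = float(volume[idx])
        entry["contrast"] = float(volume[idx] - bg)
        entry["background_sd"] = bg_sd
        for axname in ("x", "y", "z"):
            try:
                entry[f"fwhm_{axname}_mm"] = profile_fwhm(volume, grid, (cx, cy, cz), axname)
            except FWHMUndefinedError:
                entry[f"fwhm_{axname}_mm"] = float("nan")
        report.append(entry)
    if truth_volume is not None:
        err = volume - truth_volume
        rmse = float(np.sqrt(np.mean(err**2)))
        for entry in report:
            entry["rmse_vs_truth"] = rmse
    return report
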