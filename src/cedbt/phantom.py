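"""Synthetic dual-energy breast phantom and scan simulator.

Emulates a structured breast phantom: a 4 cm slab of heterogeneous
adipose/glandular tissue at 50% glandularity (a seeded Gaussian-filtered
blob field thresholded to the target fraction) with solid iodinated
contrast-agent (ICA) inserts of 2/3/5/8 mm diameter at 1/2/3/5 mg/mL,
arranged on a diameter-by-concentration grid at mid-depth.

Each beam setting (LE: 30 kV + Al filtration, HE: 49 kV + Ti filtration)
is modelled by a single effective attenuation coefficient per material —
no spectral integration, scatter or detector blur.  The default
coefficients are editable simulator inputs chosen so tissue contrast is
small and the iodine HE coefficient is about twice its LE value,
reproducing the K-edge behaviour that makes inserts conspicuous at high
energy only.

Scan simulation follows the physical preprocessing: line integrals ->
expected counts fluence * exp(-l) -> Poisson draw -> flood-field division
-> negative logarithm.  Infinite fluence (None) returns exact line
integrals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry, VolumeGrid
from .projector import forward_project

__all__ = [
    "PhantomSpec",
    "SpectralModel",
    "NoiseModel",
    "PhantomTruth",
    "make_phantom",
    "simulate_de_scan",
    "analytic_cancellation_weight",
    "ideal_normalized_volume",
]


@dataclass(frozen=True)
class SpectralModel:
    """Effective attenuation (1/mm) per material at the two beam settings.

    ``iodine_*`` values are per mg/mL of iodine concentration.
    """

    adipose_le: float = 0.050
    glandular_le: float = 0.062
    iodine_le: float = 0.0025
    adipose_he: float = 0.030
    glandular_he: float = 0.036
    iodine_he: float = 0.0050

    def __post_init__(self):
        for name in ("adipose_le", "glandular_le", "adipose_he", "glandular_he"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.iodine_he > self.iodine_le:
            raise ValueError("iodine HE coefficient must exceed its LE value (K-edge ordering)")


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and composition of the synthetic phantom.

    texture_scale_mm sets the correlation length of the glandular blob
    field; insert_shape is "sphere" or "cylinder" (cylinder axis along z,
    height equal to the diameter).
    """

    slab_thickness: float = 40.0
    insert_diameters: tuple[float, ...] = (2.0, 3.0, 5.0, 8.0)
    iodine_concentrations: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0)
    glandular_fraction: float = 0.5
    texture_scale_mm: float = 5.0
    insert_shape: str = "sphere"
    seed: int = 0

    def __post_init__(self):
        if self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be > 0")
        if any(d <= 0 for d in self.insert_diameters):
            raise ValueError("insert diameters must be > 0")
        if any(c < 0 for c in self.iodine_concentrations):
            raise ValueError("iodine concentrations must be >= 0")
        if not 0.0 <= self.glandular_fraction <= 1.0:
            raise ValueError("glandular_fraction must lie in [0, 1]")
        if self.insert_shape not in ("sphere", "cylinder"):
            raise ValueError("insert_shape must be 'sphere' or 'cylinder'")


@dataclass(frozen=True)
class NoiseModel:
    """Poisson counting noise: incident fluence per detector pixel.

    The default is set so the ramp-filtered noise floor of a breast-scale
    scan sits below the reconstruction's default data-error tolerance —
    mirroring how that tolerance is chosen just above the noise level on
    physical data.  ``fluence=None`` disables noise (exact line
    integrals).
    """

    fluence: float | None = 2e8
    seed: int = 0

    def __post_init__(self):
        if self.fluence is not None and self.fluence <= 0:
            raise ValueError("fluence must be > 0 (or None for noiseless)")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    support: np.ndarray  # bool, slab-and-breast-outline support
    glandular: np.ndarray  # bool, glandular tissue indicator (incl. insert bases)
    iodine_mgml: np.ndarray  # float, iodine concentration map
    mu_le: np.ndarray
    mu_he: np.ndarray
    inserts: list  # dicts: center_mm, diameter_mm, concentration_mgml
    glandular_fraction: float
    spectral: SpectralModel
    spec: PhantomSpec

    def to_metadata(self) -> dict:
        return {
            "inserts": self.inserts,
            "glandular_fraction": self.glandular_fraction,
            "slab_thickness": self.spec.slab_thickness,
        }


def _world_coords(grid: VolumeGrid):
    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    z = grid.axis_coords(2)
    return np.meshgrid(x, y, z, indexing="ij", sparse=True)


def make_phantom(
    spec: PhantomSpec,
    grid: VolumeGrid,
    spectral: SpectralModel | None = None,
) -> PhantomTruth:
    """Generate material maps, dual-energy attenuation volumes and truth.

    Deterministic given ``spec.seed``.  Raises if an insert does not fit
    inside the slab or the in-plane outline.
    """
    spectral = spectral or SpectralModel()
    xx, yy, zz = _world_coords(grid)
    vs = grid.voxel_size

    # in-plane elliptical outline centred on the grid, slab centred in z
    x_c = grid.axis_coords(0).mean()
    y_c = grid.axis_coords(1).mean()
    z_c = grid.axis_coords(2).mean()
    rx = 0.45 * grid.nx * vs
    ry = 0.45 * grid.ny * vs
    half_t = spec.slab_thickness / 2.0
    in_plane = ((xx - x_c) / rx) ** 2 + ((yy - y_c) / ry) ** 2 <= 1.0
    in_z = np.abs(zz - z_c) <= half_t
    support = in_plane & in_z

    # glandular texture: smoothed seeded noise thresholded to the target fraction
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(tuple(grid.shape))
    sigma_vox = spec.texture_scale_mm / vs
    field_ = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    vals = field_[support]
    if spec.glandular_fraction in (0.0, 1.0):
        glandular = support & (spec.glandular_fraction == 1.0)
    else:
        thresh = np.quantile(vals, 1.0 - spec.glandular_fraction)
        glandular = support & (field_ > thresh)

    # inserts on a diameter (x) by concentration (y) layout at mid-depth
    n_d = len(spec.insert_diameters)
    n_c = len(spec.iodine_concentrations)
    x_pos = x_c + rx * np.linspace(-0.55, 0.55, n_d) if n_d > 1 else np.array([x_c])
    y_pos = y_c + ry * np.linspace(-0.55, 0.55, n_c) if n_c > 1 else np.array([y_c])
    iodine = np.zeros(tuple(grid.shape))
    inserts = []
    for ic, conc in enumerate(spec.iodine_concentrations):
        for idm, diam in enumerate(spec.insert_diameters):
            r = diam / 2.0
            cx, cy, cz = float(x_pos[idm]), float(y_pos[ic]), float(z_c)
            if r > half_t:
                raise ValueError(
                    f"insert of diameter {diam} mm does not fit in a "
                    f"{spec.slab_thickness} mm slab"
                )
            if ((cx - x_c) / rx) ** 2 + ((cy - y_c) / ry) ** 2 > (1.0 - r / min(rx, ry)) ** 2:
                raise ValueError(f"insert at ({cx:.1f}, {cy:.1f}) falls outside the outline")
            if spec.insert_shape == "sphere":
                region = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= r**2
            else:
                region = (((xx - cx) ** 2 + (yy - cy) ** 2 <= r**2)
                          & (np.abs(zz - cz) <= r))
            iodine[region] = conc
            glandular = glandular | region  # solid inserts sit in a glandular-equivalent base
            inserts.append(
                {"center_mm": [cx, cy, cz], "diameter_mm": float(diam),
                 "concentration_mgml": float(conc)}
            )

    tissue_le = np.where(glandular, spectral.glandular_le, spectral.adipose_le)
    tissue_he = np.where(glandular, spectral.glandular_he, spectral.adipose_he)
    mu_le = support * tissue_le + iodine * spectral.iodine_le
    mu_he = support * tissue_he + iodine * spectral.iodine_he
    gfrac = float(glandular[support].mean()) if support.any() else 0.0
    return PhantomTruth(
        support=support,
        glandular=glandular,
        iodine_mgml=iodine,
        mu_le=mu_le,
        mu_he=mu_he,
        inserts=inserts,
        glandular_fraction=gfrac,
        spectral=spectral,
        spec=spec,
    )


def _simulate_one(mu, geom, grid, fluence, rng):
    line = forward_project(mu, geom, grid)
    if fluence is None or np.isinf(fluence):
        return line
    counts = rng.poisson(fluence * np.exp(-line)).astype(float)
    if np.any(counts == 0):
        warnings.warn("zero photon counts clamped to 1 before the logarithm")
        counts = np.maximum(counts, 1.0)
    return -np.log(counts / fluence)


def simulate_de_scan(
    mu_le: np.ndarray,
    mu_he: np.ndarray,
    geom: ScanGeometry,
    grid: VolumeGrid,
    noise: NoiseModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the dual-energy acquisition; returns (g_LE, g_HE).

    Per energy: line integrals -> Poisson counts at the stated fluence ->
    flood-field division -> negative log.  Deterministic given
    ``noise.seed``; ``fluence=None`` gives exact line integrals.
    """
    noise = noise or NoiseModel()
    if np.any(np.asarray(mu_le) < 0) or np.any(np.asarray(mu_he) < 0):
        raise ValueError("attenuation volumes must be non-negative")
    ss = np.random.SeedSequence(noise.seed)
    rng_le, rng_he = (np.random.default_rng(s) for s in ss.spawn(2))
    g_le = _simulate_one(mu_le, geom, grid, noise.fluence, rng_le)
    g_he = _simulate_one(mu_he, geom, grid, noise.fluence, rng_he)
    return g_le, g_he


def _background_mu(spectral: SpectralModel, glandular_fraction: float):
    mu_bg_le = (glandular_fraction * spectral.glandular_le
                + (1 - glandular_fraction) * spectral.adipose_le)
    mu_bg_he = (glandular_fraction * spectral.glandular_he
                + (1 - glandular_fraction) * spectral.adipose_he)
    return mu_bg_le, mu_bg_he


def analytic_cancellation_weight(
    spectral: SpectralModel, glandular_fraction: float = 0.5
) -> float:
    """Weight that exactly nulls tissue texture in ideal normalized volumes.

    In a normalized volume the tissue fluctuation is
    (glandular - adipose contrast) / (mean background attenuation), so the
    cancelling weight is the ratio of that relative contrast between the
    two energies.
    """
    mu_bg_le, mu_bg_he = _background_mu(spectral, glandular_fraction)
    contrast_he = (spectral.glandular_he - spectral.adipose_he) / mu_bg_he
    contrast_le = (spectral.glandular_le - spectral.adipose_le) / mu_bg_le
    return contrast_he / contrast_le


def ideal_normalized_volume(truth: PhantomTruth, energy: str) -> np.ndarray:
    """Noise- and reconstruction-free normalized volume mu / mean(mu_bg).

    The idealization of the full chain (perfect reconstruction and exact
    constant background): on the support the value is the attenuation
    divided by the mean background attenuation, zero elsewhere.
    """
    if energy not in ("le", "he"):
        raise ValueError("energy must be 'le' or 'he'")
    mu = truth.mu_le if energy == "le" else truth.mu_he
    mu_bg_le, mu_bg_he = _background_mu(truth.spectral, truth.spec.glandular_fraction)
    mu_bg = mu_bg_le if energy == "le" else mu_bg_he
    return truth.support * (mu / mu_bg)
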