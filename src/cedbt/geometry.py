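"""Scan geometry and voxel-grid descriptions for a DBT acquisition.

The scanner model is a partial-arc cone-beam system: the X-ray source
travels on a circular arc above a stationary flat-panel detector while the
detector collects one projection per source position.  The arc lies in the
y-z plane (y is the source travel direction, z the detector normal), and
the rotation axis is parallel to x at a configurable height above the
detector plane.

Units are millimetres and degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ScanGeometry",
    "VolumeGrid",
    "make_dbt_geometry",
    "desk_geometry",
    "default_volume_grid",
]

#: Native detector pixel pitch of a clinical DBT flat panel, mm.
NATIVE_DETECTOR_PITCH_MM = 0.085

#: Default down-sampling factor from native to working resolution.
DEFAULT_BINNING = 8


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {name}: {msg}")


@dataclass(frozen=True)
class ScanGeometry:
    """Arc of source positions over a stationary flat detector.

    Attributes
    ----------
    n_views:
        Number of projections acquired along the arc.
    arc_span:
        Total angular range of the arc in degrees, symmetric about the
        detector normal.
    source_to_detector_distance:
        Distance from the source (at the central view) to the detector
        plane, mm.
    rotation_axis_height:
        Height of the rotation axis above the detector plane, mm.  The
        axis is parallel to x.
    detector_pitch:
        Detector pixel pitch at the working resolution, mm.
    detector_shape:
        ``(rows, cols)``; rows run along y (source travel), cols along x.
    """

    n_views: int = 25
    arc_span: float = 50.0
    source_to_detector_distance: float = 650.0
    rotation_axis_height: float = 47.0
    detector_pitch: float = 0.68
    detector_shape: tuple[int, int] = (208, 160)

    def __post_init__(self):
        _require(self.n_views >= 1, "n_views", "must be >= 1")
        _require(0 < self.arc_span < 360, "arc_span", "must lie in (0, 360)")
        _require(self.detector_pitch > 0, "detector_pitch", "must be > 0")
        _require(
            self.source_to_detector_distance > self.rotation_axis_height >= 0,
            "rotation_axis_height",
            "must satisfy 0 <= height < source_to_detector_distance",
        )
        rows, cols = self.detector_shape
        _require(rows >= 1 and cols >= 1, "detector_shape", "must be positive")

    @property
    def view_angles(self) -> np.ndarray:
        """View angles in degrees, equally spaced and centred on 0."""
        n = self.n_views
        if n == 1:
            return np.zeros(1)
        half = self.arc_span / 2.0
        return np.linspace(-half, half, n)

    @property
    def source_radius(self) -> float:
        """Distance from the rotation axis to the source, mm."""
        return self.source_to_detector_distance - self.rotation_axis_height

    def source_positions(self) -> np.ndarray:
        """Source positions, shape (n_views, 3) as (x, y, z) in mm.

        At angle theta the source sits at
        ``(0, r sin(theta), h + r cos(theta))`` with r the source radius
        and h the rotation-axis height; theta = 0 puts the source on the
        detector normal at the source-to-detector distance.
        """
        th = np.deg2rad(self.view_angles)
        r = self.source_radius
        pos = np.zeros((self.n_views, 3))
        pos[:, 1] = r * np.sin(th)
        pos[:, 2] = self.rotation_axis_height + r * np.cos(th)
        return pos

    def detector_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World (y_rows, x_cols) coordinates of detector pixel centres.

        The detector is centred on the origin of the x-y plane at z = 0.
        """
        rows, cols = self.detector_shape
        ys = (np.arange(rows) - (rows - 1) / 2.0) * self.detector_pitch
        xs = (np.arange(cols) - (cols - 1) / 2.0) * self.detector_pitch
        return ys, xs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector_shape"] = list(self.detector_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        d["detector_shape"] = tuple(d["detector_shape"])
        return cls(**d)


@dataclass(frozen=True)
class VolumeGrid:
    """Cubic-voxel reconstruction grid.

    ``shape`` is ``(nx, ny, nz)``: x and y are in-plane, z is depth
    (perpendicular to the detector, increasing from the detector plane
    toward the source).  ``origin`` is the world position of the centre of
    voxel (0, 0, 0), mm.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        _require(all(n >= 1 for n in self.shape), "shape", "all dims must be >= 1")
        _require(self.voxel_size > 0, "voxel_size", "must be > 0")

    @property
    def nx(self) -> int:
        return self.shape[0]

    @property
    def ny(self) -> int:
        return self.shape[1]

    @property
    def nz(self) -> int:
        return self.shape[2]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size": self.voxel_size,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeGrid":
        return cls(tuple(d["shape"]), d["voxel_size"], tuple(d["origin"]))


def make_dbt_geometry(
    n_views: int = 25,
    arc_span: float = 50.0,
    source_to_detector_distance: float = 650.0,
    rotation_axis_height: float = 47.0,
    detector_pitch: float | None = None,
    detector_shape: tuple[int, int] = (208, 160),
    binning: int = DEFAULT_BINNING,
) -> ScanGeometry:
    """Build a DBT scan geometry.

    When ``detector_pitch`` is None the working pitch is derived from the
    native 85 um panel pitch times the ``binning`` factor (8 by default,
    giving 0.68 mm working pixels).
    """
    if detector_pitch is None:
        _require(binning >= 1, "binning", "must be >= 1")
        detector_pitch = NATIVE_DETECTOR_PITCH_MM * binning
    return ScanGeometry(
        n_views=n_views,
        arc_span=arc_span,
        source_to_detector_distance=source_to_detector_distance,
        rotation_axis_height=rotation_axis_height,
        detector_pitch=detector_pitch,
        detector_shape=tuple(detector_shape),
    )


def desk_geometry(
    n_views: int = 25,
    arc_span: float = 50.0,
    detector_pitch: float = 1.0,
    detector_shape: tuple[int, int] = (176, 128),
) -> ScanGeometry:
    """Desk-scale geometry matched to the default 1 mm test grid.

    Same arc as the clinical acquisition (25 views over 50 degrees) but
    with 1 mm detector pixels sized to cover the desk phantom from every
    view, keeping simulation cost low.
    """
    return ScanGeometry(
        n_views=n_views,
        arc_span=arc_span,
        detector_pitch=detector_pitch,
        detector_shape=tuple(detector_shape),
    )


def default_volume_grid(
    shape: tuple[int, int, int] = (128, 128, 64), voxel_size: float = 1.0
) -> VolumeGrid:
    """Desk-scale grid centred under the detector with z = 0 at its base.

    The grid is centred on the rotation axis in x and y; the first voxel
    layer sits half a voxel above the detector plane.
    """
    nx, ny, nz = shape
    origin = (
        -(nx - 1) / 2.0 * voxel_size,
        -(ny - 1) / 2.0 * voxel_size,
        voxel_size / 2.0,
    )
    return VolumeGrid(tuple(shape), voxel_size, origin)
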