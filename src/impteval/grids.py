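"""Regular dose grids and beam-frame geometry.

Coordinate convention (patient-centric, fixed throughout the package):
axis 0 = x = R-L (+x toward patient left), axis 1 = y = A-P (+y toward
anterior), axis 2 = z = S-I (+z toward superior).  Voxel ``(i, j, k)`` owns
the half-open cube ``[origin + i*spacing, origin + (i+1)*spacing)``; the
coordinates used for dose evaluation are voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AXIS_NAMES = ("RL", "AP", "SI")


@dataclass
class DoseGrid:
    """A 3D scalar field of absorbed dose in Gy[RBE] on a regular grid."""

    values: np.ndarray
    spacing: np.ndarray  # mm per axis, shape (3,)
    origin: np.ndarray  # mm, position of voxel (0,0,0) corner

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.values.copy(), self.spacing.copy(), self.origin.copy())

    def same_geometry(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def __add__(self, other: "DoseGrid") -> "DoseGrid":
        if not self.same_geometry(other):
            raise ValueError("cannot add dose grids with mismatched geometry")
        return DoseGrid(self.values + other.values, self.spacing, self.origin)

    def __mul__(self, scale: float) -> "DoseGrid":
        return DoseGrid(self.values * float(scale), self.spacing, self.origin)

    __rmul__ = __mul__

    def integral_gy_cm3(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_cm3


def grid_like(shape, spacing, origin=None) -> DoseGrid:
    """An all-zero dose grid; origin defaults to centering the grid on (0,0,0)."""
    spacing = np.asarray(spacing, dtype=float).reshape(-1)
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    shape = tuple(int(s) for s in shape)
    if origin is None:
        origin = -spacing * np.asarray(shape) / 2.0
    return DoseGrid(np.zeros(shape), spacing, np.asarray(origin, dtype=float))


def voxel_centers(grid: DoseGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis 1D arrays of voxel-center coordinates in mm."""
    return tuple(
        grid.origin[a] + (np.arange(grid.shape[a]) + 0.5) * grid.spacing[a]
        for a in range(3)
    )


def beam_direction(gantry_deg: float, couch_deg: float) -> np.ndarray:
    """Unit direction of proton travel in patient coordinates.

    Gantry 0 enters from anterior, 180 from posterior; the couch angle
    rotates the gantry plane about the A-P axis, so couch 270 with posterior
    oblique gantry angles produces superior/inferior-posterior obliques.
    """
    g = np.deg2rad(gantry_deg)
    c = np.deg2rad(couch_deg)
    d0 = np.array([np.sin(g), -np.cos(g), 0.0])
    rot = np.array(
        [
            [np.cos(c), 0.0, np.sin(c)],
            [0.0, 1.0, 0.0],
            [-np.sin(c), 0.0, np.cos(c)],
        ]
    )
    d = rot @ d0
    return d / np.linalg.norm(d)


def beam_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (e_u, e_v, e_w) with e_w along the beam.

    Lateral axes are chosen deterministically: e_u is the normalized cross
    product of the S-I axis with the beam direction (falling back to the R-L
    axis for near-axial beams).
    """
    w = np.asarray(direction, dtype=float)
    w = w / np.linalg.norm(w)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(w, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, w)
    u = u / np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w
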