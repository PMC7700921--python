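"""Voxel phantoms with target and organ-at-risk structure masks.

The phantom is a geometric stand-in for a distal-esophageal-cancer patient:
an elliptical-cylinder body containing a two-level target (CTV_high inside
CTV_low, both near the posterior midline above the gastroesophageal
junction) surrounded by the organs at risk that drive the dose constraints
(liver right-lateral, heart anterior-superior, spinal cord posterior
midline, lungs superior-lateral, stomach left, kidneys posterior-inferior).
The optimization target volume (OTV) is the CTV_low expanded by a uniform
Euclidean margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import voxel_centers, grid_like, DoseGrid

TARGET_CHAIN = ("ctv_high", "ctv_low", "otv")
OAR_NAMES = (
    "liver",
    "heart",
    "spinal_cord",
    "lung_left",
    "lung_right",
    "stomach",
    "kidney_left",
    "kidney_right",
)


class PhantomSizingError(ValueError):
    """A requested structure volume cannot be realized on the grid."""


class PhantomLayoutError(ValueError):
    """Structures overlap beyond tolerance or fall outside the body."""


@dataclass
class Phantom:
    """Voxelized anatomy: a body mask plus named binary structure masks."""

    grid_shape: tuple[int, int, int]
    spacing: np.ndarray  # mm
    origin: np.ndarray  # mm
    structures: dict[str, np.ndarray]
    body_mask: np.ndarray

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.validate()

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def volume_cm3(self, name: str) -> float:
        return float(self.structures[name].sum()) * self.voxel_volume_cm3

    def mask(self, name: str) -> np.ndarray:
        if name == "lungs":
            return self.structures["lung_left"] | self.structures["lung_right"]
        if name == "body":
            return self.body_mask
        return self.structures[name]

    def empty_grid(self) -> DoseGrid:
        return grid_like(self.grid_shape, self.spacing, self.origin)

    def validate(self) -> None:
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        for name, m in self.structures.items():
            if m.shape != tuple(self.grid_shape):
                raise ValueError(f"mask {name!r} does not share the phantom grid")
            if not m.any():
                raise PhantomSizingError(f"structure {name!r} is empty")
        chain = [self.structures[n] for n in TARGET_CHAIN] + [self.body_mask]
        for inner, outer, names in zip(
            chain, chain[1:], zip(TARGET_CHAIN, TARGET_CHAIN[1:] + ("body",))
        ):
            if np.any(inner & ~outer):
                raise PhantomLayoutError(
                    f"containment violated: {names[0]} not inside {names[1]}"
                )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry request for :func:`build_phantom` (volumes in cm^3, mm grid)."""

    ctv_high_cm3: float = 180.0
    ctv_low_cm3: float = 390.0
    grid_shape: tuple[int, int, int] = (96, 96, 120)
    spacing_mm: float = 2.5
    otv_margin_mm: float = 5.0
    ctv_aspect_si: float = 2.2  # S-I elongation of the target ellipsoids
    center_jitter_mm: float = 4.0  # per-axis uniform jitter of the target center
    volume_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.ctv_high_cm3 <= 0 or self.ctv_low_cm3 <= 0:
            raise PhantomSizingError("structure volumes must be positive")
        if self.ctv_high_cm3 >= self.ctv_low_cm3:
            raise PhantomSizingError("CTV_high volume must be below CTV_low volume")


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (
        ((x[:, None, None] - center[0]) / semi[0]) ** 2
        + ((y[None, :, None] - center[1]) / semi[1]) ** 2
        + ((z[None, None, :] - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _calibrated_ellipsoid(coords, center, semi, target_cm3, vox_cm3, tol):
    """Scale the semi-axes until the voxelized volume matches the request."""
    lo, hi = 0.7, 1.4
    semi = np.asarray(semi, dtype=float)
    best = None
    for _ in range(40):
        s = 0.5 * (lo + hi)
        m = _ellipsoid(coords, center, semi * s)
        v = m.sum() * vox_cm3
        best = m
        if abs(v - target_cm3) / target_cm3 < min(tol, 0.01):
            return m
        if v < target_cm3:
            lo = s
        else:
            hi = s
    v = best.sum() * vox_cm3
    if abs(v - target_cm3) / target_cm3 > tol:
        raise PhantomSizingError(
            f"could not realize {target_cm3:.1f} cm^3 on the grid (got {v:.1f})"
        )
    return best


def build_phantom(config: PhantomConfig = PhantomConfig(), seed: int = 0) -> Phantom:
    """Build a phantom with target volumes within tolerance of the request.

    Generation is a pure function of ``(config, seed)``; the seed perturbs
    the target position slightly so cohort members differ anatomically.
    """
    rng = np.random.default_rng(seed)
    grid = grid_like(config.grid_shape, config.spacing_mm)
    coords = voxel_centers(grid)
    x, y, z = coords
    vox_cm3 = grid.voxel_volume_cm3
    half_extent = np.asarray(config.grid_shape) * config.spacing_mm / 2.0

    # Body: elliptical cylinder filling most of the transverse extent.
    body_semi = (0.92 * half_extent[0], 0.88 * half_extent[1])
    body = (
        (x[:, None, None] / body_semi[0]) ** 2 + (y[None, :, None] / body_semi[1]) ** 2
    ) <= 1.0
    body = np.broadcast_to(body, config.grid_shape).copy()

    jitter = rng.uniform(-config.center_jitter_mm, config.center_jitter_mm, size=3)
    ctv_center = np.array([0.0, -0.22 * half_extent[1], 0.0]) + jitter

    # Target ellipsoids elongated along S-I; CTV_high sits concentric with a
    # slight inferior offset (the boost covers the distal/junctional part).
    def semi_axes(volume_cm3):
        a = (volume_cm3 * 1000.0 * 3.0 / (4.0 * np.pi * config.ctv_aspect_si)) ** (
            1.0 / 3.0
        )
        return np.array([a, a, config.ctv_aspect_si * a])

    ctv_low = _calibrated_ellipsoid(
        coords,
        ctv_center,
        semi_axes(config.ctv_low_cm3),
        config.ctv_low_cm3,
        vox_cm3,
        config.volume_tolerance,
    )
    high_center = ctv_center + np.array([0.0, 0.0, -0.1 * half_extent[2] * 0.3])
    ctv_high = _calibrated_ellipsoid(
        coords,
        high_center,
        semi_axes(config.ctv_high_cm3),
        config.ctv_high_cm3,
        vox_cm3,
        config.volume_tolerance,
    )
    ctv_high &= ctv_low
    if ctv_high.sum() * vox_cm3 < (1 - config.volume_tolerance) * config.ctv_high_cm3:
        raise PhantomSizingError("CTV_high does not fit inside CTV_low")

    # OTVs: Euclidean-distance expansion of each CTV, clipped to the body.
    dist = ndimage.distance_transform_edt(~ctv_low, sampling=grid.spacing)
    otv = (dist <= config.otv_margin_mm) & body
    dist_h = ndimage.distance_transform_edt(~ctv_high, sampling=grid.spacing)
    otv_high = (dist_h <= config.otv_margin_mm) & body & otv
    ctv_low &= body
    ctv_high &= body

    hx, hy, hz = half_extent

    def oar(center_frac, semi_mm):
        c = np.array(center_frac) * half_extent
        return _ellipsoid(coords, c, np.asarray(semi_mm, dtype=float))

    structures = {
        "ctv_high": ctv_high,
        "ctv_low": ctv_low,
        "otv": otv,
        "otv_high": otv_high,
        # Fixed anatomically-plausible OAR layout (fractions of the half-extent).
        "liver": oar((-0.45, 0.05, -0.45), (0.42 * hx, 0.5 * hy, 0.42 * hz)),
        "heart": oar((0.12, 0.35, 0.30), (0.40 * hx, 0.36 * hy, 0.30 * hz)),
        "spinal_cord": np.broadcast_to(
            (
                (x[:, None, None] - 0.0) ** 2
                + (y[None, :, None] - (-0.82 * hy)) ** 2
            )
            <= 4.0**2,
            config.grid_shape,
        ).copy(),
        "lung_left": oar((0.55, 0.08, 0.52), (0.33 * hx, 0.46 * hy, 0.42 * hz)),
        "lung_right": oar((-0.55, 0.08, 0.52), (0.33 * hx, 0.46 * hy, 0.42 * hz)),
        "stomach": oar((0.48, 0.12, -0.55), (0.33 * hx, 0.33 * hy, 0.28 * hz)),
        "kidney_left": oar((0.42, -0.42, -0.72), (0.18 * hx, 0.24 * hy, 0.24 * hz)),
        "kidney_right": oar((-0.42, -0.42, -0.72), (0.18 * hx, 0.24 * hy, 0.24 * hz)),
    }

    # OARs never overlap the OTV or each other (priority = listed order).
    claimed = otv.copy()
    for name in OAR_NAMES:
        m = structures[name] & body & ~claimed
        if not m.any():
            raise PhantomLayoutError(f"OAR {name!r} vanished after overlap removal")
        structures[name] = m
        claimed |= m

    return Phantom(
        grid_shape=tuple(config.grid_shape),
        spacing=grid.spacing,
        origin=grid.origin,
        structures=structures,
        body_mask=body,
    )


@dataclass(frozen=True)
class MotionModel:
    """Rigid respiratory motion between two extreme phases.

    ``amplitude_mm`` is the exhale-to-inhale displacement vector on the
    (R-L, A-P, S-I) axes; the scalar "tumor motion amplitude" is defined as
    the largest single-axis component.
    """

    amplitude_mm: np.ndarray
    period_s: float = 4.0
    n_phases: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "amplitude_mm", np.asarray(self.amplitude_mm, dtype=float).reshape(3)
        )
        if self.period_s <= 0:
            raise ValueError("breathing period must be positive")
        if np.any(np.isnan(self.amplitude_mm)):
            raise ValueError("amplitude must be finite")

    @property
    def scalar_amplitude_mm(self) -> float:
        return float(np.max(np.abs(self.amplitude_mm)))


DEFAULT_AXIS_WEIGHTS = (0.25, 0.3, 1.0)  # S-I dominant breathing motion


def make_motion_model(
    amplitude_cm: float,
    period_s: float = 4.0,
    axis_weights: tuple[float, float, float] = DEFAULT_AXIS_WEIGHTS,
) -> MotionModel:
    """Motion model whose largest single-axis component equals ``amplitude_cm``."""
    if amplitude_cm < 0:
        raise ValueError("motion amplitude must be non-negative")
    w = np.abs(np.asarray(axis_weights, dtype=float))
    if w.max() == 0:
        vec = np.zeros(3)
    else:
        vec = amplitude_cm * 10.0 * w / w.max()
    return MotionModel(amplitude_mm=vec, period_s=period_s)
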