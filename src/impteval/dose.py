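"""Analytic pencil-beam dose engine.

The engine computes 3D dose on the phantom grid from a spot plan under a
delivery scenario (rigid setup shift, multiplicative range scaling,
respiratory phase).  Each spot deposits

    dose = MU * A * L(z; R * range_scale) * G2(lateral offset; sigma)

where ``z`` is the depth along the beam axis measured from the first
body-surface intersection of the ray, ``R`` the Bragg-Kleeman range of the
layer energy, ``G2`` a 2D lateral Gaussian, and ``L`` a plateau-plus-
Gaussian-peak depth-dose:

    L(z; R) = f + (1 - f) * exp(-(z - R)^2 / (2 sigma_z^2))   for 0 <= z <= R
    L(z; R) = exp(-(z - R)^2 / (2 sigma_z^2))                 for z > R

The medium is water-equivalent (geometric depth = radiological depth), so a
rigid whole-patient translation leaves depths unchanged and acts purely as a
lateral displacement of the spot pattern relative to the anatomy; this is the
stated equivalence between shifting the patient and counter-shifting the beam
isocenters, and is how scenarios are evaluated.

For speed, :meth:`DoseEngine.compute_dose` rasterizes each layer's spot MU
onto a fine lateral grid (bilinear deposition), Gaussian-filters it once, and
samples the filtered fluence at voxel positions; :func:`spot_dose` evaluates
the single-spot kernel exactly and serves as the engine's cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import DoseGrid, beam_frame, voxel_centers
from .machine import bragg_range_mm
from .phantom import Phantom, MotionModel

PHASES = ("averaged", "exhale", "inhale")


class GeometryError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """A rigid setup shift (mm), a range scaling factor, and a breathing phase."""

    setup_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    range_scale: float = 1.0
    phase: str = "averaged"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if not np.isfinite(self.range_scale) or self.range_scale <= 0:
            raise ValueError("range_scale must be positive and finite")

    @property
    def shift(self) -> np.ndarray:
        return np.asarray(self.setup_shift_mm, dtype=float)


NOMINAL = Scenario()


@dataclass(frozen=True)
class SpotKernel:
    """Parameters of the analytic spot kernel.

    sigma_lateral_mm   in-air + in-medium lateral spot sigma
    sigma_bragg_mm     Gaussian width of the Bragg peak in depth
    plateau_fraction   entrance-plateau level relative to the peak
    gy_mm2_per_mu      absolute calibration: peak-layer dose integrated over
                       the lateral plane per MU.  Fixes the MU scale so that
                       a standard-fractionation plan produces per-fraction
                       spot weights mostly above the iso-layer repaint
                       maximum (median near 0.08 MU), keeping the repainting
                       mechanism operative as on the modeled machine.
    """

    sigma_lateral_mm: float = 5.0
    sigma_bragg_mm: float = 3.0
    plateau_fraction: float = 0.35
    gy_mm2_per_mu: float = 200.0

    def __post_init__(self) -> None:
        if min(self.sigma_lateral_mm, self.sigma_bragg_mm, self.gy_mm2_per_mu) <= 0:
            raise ValueError("kernel parameters must be positive")
        if not 0 < self.plateau_fraction < 1:
            raise ValueError("plateau_fraction must lie in (0, 1)")

    def depth_dose(self, z_mm: np.ndarray, range_mm: float) -> np.ndarray:
        z = np.asarray(z_mm, dtype=float)
        peak = np.exp(-((z - range_mm) ** 2) / (2.0 * self.sigma_bragg_mm**2))
        out = np.where(
            z <= range_mm,
            self.plateau_fraction + (1.0 - self.plateau_fraction) * peak,
            peak,
        )
        return np.where(z < 0, 0.0, out)


def phase_displacement(motion: MotionModel | None, phase: str) -> np.ndarray:
    """Patient displacement of a breathing phase relative to the exhale frame."""
    if motion is None:
        return np.zeros(3)
    if phase == "exhale":
        return np.zeros(3)
    if phase == "inhale":
        return motion.amplitude_mm.copy()
    if phase == "averaged":
        return 0.5 * motion.amplitude_mm
    raise ValueError(f"unknown phase {phase!r}")


class DoseEngine:
    """Caches per-beam voxel geometry (beam-frame coordinates and the
    body-entry depth map) for repeated scenario evaluations on one phantom."""

    def __init__(
        self,
        phantom: Phantom,
        kernel: SpotKernel | None = None,
        lateral_grid_mm: float = 2.5,
    ):
        self.phantom = phantom
        self.kernel = kernel or SpotKernel()
        self.h = float(lateral_grid_mm)
        self._beam_cache: dict = {}
        cx, cy, cz = voxel_centers(phantom.empty_grid())
        self._cx, self._cy, self._cz = cx, cy, cz

    # -- geometry ---------------------------------------------------------
    def _beam_key(self, direction, isocenter):
        return tuple(np.round(direction, 9)) + tuple(np.round(isocenter, 6))

    def beam_geometry(self, direction: np.ndarray, isocenter: np.ndarray):
        key = self._beam_key(direction, isocenter)
        if key in self._beam_cache:
            return self._beam_cache[key]
        eu, ev, ew = beam_frame(direction)
        iso = np.asarray(isocenter, dtype=float)
        px = (self._cx - iso[0]).astype(np.float32)
        py = (self._cy - iso[1]).astype(np.float32)
        pz = (self._cz - iso[2]).astype(np.float32)

        def frame_coord(e):
            return (
                px[:, None, None] * np.float32(e[0])
                + py[None, :, None] * np.float32(e[1])
                + pz[None, None, :] * np.float32(e[2])
            )

        u = frame_coord(eu)
        v = frame_coord(ev)
        s = frame_coord(ew)

        # Body entry map: minimal along-axis coordinate of body voxels per
        # lateral bin; depth of a voxel = its s minus the entry of its ray.
        body = self.phantom.body_mask
        ub, vb, sb = u[body], v[body], s[body]
        u0, v0 = float(ub.min()), float(vb.min())
        nu = int(np.ceil((ub.max() - u0) / self.h)) + 1
        nv = int(np.ceil((vb.max() - v0) / self.h)) + 1
        entry = np.full((nu, nv), np.inf, dtype=np.float32)
        iu = np.clip(((ub - u0) / self.h).astype(np.int64), 0, nu - 1)
        iv = np.clip(((vb - v0) / self.h).astype(np.int64), 0, nv - 1)
        np.minimum.at(entry, (iu, iv), sb)
        empty = ~np.isfinite(entry)
        if empty.any():
            idx = ndimage.distance_transform_edt(
                empty, return_distances=False, return_indices=True
            )
            entry = entry[tuple(idx)]

        # Depth relative to the (motion-independent) body surface.
        gi = np.clip((u - u0) / self.h, 0, nu - 1.001)
        gj = np.clip((v - v0) / self.h, 0, nv - 1.001)
        s0 = ndimage.map_coordinates(entry, [gi.ravel(), gj.ravel()], order=1)
        z = (s.ravel() - s0).reshape(u.shape).astype(np.float32)

        geo = {
            "eu": eu,
            "ev": ev,
            "ew": ew,
            "u": u,
            "v": v,
            "z": z,
            "entry": entry,
            "u0": u0,
            "v0": v0,
        }
        self._beam_cache[key] = geo
        return geo

    # -- fluence ----------------------------------------------------------
    def _layer_fluence(self, spots: np.ndarray, pad_mm: float):
        """Gaussian-filtered lateral MU density (MU/mm^2) on a fine grid."""
        h = self.h
        sig = self.kernel.sigma_lateral_mm
        x, y, mu = spots[:, 0], spots[:, 1], spots[:, 2]
        fu0 = float(x.min()) - pad_mm
        fv0 = float(y.min()) - pad_mm
        nu = int(np.ceil((x.max() + pad_mm - fu0) / h)) + 2
        nv = int(np.ceil((y.max() + pad_mm - fv0) / h)) + 2
        grid = np.zeros((nu, nv))
        gx = (x - fu0) / h
        gy = (y - fv0) / h
        i0 = np.floor(gx).astype(int)
        j0 = np.floor(gy).astype(int)
        fx = gx - i0
        fy = gy - j0
        # Bilinear deposition preserves each spot's MU and first moment.
        for di, dj, w in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            np.add.at(grid, (np.clip(i0 + di, 0, nu - 1), np.clip(j0 + dj, 0, nv - 1)), mu * w)
        flu = ndimage.gaussian_filter(grid, sigma=sig / h, mode="constant") / h**2
        return flu, fu0, fv0

    # -- dose -------------------------------------------------------------
    def compute_dose(
        self,
        plan,
        scenario: Scenario = NOMINAL,
        motion: MotionModel | None = None,
        total_course: bool = True,
        roi_mask: np.ndarray | None = None,
        frame: str = "patient",
    ) -> DoseGrid:
        """Dose grid for the plan under a scenario.

        ``frame="patient"`` returns dose-to-tissue on the reference (exhale,
        unshifted) anatomy grid; ``frame="room"`` returns the same dose
        expressed on the room-fixed grid with the patient displaced, which is
        the representation consumed by the phase-to-reference mapping of the
        4D accumulation.
        """
        ph = self.phantom
        out = np.zeros(ph.grid_shape)
        disp = scenario.shift + phase_displacement(motion, scenario.phase)
        pad = 4.0 * self.kernel.sigma_lateral_mm
        for beam in plan.beams:
            if not beam.layers:
                continue
            geo = self.beam_geometry(beam.direction, plan.isocenter_mm)
            du = float(disp @ geo["eu"])
            dv = float(disp @ geo["ev"])
            u, v, z = geo["u"], geo["v"], geo["z"]
            # Candidate voxels: along-ray depth reached and laterally near
            # the spot field (margin covers shifts and the Gaussian tails).
            all_x = np.concatenate([l.spots[:, 0] for l in beam.layers])
            all_y = np.concatenate([l.spots[:, 1] for l in beam.layers])
            m = 1.5 * pad + 15.0
            cand = (
                (z >= 0)
                & (u + du >= all_x.min() - m)
                & (u + du <= all_x.max() + m)
                & (v + dv >= all_y.min() - m)
                & (v + dv <= all_y.max() + m)
            )
            if roi_mask is not None:
                cand &= roi_mask
            idx = np.flatnonzero(cand.ravel())
            if idx.size == 0:
                continue
            uc = u.ravel()[idx] + du
            vc = v.ravel()[idx] + dv
            zc = z.ravel()[idx]
            acc = np.zeros(idx.size)
            zmax_pad = 4.0 * self.kernel.sigma_bragg_mm
            for layer in beam.layers:
                if layer.spots.shape[0] == 0 or layer.spots[:, 2].sum() == 0:
                    continue
                r = float(bragg_range_mm(layer.energy_mev)) * scenario.range_scale
                sel = zc <= r + zmax_pad
                if not sel.any():
                    continue
                flu, fu0, fv0 = self._layer_fluence(layer.spots, pad)
                gi = (uc[sel] - fu0) / self.h
                gj = (vc[sel] - fv0) / self.h
                f = ndimage.map_coordinates(
                    flu, [gi, gj], order=1, mode="constant", cval=0.0
                )
                ld = self.kernel.depth_dose(zc[sel], r)
                acc[sel] += f * ld
            out.ravel()[idx] += acc * self.kernel.gy_mm2_per_mu
        if total_course:
            out *= plan.n_fractions
        dose = DoseGrid(out, ph.spacing, ph.origin)
        if frame == "room":
            dose = _shift_grid(dose, disp)
        elif frame != "patient":
            raise ValueError("frame must be 'patient' or 'room'")
        return dose


def _shift_grid(dose: DoseGrid, displacement_mm: np.ndarray) -> DoseGrid:
    """Express a patient-frame dose on the room grid with the patient
    displaced by ``displacement_mm`` (trilinear; exact for integer-voxel
    shifts)."""
    d = np.asarray(displacement_mm, dtype=float)
    if not d.any():
        return dose.copy()
    shifted = ndimage.shift(
        dose.values, d / dose.spacing, order=1, mode="constant", cval=0.0
    )
    return DoseGrid(shifted, dose.spacing, dose.origin)


def spot_dose(
    spot_xy_mu: tuple[float, float, float],
    energy_mev: float,
    beam_direction: np.ndarray,
    phantom: Phantom,
    scenario: Scenario = NOMINAL,
    kernel: SpotKernel | None = None,
    motion: MotionModel | None = None,
    isocenter_mm=(0.0, 0.0, 0.0),
    engine: DoseEngine | None = None,
) -> DoseGrid:
    """Exact single-spot dose (no fluence rasterization); one fraction."""
    x, y, mu = spot_xy_mu
    if mu < 0:
        raise ValueError("spot MU must be non-negative")
    kernel = kernel or SpotKernel()
    if not np.all(np.isfinite([x, y, mu, energy_mev])):
        raise ValueError("spot parameters must be finite")
    eng = engine or DoseEngine(phantom, kernel)
    geo = eng.beam_geometry(np.asarray(beam_direction, float), np.asarray(isocenter_mm, float))
    disp = scenario.shift + phase_displacement(motion, scenario.phase)
    du, dv = float(disp @ geo["eu"]), float(disp @ geo["ev"])
    r = float(bragg_range_mm(energy_mev)) * scenario.range_scale
    sig = kernel.sigma_lateral_mm
    lat2 = (geo["u"] + du - x) ** 2 + (geo["v"] + dv - y) ** 2
    gauss = np.exp(-lat2 / (2.0 * sig**2)) / (2.0 * np.pi * sig**2)
    vals = mu * kernel.gy_mm2_per_mu * gauss * kernel.depth_dose(geo["z"], r)
    return DoseGrid(vals, phantom.spacing, phantom.origin)


def compute_dose(
    plan,
    phantom: Phantom,
    scenario: Scenario = NOMINAL,
    kernel: SpotKernel | None = None,
    motion: MotionModel | None = None,
    **kw,
) -> DoseGrid:
    """Convenience wrapper constructing a one-shot :class:`DoseEngine`."""
    return DoseEngine(phantom, kernel).compute_dose(
        plan, scenario=scenario, motion=motion, **kw
    )


def normalize_to_ctvlow_d95(
    dose: DoseGrid, phantom: Phantom, prescription_gy: float = 45.0
) -> tuple[DoseGrid, float]:
    """Scale so the CTV_low D95% equals the prescription; returns (dose, s).

    The same factor ``s`` must be applied to every perturbed-scenario, phase
    and dynamic dose of the same plan.
    """
    from .dvh import dose_at_volume

    vals = dose.values[phantom.mask("ctv_low")]
    d95 = dose_at_volume(vals, 95.0)
    if d95 <= 0:
        raise NormalizationError("nominal CTV_low D95% is zero; cannot normalize")
    s = prescription_gy / d95
    return dose * s, s
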