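"""Spot-plan generation: energy-layer selection, lateral spot placement, and
single-field-optimization (SFO) style weight fitting.

Each posterior field is optimized independently to deliver an equal share of
the simultaneously-integrated-boost prescription (50 Gy[RBE] to CTV_high,
45 Gy[RBE] to CTV_low in 25 fractions) uniformly across the OTV, by
non-negative least squares on a sampled set of target voxels.  The plan is
then normalized so the nominal (averaged-geometry) CTV_low D95% equals the
prescription, and post-processed to the machine's deliverable MU resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .grids import beam_direction, beam_frame
from .machine import MACHINE_ENERGIES_MEV, bragg_range_mm
from .phantom import Phantom, MotionModel
from .dose import DoseEngine, Scenario, SpotKernel, phase_displacement

log = logging.getLogger(__name__)


class PlanningError(RuntimeError):
    pass


class InfeasiblePlanError(PlanningError):
    pass


@dataclass
class Beam:
    gantry_deg: float
    couch_deg: float

    @property
    def direction(self) -> np.ndarray:
        return beam_direction(self.gantry_deg, self.couch_deg)


@dataclass(frozen=True)
class BeamConfig:
    """A named beam-angle configuration.

    The S-I group uses two posterior oblique beams rotated into the sagittal
    plane (couch 270), entering superior-posteriorly and inferior-
    posteriorly; the R-L group uses the same gantry obliques in the
    transverse plane.  The R-L group may add up to two anterior supplements.
    """

    group_label: str
    beams: tuple[Beam, ...]
    n_anterior_supplements: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in ("S-I", "R-L"):
            raise ValueError("group_label must be 'S-I' or 'R-L'")
        n_post = len(self.beams) - self.n_anterior_supplements
        if n_post != 2:
            raise ValueError("exactly two posterior oblique beams are required")
        if self.n_anterior_supplements and self.group_label != "R-L":
            raise ValueError("anterior supplements only exist in the R-L group")
        if not 0 <= self.n_anterior_supplements <= 2:
            raise ValueError("at most two anterior supplements")


def make_beam_config(group_label: str, n_anterior_supplements: int = 0) -> BeamConfig:
    """Default beam geometry per group (gantry 155/205 posterior obliques)."""
    if group_label == "S-I":
        beams = (Beam(155.0, 270.0), Beam(205.0, 270.0))
    elif group_label == "R-L":
        beams = [Beam(155.0, 0.0), Beam(205.0, 0.0)]
        beams += [Beam((20.0, -20.0)[i], 0.0) for i in range(n_anterior_supplements)]
        beams = tuple(beams)
    else:
        raise ValueError("group_label must be 'S-I' or 'R-L'")
    return BeamConfig(group_label, beams, n_anterior_supplements)


@dataclass
class EnergyLayer:
    energy_mev: float
    spots: np.ndarray  # (n, 3): lateral x, y [mm, beam frame], MU per fraction

    def __post_init__(self) -> None:
        self.spots = np.atleast_2d(np.asarray(self.spots, dtype=float))
        if self.spots.size and self.spots.shape[1] != 3:
            raise ValueError("spots must have columns (x_mm, y_mm, mu)")
        if self.spots.size and (self.spots[:, 2] < 0).any():
            raise ValueError("spot MU must be non-negative")


@dataclass
class BeamPlan:
    gantry_deg: float
    couch_deg: float
    layers: list[EnergyLayer]

    @property
    def direction(self) -> np.ndarray:
        return beam_direction(self.gantry_deg, self.couch_deg)

    @property
    def total_mu(self) -> float:
        return float(sum(l.spots[:, 2].sum() for l in self.layers))

    @property
    def n_spots(self) -> int:
        return int(sum(l.spots.shape[0] for l in self.layers))


@dataclass
class SpotPlan:
    """Beams -> energy layers -> spots; MU values are per fraction."""

    beams: list[BeamPlan]
    isocenter_mm: np.ndarray
    prescription_gy: tuple[float, float] = (50.0, 45.0)  # (CTV_high, CTV_low)
    n_fractions: int = 25
    normalization: float = 1.0  # factor already folded into the MU values

    def __post_init__(self) -> None:
        self.isocenter_mm = np.asarray(self.isocenter_mm, dtype=float).reshape(3)

    @property
    def total_mu(self) -> float:
        return float(sum(b.total_mu for b in self.beams))

    @property
    def n_spots(self) -> int:
        return int(sum(b.n_spots for b in self.beams))

    def scale_mu(self, s: float) -> None:
        for b in self.beams:
            for l in b.layers:
                l.spots[:, 2] *= s
        self.normalization *= s

    def to_dict(self) -> dict:
        return {
            "isocenter_mm": self.isocenter_mm.tolist(),
            "prescription": list(self.prescription_gy),
            "n_fractions": self.n_fractions,
            "normalization": self.normalization,
            "beams": [
                {
                    "gantry_deg": b.gantry_deg,
                    "couch_deg": b.couch_deg,
                    "layers": [
                        {
                            "energy_MeV": l.energy_mev,
                            "spots": [
                                {"x_mm": s[0], "y_mm": s[1], "mu": s[2]}
                                for s in l.spots
                            ],
                        }
                        for l in b.layers
                    ],
                }
                for b in self.beams
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpotPlan":
        beams = [
            BeamPlan(
                b["gantry_deg"],
                b["couch_deg"],
                [
                    EnergyLayer(
                        l["energy_MeV"],
                        np.array(
                            [[s["x_mm"], s["y_mm"], s["mu"]] for s in l["spots"]]
                        ).reshape(-1, 3),
                    )
                    for l in b["layers"]
                ],
            )
            for b in d["beams"]
        ]
        return cls(
            beams=beams,
            isocenter_mm=np.asarray(d["isocenter_mm"]),
            prescription_gy=tuple(d["prescription"]),
            n_fractions=int(d["n_fractions"]),
            normalization=float(d.get("normalization", 1.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "SpotPlan":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _nnls_fista(a: np.ndarray, b: np.ndarray, n_iter: int = 600) -> np.ndarray:
    """Non-negative least squares via FISTA (projected accelerated gradient).

    Fast for the dense few-thousand-variable influence systems arising in
    per-field spot-weight fitting, where active-set solvers are impractical.
    """
    at = a.T.copy()
    # Lipschitz constant of the gradient = largest eigenvalue of A^T A.
    x = np.random.default_rng(0).random(a.shape[1])
    for _ in range(30):
        x = at @ (a @ x)
        x /= np.linalg.norm(x)
    lip = float(x @ (at @ (a @ x)))
    w = np.zeros(a.shape[1])
    y = w.copy()
    t = 1.0
    atb = at @ b
    for _ in range(n_iter):
        grad = at @ (a @ y) - atb
        w_new = np.maximum(y - grad / lip, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = w_new + (t - 1.0) / t_new * (w_new - w)
        w, t = w_new, t_new
    return w


def _structure_centroid(phantom: Phantom, name: str) -> np.ndarray:
    from .grids import voxel_centers

    cx, cy, cz = voxel_centers(phantom.empty_grid())
    m = phantom.mask(name)
    idx = np.nonzero(m)
    return np.array([cx[idx[0]].mean(), cy[idx[1]].mean(), cz[idx[2]].mean()])


def _select_layers(z_depths: np.ndarray, layer_spacing_mm: float) -> np.ndarray:
    """Machine energies whose Bragg depths tile the target depth extent."""
    zmin, zmax = float(z_depths.min()), float(z_depths.max())
    ranges = bragg_range_mm(MACHINE_ENERGIES_MEV)
    ok = (ranges >= zmin - 2.0) & (ranges <= zmax + 2.0)
    if not ok.any():
        raise PlanningError(
            f"target depth extent {zmin:.0f}-{zmax:.0f} mm is outside the "
            "machine's reachable range"
        )
    cand = np.flatnonzero(ok)
    chosen = [cand[0]]
    for i in cand[1:]:
        if ranges[i] - ranges[chosen[-1]] >= layer_spacing_mm:
            chosen.append(i)
    if chosen[-1] != cand[-1]:
        chosen.append(cand[-1])
    return MACHINE_ENERGIES_MEV[np.array(chosen)]


def generate_plan(
    phantom: Phantom,
    beam_config: BeamConfig,
    motion: MotionModel | None = None,
    kernel: SpotKernel | None = None,
    spot_spacing_mm: float = 6.5,
    layer_spacing_mm: float = 6.0,
    n_sample_voxels: int = 2200,
    n_fractions: int = 25,
    prescription_gy: tuple[float, float] = (50.0, 45.0),
    boost_weight: float = 5.0,
    oar_weights: dict | None = None,
    seed: int = 0,
    engine: DoseEngine | None = None,
    min_deliverable_mu: float | None = 0.003,
) -> SpotPlan:
    """Generate and normalize a spot plan for the phantom and beam set.

    Planning is done on the averaged breathing geometry (midway patient
    displacement), matching how plans are optimized on an averaged 4D-CT.
    """
    kernel = kernel or SpotKernel()
    eng = engine or DoseEngine(phantom, kernel)
    rng = np.random.default_rng(seed)
    iso = _structure_centroid(phantom, "otv")
    otv = phantom.mask("otv")
    ctv_high = phantom.mask("ctv_high")
    scen = Scenario(phase="averaged")
    disp = phase_displacement(motion, "averaged")

    n_fields = len(beam_config.beams)
    beam_plans: list[BeamPlan] = []
    for beam in beam_config.beams:
        geo = eng.beam_geometry(beam.direction, iso)
        du, dv = float(disp @ geo["eu"]), float(disp @ geo["ev"])
        u_t = geo["u"][otv] + du
        v_t = geo["v"][otv] + dv
        z_t = geo["z"][otv]
        if not (z_t >= 0).any():
            raise PlanningError("beam does not intersect the OTV through the body")
        energies = _select_layers(z_t, layer_spacing_mm)
        ranges = bragg_range_mm(energies)
        # Half-gap per layer for assigning target voxels by depth.
        gaps = np.diff(ranges)
        lo = ranges - np.concatenate([[layer_spacing_mm], gaps]) / 2.0
        hi = ranges + np.concatenate([gaps, [layer_spacing_mm]]) / 2.0

        layers = []
        for e, l, h in zip(energies, lo, hi):
            sel = (z_t >= l) & (z_t < h)
            if not sel.any():
                continue
            iu = np.round(u_t[sel] / spot_spacing_mm).astype(int)
            iv = np.round(v_t[sel] / spot_spacing_mm).astype(int)
            cells = set(zip(iu.tolist(), iv.tolist()))
            # One-spacing margin ring: guarantees spots outside the OTV edge
            # so the dose inside stays uniform up to the boundary.
            ring = set()
            for ci, cj in cells:
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ring.add((ci + di, cj + dj))
            pos = np.array(sorted(ring), dtype=float) * spot_spacing_mm
            spots = np.column_stack([pos, np.zeros(len(pos))])
            layers.append(EnergyLayer(e, spots))
        if not layers:
            raise PlanningError("no energy layers cover the target for this beam")
        beam_plans.append(BeamPlan(beam.gantry_deg, beam.couch_deg, layers))

    # --- SFO weight fitting, one NNLS per field ---------------------------
    otv_idx = np.flatnonzero(otv.ravel())
    if otv_idx.size > n_sample_voxels:
        otv_idx = rng.choice(otv_idx, size=n_sample_voxels, replace=False)
    # Boost objective on the boost OTV (CTV_high + margin) where available.
    boost = phantom.structures.get("otv_high", ctv_high)
    high_flat = boost.ravel()[otv_idx]
    target = np.where(high_flat, prescription_gy[0], prescription_gy[1]) / n_fields
    # Boost-coverage priority: weight boost voxels harder in the objective.
    row_w = np.sqrt(np.where(high_flat, boost_weight, 1.0))

    # OAR-sparing terms (zero-dose objectives), mirroring how single-field
    # optimization trades entrance-channel dose against the dose-volume
    # constraints; the spinal cord is the binding constraint for posterior
    # oblique beams.
    if oar_weights is None:
        oar_weights = {"spinal_cord": 0.1}
    oar_idx, oar_w = [], []
    for name, wgt in oar_weights.items():
        idx = np.flatnonzero(phantom.mask(name).ravel())
        if idx.size > 500:
            idx = rng.choice(idx, size=500, replace=False)
        oar_idx.append(idx)
        oar_w.append(np.full(idx.size, wgt))
    oar_idx = np.concatenate(oar_idx) if oar_idx else np.array([], dtype=int)
    oar_w = np.concatenate(oar_w) if oar_w else np.array([])
    fit_idx = np.concatenate([otv_idx, oar_idx])
    target = np.concatenate([target, np.zeros(oar_idx.size)])
    row_w = np.concatenate([row_w, np.sqrt(oar_w)])

    sig = kernel.sigma_lateral_mm
    norm2d = 1.0 / (2.0 * np.pi * sig**2)
    for bp in beam_plans:
        geo = eng.beam_geometry(bp.direction, iso)
        du, dv = float(disp @ geo["eu"]), float(disp @ geo["ev"])
        up = geo["u"].ravel()[fit_idx] + du
        vp = geo["v"].ravel()[fit_idx] + dv
        zp = geo["z"].ravel()[fit_idx]
        cols = []
        for layer in bp.layers:
            r = float(bragg_range_mm(layer.energy_mev))
            ld = kernel.depth_dose(zp, r)
            dx = up[:, None] - layer.spots[None, :, 0]
            dy = vp[:, None] - layer.spots[None, :, 1]
            g = np.exp(-(dx**2 + dy**2) / (2.0 * sig**2)) * norm2d
            cols.append(g * ld[:, None])
        a = np.concatenate(cols, axis=1) * kernel.gy_mm2_per_mu
        w = _nnls_fista(a * row_w[:, None], target * row_w)
        achieved = a @ w
        if np.median(achieved) < 0.9 * np.median(target):
            raise InfeasiblePlanError(
                "field weights reach below 90% of the per-field prescription"
            )
        # Scatter weights back into the layers (per-fraction MU).
        k = 0
        for layer in bp.layers:
            n = layer.spots.shape[0]
            layer.spots[:, 2] = w[k : k + n] / n_fractions
            k += n

    plan = SpotPlan(
        beams=beam_plans,
        isocenter_mm=iso,
        prescription_gy=prescription_gy,
        n_fractions=n_fractions,
    )

    # --- normalization on the nominal averaged geometry -------------------
    from .dvh import dose_at_volume

    dose = eng.compute_dose(plan, Scenario(phase="averaged"), motion=motion)
    vals = dose.values[phantom.mask("ctv_low")]
    d95 = dose_at_volume(vals, 95.0)
    if d95 <= 0:
        raise InfeasiblePlanError("CTV_low D95% is zero before normalization")
    plan.scale_mu(prescription_gy[1] / d95)

    # --- deliverable MU post-processing -----------------------------------
    if min_deliverable_mu is not None:
        dropped = 0.0
        for bp in plan.beams:
            kept = []
            for layer in bp.layers:
                mu = layer.spots[:, 2]
                low = mu < min_deliverable_mu
                roundable = low & (mu > min_deliverable_mu / 2.0)
                dropped += mu[low & ~roundable].sum()
                layer.spots[roundable, 2] = min_deliverable_mu
                layer.spots = layer.spots[mu > min_deliverable_mu / 2.0]
                if layer.spots.shape[0]:
                    kept.append(layer)
            bp.layers = kept
        if dropped:
            log.info("plan post-processing dropped %.4f MU of sub-minimum spots", dropped)
        # Renormalize: rounding perturbs D95 slightly.
        dose = eng.compute_dose(plan, Scenario(phase="averaged"), motion=motion)
        vals = dose.values[phantom.mask("ctv_low")]
        plan.scale_mu(prescription_gy[1] / dose_at_volume(vals, 95.0))
        dose = eng.compute_dose(plan, Scenario(phase="averaged"), motion=motion)

    d95_high = dose_at_volume(dose.values[ctv_high], 95.0)
    if d95_high < 0.98 * prescription_gy[0]:
        log.warning(
            "CTV_high D95%% = %.2f Gy is below 98%% of the boost prescription",
            d95_high,
        )
    return plan
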