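"""4D dynamic dose: interplay between spot delivery and breathing motion.

Each delivered spot piece of each field and fraction is assigned to a
breathing phase (two equally weighted extreme phases: exhale = reference,
inhale) by the phase active at its delivery midpoint under a square-
occupancy breathing trace whose starting phase is randomized per field per
fraction.  Per-phase doses are computed on the phase geometry and the
inhale dose is mapped onto the reference (exhale) grid by the inverse of
the (rigid, exactly invertible) exhale-to-inhale displacement, then summed
over fractions.

Because dose is linear in MU and the phase geometries repeat every
fraction, the accumulation sums each spot's delivered MU by assigned phase
across all fractions first and then performs a single dose computation per
phase — numerically identical to accumulating fraction by fraction.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from .delivery import DeliveryTimeline, sequence_delivery
from .dose import DoseEngine, DoseGrid, Scenario, _shift_grid
from .machine import RepaintRules, TimingParams
from .phantom import MotionModel, Phantom

log = logging.getLogger(__name__)

PHASE_LABELS = ("exhale", "inhale")


@dataclass(frozen=True)
class BreathingTrace:
    """Square-occupancy two-phase breathing trace.

    The cycle fraction at time t is ``frac(t / period + start_phase)``;
    exhale occupies [0, 0.5) and inhale [0.5, 1), so both extreme phases
    are equally weighted.
    """

    period_s: float
    start_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("breathing period must be positive")
        if not 0 <= self.start_phase < 1:
            raise ValueError("start_phase must lie in [0, 1)")

    def cycle_fraction(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return (t / self.period_s + self.start_phase) % 1.0

    def phase_at_time(self, t):
        """'exhale' or 'inhale' (vectorized -> boolean inhale array)."""
        frac = self.cycle_fraction(t)
        inhale = frac >= 0.5
        if np.ndim(t) == 0:
            return "inhale" if inhale else "exhale"
        return inhale


def phase_at_time(t, trace: BreathingTrace):
    return trace.phase_at_time(t)


def map_to_reference(
    dose_on_phase: DoseGrid,
    displacement_mm,
    phase: str = "inhale",
    warn_lost_fraction: float = 1e-3,
) -> DoseGrid:
    """Resample a phase dose onto the reference (exhale) grid.

    ``displacement_mm`` is the rigid exhale-to-inhale patient displacement;
    the inverse mapping shifts the inhale dose by its negation (trilinear,
    exact for integer-voxel shifts).  Exhale doses pass through unchanged.
    Dose carried outside the grid is clipped; the lost mass fraction is
    logged.
    """
    d = np.asarray(displacement_mm, dtype=float)
    if phase == "exhale" or not d.any():
        return dose_on_phase.copy()
    if phase != "inhale":
        raise ValueError("phase must be 'exhale' or 'inhale'")
    mapped = _shift_grid(dose_on_phase, -d)
    before = dose_on_phase.values.sum()
    if before > 0:
        lost = 1.0 - mapped.values.sum() / before
        if lost > warn_lost_fraction:
            log.warning("map_to_reference clipped %.3e of the dose mass", lost)
    return mapped


def field_start_phase(seed: int, case_index: int, fraction: int, field_index: int) -> float:
    """Uniform start phase, reproducible from (seed, case, fraction, field).

    Counter-based: an independent generator is derived per key, so draws
    never depend on global state or evaluation order.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(case_index, fraction, field_index))
    return float(np.random.default_rng(ss).random())


@dataclass
class InterplayResult:
    """Dynamic dose on the reference phase plus delivery diagnostics."""

    dose: DoseGrid
    timeline: DeliveryTimeline
    start_phases: np.ndarray  # (n_fractions, n_fields)
    mu_by_phase: dict  # label -> total delivered MU over all fractions

    @property
    def inhale_mu_fraction(self) -> float:
        tot = sum(self.mu_by_phase.values())
        return self.mu_by_phase["inhale"] / tot if tot else 0.0


def accumulate_dynamic_dose(
    plan,
    phantom: Phantom,
    motion: MotionModel,
    rules: RepaintRules | None = None,
    timing: TimingParams | None = None,
    n_fractions: int | None = None,
    seed: int = 0,
    case_index: int = 0,
    engine: DoseEngine | None = None,
    scenario: Scenario | None = None,
    roi_mask: np.ndarray | None = None,
) -> InterplayResult:
    """4D dynamic dose of the full treatment course on the reference phase."""
    rules = rules or RepaintRules()
    timing = timing or TimingParams()
    eng = engine or DoseEngine(phantom)
    n_fractions = n_fractions or plan.n_fractions
    base = scenario or Scenario()
    amp = motion.scalar_amplitude_mm

    if roi_mask is not None and amp > 0:
        # The room->reference shift pulls dose across the ROI boundary, so
        # evaluate on an ROI dilated by the displacement.
        from scipy import ndimage

        it = int(np.ceil(amp / float(phantom.spacing.min()))) + 1
        roi_mask = ndimage.binary_dilation(roi_mask, iterations=it)

    timeline = sequence_delivery(plan, rules, timing, amp)
    n_fields = len(plan.beams)
    n_spots_per_field = [b.n_spots for b in plan.beams]

    # Accumulate each original spot's delivered MU by assigned phase across
    # all fractions (midpoint-time phase assignment).
    mu_phase = {
        lab: [np.zeros(n) for n in n_spots_per_field] for lab in PHASE_LABELS
    }
    start_phases = np.zeros((n_fractions, n_fields))
    for fi in range(n_fields):
        f = timeline.field_frame(fi)
        t_mid = 0.5 * (f.t_start_s.values + f.t_end_s.values)
        spot_idx = f.spot.values
        mu = f.mu.values
        for k in range(n_fractions):
            phi = field_start_phase(seed, case_index, k, fi)
            start_phases[k, fi] = phi
            inhale = BreathingTrace(motion.period_s, phi).phase_at_time(t_mid)
            np.add.at(mu_phase["inhale"][fi], spot_idx[inhale], mu[inhale])
            np.add.at(mu_phase["exhale"][fi], spot_idx[~inhale], mu[~inhale])

    # One dose computation per phase with the accumulated MU totals.
    total = None
    mu_totals = {}
    for lab in PHASE_LABELS:
        phase_plan = copy.deepcopy(plan)
        for fi, bp in enumerate(phase_plan.beams):
            k = 0
            for layer in bp.layers:
                n = layer.spots.shape[0]
                layer.spots[:, 2] = mu_phase[lab][fi][k : k + n]
                k += n
        mu_totals[lab] = float(sum(m.sum() for m in mu_phase[lab]))
        if mu_totals[lab] == 0.0:
            continue
        sc = Scenario(base.setup_shift_mm, base.range_scale, lab)
        dose = eng.compute_dose(
            phase_plan,
            sc,
            motion=motion,
            total_course=False,
            frame="room",
            roi_mask=roi_mask,
        )
        dose = map_to_reference(dose, motion.amplitude_mm, phase=lab)
        total = dose if total is None else total + dose
    if total is None:
        total = phantom.empty_grid()
    return InterplayResult(
        dose=total,
        timeline=timeline,
        start_phases=start_phases,
        mu_by_phase=mu_totals,
    )
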