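"""Matched two-group synthetic patient cohorts.

Each pair shares sampled target volumes (within 15% relative) and an
identical respiratory motion amplitude; one member is planned with the S-I
oblique posterior beams and the other with the R-L oblique posterior beams,
mirroring a volume- and motion-matched two-arm comparison of 10 patients
per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dose import DoseEngine, SpotKernel
from .phantom import (
    MotionModel,
    Phantom,
    PhantomConfig,
    build_phantom,
    make_motion_model,
)
from .planning import BeamConfig, SpotPlan, generate_plan, make_beam_config


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for the matched cohort (volumes cm^3, amplitude cm)."""

    ctv_high_cm3: tuple[float, float] = (132.0, 339.0)
    ctv_low_cm3: tuple[float, float] = (243.0, 733.0)
    amplitude_cm: tuple[float, float] = (0.5, 1.0)
    pair_volume_jitter: float = 0.10  # relative CTV-volume offset within a pair

    def __post_init__(self) -> None:
        for name in ("ctv_high_cm3", "ctv_low_cm3", "amplitude_cm"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise CohortConfigError(f"empty sampling range for {name}")


@dataclass
class PatientCase:
    """One synthetic patient: anatomy, motion, beam set and (optionally) plan."""

    id: str
    phantom: Phantom
    motion: MotionModel
    beam_config: BeamConfig
    plan: SpotPlan | None
    rng_seed: int


def _log_uniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_matched_cohort(
    n_pairs: int = 10,
    seed: int = 7,
    ranges: CohortRanges = CohortRanges(),
    phantom_config: PhantomConfig = PhantomConfig(),
    kernel: SpotKernel | None = None,
    with_plans: bool = True,
    **plan_kwargs,
) -> list[tuple[PatientCase, PatientCase]]:
    """Generate ``n_pairs`` matched (S-I, R-L) patient pairs.

    Target volumes are sampled log-uniformly within the configured ranges
    (matching the right-skewed spread of clinical target volumes); the R-L
    member's volumes are jittered by at most ±``pair_volume_jitter``
    relative so pairs are matched but not identical.  Pure function of
    ``(arguments, seed)``.
    """
    if n_pairs < 1:
        raise CohortConfigError("n_pairs must be at least 1")
    root = np.random.SeedSequence(seed)
    pairs = []
    for p, pair_ss in enumerate(root.spawn(n_pairs)):
        rng = np.random.default_rng(pair_ss)
        v_high = _log_uniform(rng, *ranges.ctv_high_cm3)
        lo_low = max(1.3 * v_high, ranges.ctv_low_cm3[0])
        v_low = _log_uniform(rng, lo_low, max(ranges.ctv_low_cm3[1], 1.01 * lo_low))
        amp = rng.uniform(*ranges.amplitude_cm)
        jit = rng.uniform(-ranges.pair_volume_jitter, ranges.pair_volume_jitter)
        members = []
        for g, group in enumerate(("S-I", "R-L")):
            f = 1.0 + (jit if g == 1 else 0.0)
            cfg = replace(
                phantom_config, ctv_high_cm3=v_high * f, ctv_low_cm3=v_low * f
            )
            case_seed = int(rng.integers(0, 2**31 - 1))
            phantom = build_phantom(cfg, seed=case_seed)
            motion = make_motion_model(amp)
            bc = make_beam_config(group)
            plan = None
            if with_plans:
                plan = generate_plan(
                    phantom,
                    bc,
                    motion=motion,
                    kernel=kernel,
                    seed=case_seed,
                    **plan_kwargs,
                )
            members.append(
                PatientCase(
                    id=f"P{p + 1:02d}-{group}",
                    phantom=phantom,
                    motion=motion,
                    beam_config=bc,
                    plan=plan,
                    rng_seed=case_seed,
                )
            )
        pairs.append(tuple(members))
    return pairs
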