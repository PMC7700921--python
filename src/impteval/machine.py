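"""Synchrotron machine model: energy list, timing constants, MU limits.

The delivery timing constants describe a Hitachi-style spot-scanning
synchrotron: slow extraction spills of fixed charge, multi-energy
extraction (several energy layers delivered within one spill), dead time
for scanning-magnet preparation between spots, and a fixed spot dose rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# 97 discrete energy layers spanning the machine's deliverable range in MeV.
# The true per-layer energies are machine-specific; a uniform grid over the
# published endpoints is used as the synthetic stand-in.
N_ENERGY_LAYERS = 97
ENERGY_MIN_MEV = 71.3
ENERGY_MAX_MEV = 228.8
MACHINE_ENERGIES_MEV = np.linspace(ENERGY_MIN_MEV, ENERGY_MAX_MEV, N_ENERGY_LAYERS)

# Bragg-Kleeman power law R[cm] = alpha * E[MeV]^p in water.
BRAGG_KLEEMAN_ALPHA_CM = 0.0022
BRAGG_KLEEMAN_P = 1.77


def bragg_range_mm(energy_mev) -> np.ndarray:
    """Proton range in water (mm) from the Bragg-Kleeman power law."""
    e = np.asarray(energy_mev, dtype=float)
    return 10.0 * BRAGG_KLEEMAN_ALPHA_CM * e**BRAGG_KLEEMAN_P


def energy_for_range_mm(range_mm) -> np.ndarray:
    """Inverse of :func:`bragg_range_mm`."""
    r = np.asarray(range_mm, dtype=float)
    return (r / (10.0 * BRAGG_KLEEMAN_ALPHA_CM)) ** (1.0 / BRAGG_KLEEMAN_P)


@dataclass(frozen=True)
class TimingParams:
    """Delivery timing constants (defaults are the machine's measured averages).

    accel_s            proton acceleration/deceleration, charged per new spill
    energy_switch_s    energy-layer switch within a spill
    magnet_prep_ms     scanning-magnet preparation and verification per spot
    extraction_spill_s beam-on budget of one extraction spill
    extraction_setup_s extraction setup when a new spill starts
    spot_interval_ms   dead-time interval between consecutive spots
    dose_rate_mu_per_s spot dose delivery rate
    extraction_mode    "MEE": several energy layers may share one spill;
                       "SEE": every layer forces a new spill
    """

    accel_s: float = 1.0
    energy_switch_s: float = 1.91
    magnet_prep_ms: float = 1.93
    extraction_spill_s: float = 7.9
    extraction_setup_s: float = 0.1
    spot_interval_ms: float = 3.0
    dose_rate_mu_per_s: float = 8.7
    extraction_mode: str = "MEE"

    def __post_init__(self) -> None:
        for name in (
            "accel_s",
            "energy_switch_s",
            "magnet_prep_ms",
            "extraction_spill_s",
            "extraction_setup_s",
            "spot_interval_ms",
            "dose_rate_mu_per_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.extraction_mode not in ("MEE", "SEE"):
            raise ValueError("extraction_mode must be 'MEE' or 'SEE'")

    @property
    def interspot_dead_s(self) -> float:
        """Dead time between consecutive spots in a layer."""
        return (self.magnet_prep_ms + self.spot_interval_ms) / 1000.0


@dataclass(frozen=True)
class RepaintRules:
    """Iso-layer repainting MU limits.

    Spots above the applicable maximum MU are split into full repaints at the
    maximum plus one residual; the maximum is tightened when the respiratory
    motion amplitude exceeds ``motion_threshold_mm`` to force more repainting.
    """

    min_mu: float = 0.003
    max_mu_small_motion: float = 0.04
    max_mu_large_motion: float = 0.01
    motion_threshold_mm: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.min_mu:
            raise ValueError("min_mu must be positive")
        if self.min_mu >= min(self.max_mu_small_motion, self.max_mu_large_motion):
            raise ValueError("min_mu must be smaller than both maximum MU limits")
        if self.motion_threshold_mm <= 0:
            raise ValueError("motion_threshold_mm must be positive")

    def max_mu(self, motion_amplitude_mm: float) -> float:
        if motion_amplitude_mm <= self.motion_threshold_mm:
            return self.max_mu_small_motion
        return self.max_mu_large_motion
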