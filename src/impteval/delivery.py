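"""Spot-delivery sequencing with iso-layer repainting and machine timing.

Repainting splits every spot above the applicable maximum MU into full
repaints at the maximum plus one residual; residuals below the minimum MU
are rounded up to the minimum when larger than half of it and dropped
otherwise.  Each energy layer is then delivered in passes (pass j delivers
the j-th piece of every spot that has one, in serpentine scan order), so
the repaints of one spot are spread in time across the layer — the
mechanism by which repainting averages over breathing phases.

Timing: within a layer consecutive spots are separated by the scanning-
magnet preparation plus the inter-spot interval; layers within a spill are
separated by the energy-switch time (multi-energy extraction); only beam-on
time consumes the spill's extraction budget, and a new spill costs the
extraction setup plus acceleration time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .machine import RepaintRules, TimingParams


def repaint_spot(
    mu: float, rules: RepaintRules, motion_amplitude_mm: float
) -> np.ndarray:
    """Delivered MU pieces for one planned spot (possibly empty).

    Contract: with M the applicable maximum, emit floor(mu/M) full pieces of
    M plus one residual r = mu - floor(mu/M)*M; a piece in [min_mu, M] is
    delivered as-is, a residual in (min_mu/2, min_mu) is rounded up to
    min_mu, and a residual <= min_mu/2 is dropped (strictly "larger than
    half" survives).
    """
    if mu < 0:
        raise ValueError("spot MU must be non-negative")
    m = rules.max_mu(motion_amplitude_mm)
    # Tolerant floor: an MU exactly at a multiple of M yields no residual.
    k = int(np.floor(mu / m + 1e-9))
    r = mu - k * m
    pieces = [m] * k
    if r >= rules.min_mu - 1e-12:
        pieces.append(r)
    elif r > rules.min_mu / 2.0 + 1e-15:
        pieces.append(rules.min_mu)
    return np.asarray(pieces, dtype=float)


@dataclass
class FieldLedger:
    """Per-field MU bookkeeping of the repainting pass."""

    planned_mu: float = 0.0
    delivered_mu: float = 0.0
    n_rounded_up: int = 0
    rounded_added_mu: float = 0.0
    n_dropped: int = 0
    dropped_mu: float = 0.0

    @property
    def conservation_bound(self) -> float:
        """|delivered - planned| can never exceed this."""
        return self.rounded_added_mu + self.dropped_mu


@dataclass
class DeliveryTimeline:
    """Post-repainting spot sequence with absolute timestamps, one fraction.

    ``spots`` holds one row per delivered piece with columns: field, layer,
    energy_mev, spot (index of the originating planned spot within its
    field), x_mm, y_mm, mu, t_start_s, t_end_s, spill.  Each field's clock
    starts at zero.
    """

    spots: pd.DataFrame
    ledgers: list[FieldLedger]
    rules: RepaintRules
    timing: TimingParams

    @property
    def total_mu(self) -> float:
        return float(self.spots.mu.sum())

    def field_frame(self, field_index: int) -> pd.DataFrame:
        return self.spots[self.spots.field == field_index]


def _serpentine_order(spots: np.ndarray, row_pitch_mm: float) -> np.ndarray:
    """Scan order: rows of increasing y, alternating x direction per row."""
    y = np.round(spots[:, 1] / row_pitch_mm).astype(int)
    x = spots[:, 0]
    sign = np.where(y % 2 == 0, 1.0, -1.0)
    return np.lexsort((sign * x, y))


def sequence_delivery(
    plan,
    rules: RepaintRules,
    timing: TimingParams,
    motion_amplitude_mm: float,
    row_pitch_mm: float = 6.5,
) -> DeliveryTimeline:
    """Timestamped delivery sequence of one fraction of the plan."""
    rows = []
    ledgers = []
    rate = timing.dose_rate_mu_per_s
    dead = timing.interspot_dead_s
    for fi, beam in enumerate(plan.beams):
        ledger = FieldLedger()
        t = timing.accel_s  # first spill acceleration
        spill = 0
        spill_beam_on = 0.0
        first_in_field = True
        # Layers delivered from highest to lowest energy.
        layers = sorted(
            enumerate(beam.layers), key=lambda il: -il[1].energy_mev
        )
        spot_base = 0
        base_of_layer = {}
        for li, layer in enumerate(beam.layers):
            base_of_layer[li] = spot_base
            spot_base += layer.spots.shape[0]
        for li, layer in layers:
            if not first_in_field:
                t += timing.energy_switch_s
                if timing.extraction_mode == "SEE":
                    t += timing.extraction_setup_s + timing.accel_s
                    spill += 1
                    spill_beam_on = 0.0
            pieces_per_spot = []
            for x, y, mu in layer.spots:
                ledger.planned_mu += mu
                p = repaint_spot(mu, rules, motion_amplitude_mm)
                diff = p.sum() - mu
                if diff > 1e-12:
                    ledger.n_rounded_up += 1
                    ledger.rounded_added_mu += diff
                elif diff < -1e-12:
                    ledger.n_dropped += 1
                    ledger.dropped_mu += -diff
                pieces_per_spot.append(p)
            order = _serpentine_order(layer.spots, row_pitch_mm)
            n_pass = max((p.size for p in pieces_per_spot), default=0)
            first_in_layer = True
            for j in range(n_pass):
                for si in order:
                    p = pieces_per_spot[si]
                    if j >= p.size:
                        continue
                    mu_piece = float(p[j])
                    if not first_in_layer:
                        t += dead
                    beam_on = mu_piece / rate
                    if spill_beam_on + beam_on > timing.extraction_spill_s + 1e-12:
                        t += timing.extraction_setup_s + timing.accel_s
                        spill += 1
                        spill_beam_on = 0.0
                    rows.append(
                        (
                            fi,
                            li,
                            layer.energy_mev,
                            base_of_layer[li] + si,
                            layer.spots[si, 0],
                            layer.spots[si, 1],
                            mu_piece,
                            t,
                            t + beam_on,
                            spill,
                        )
                    )
                    ledger.delivered_mu += mu_piece
                    t += beam_on
                    spill_beam_on += beam_on
                    first_in_layer = False
                    first_in_field = False
            if n_pass:
                first_in_field = False
        ledgers.append(ledger)
    df = pd.DataFrame(
        rows,
        columns=[
            "field",
            "layer",
            "energy_mev",
            "spot",
            "x_mm",
            "y_mm",
            "mu",
            "t_start_s",
            "t_end_s",
            "spill",
        ],
    )
    return DeliveryTimeline(df, ledgers, rules, timing)
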