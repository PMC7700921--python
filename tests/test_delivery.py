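"""Iso-layer repainting contract and delivery-timeline timing model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impteval.delivery import repaint_spot, sequence_delivery
from impteval.machine import RepaintRules, TimingParams
from impteval.planning import BeamPlan, EnergyLayer, SpotPlan

RULES = RepaintRules()


def brute_force_repaint(mu, min_mu, max_mu):
    """Independent re-derivation of the split/round/drop contract."""
    pieces = []
    remaining = mu
    while remaining > max_mu + 1e-12 or abs(remaining - max_mu) < 1e-12:
        # subtract full repaints; exact multiples leave no residual
        if remaining < max_mu + 1e-12 and remaining > max_mu - 1e-12:
            pieces.append(max_mu)
            remaining = 0.0
            break
        pieces.append(max_mu)
        remaining -= max_mu
    if remaining > 1e-15:
        if remaining >= min_mu - 1e-12:
            pieces.append(remaining)
        elif remaining > min_mu / 2.0:
            pieces.append(min_mu)
        # else dropped
    return pieces


@pytest.mark.parametrize(
    "mu,amplitude,expected",
    [
        (0.095, 4.0, [0.04, 0.04, 0.015]),
        (0.002, 4.0, [0.003]),
        (0.001, 4.0, []),
        (0.0015, 4.0, []),  # exactly half the minimum is dropped
        (0.04, 4.0, [0.04]),
        (0.08, 4.0, [0.04, 0.04]),
        (0.095, 6.0, [0.01] * 9 + [0.005]),
        (0.0, 4.0, []),
    ],
)
def test_repaint_worked_examples(mu, amplitude, expected):
    np.testing.assert_allclose(repaint_spot(mu, RULES, amplitude), expected, atol=1e-12)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    mu=st.floats(min_value=0.0, max_value=1.0),
    large_motion=st.booleans(),
)
def test_repaint_contract_matches_brute_force(mu, large_motion):
    amp = 8.0 if large_motion else 3.0
    m = RULES.max_mu(amp)
    got = repaint_spot(mu, RULES, amp)
    expected = brute_force_repaint(mu, RULES.min_mu, m)
    np.testing.assert_allclose(got, expected, atol=1e-9)
    # every delivered piece is within the machine limits
    assert all(RULES.min_mu - 1e-12 <= p <= m + 1e-12 for p in got)
    # conservation: |delivered - planned| bounded by round-up or drop size
    assert abs(got.sum() - mu) <= max(RULES.min_mu, m * 1e-9) + 1e-12


def test_smaller_max_mu_never_reduces_piece_count(rng):
    mus = rng.uniform(0, 0.5, size=200)
    small = RepaintRules()
    for mu in mus:
        n_small = len(repaint_spot(mu, small, 3.0))  # M = 0.04
        n_large = len(repaint_spot(mu, small, 8.0))  # M = 0.01
        assert n_large >= n_small


def test_negative_mu_rejected():
    with pytest.raises(ValueError):
        repaint_spot(-0.01, RULES, 3.0)


def test_rules_validation():
    with pytest.raises(ValueError):
        RepaintRules(min_mu=0.05)  # min above max
    with pytest.raises(ValueError):
        RepaintRules(min_mu=0.0)


def _plan(layer_spots, energies=(140.0,)):
    layers = [EnergyLayer(e, np.asarray(s, dtype=float)) for e, s in zip(energies, layer_spots)]
    return SpotPlan(
        beams=[BeamPlan(180.0, 0.0, layers)], isocenter_mm=np.zeros(3), n_fractions=1
    )


def test_three_spot_layer_timing():
    """Beam-on 3 x 0.03/8.7 s with two 4.93 ms inter-spot gaps."""
    plan = _plan([[[0, 0, 0.03], [6, 0, 0.03], [12, 0, 0.03]]])
    tl = sequence_delivery(plan, RULES, TimingParams(), 4.0)
    t = tl.spots
    dur = t.t_end_s.max() - t.t_start_s.min()
    expected = 3 * 0.03 / 8.7 + 2 * (1.93 + 3.0) / 1000.0
    assert dur == pytest.approx(expected, rel=1e-9)
    assert t.t_start_s.min() == pytest.approx(TimingParams().accel_s)


def test_timeline_mu_conservation_and_monotone_times(plan_si):
    tl = sequence_delivery(plan_si, RULES, TimingParams(), 4.0)
    expected_mu = sum(
        repaint_spot(mu, RULES, 4.0).sum()
        for b in plan_si.beams
        for l in b.layers
        for mu in l.spots[:, 2]
    )
    assert tl.total_mu == pytest.approx(expected_mu, rel=1e-12)
    for fi in range(len(plan_si.beams)):
        f = tl.field_frame(fi)
        assert (np.diff(f.t_start_s.values) > 0).all()
        assert (f.t_start_s.values[1:] >= f.t_end_s.values[:-1] - 1e-12).all()
    # conservation bound from the ledgers
    for ledger in tl.ledgers:
        assert abs(ledger.delivered_mu - ledger.planned_mu) <= (
            ledger.conservation_bound + 1e-9
        )


def test_layers_delivered_high_to_low_energy(plan_si):
    tl = sequence_delivery(plan_si, RULES, TimingParams(), 4.0)
    for fi in range(len(plan_si.beams)):
        f = tl.field_frame(fi)
        first_seen = f.groupby("energy_mev").t_start_s.min().sort_index(ascending=False)
        assert first_seen.is_monotonic_increasing


def test_energy_switch_time_linearity():
    """Doubling the switch time adds (n_layers - 1) x 1.91 s per field."""
    spots = [[[0, 0, 0.02]], [[0, 0, 0.02]], [[0, 0, 0.02]]]
    plan = _plan(spots, energies=(160.0, 150.0, 140.0))
    t1 = sequence_delivery(plan, RULES, TimingParams(), 4.0).spots.t_end_s.max()
    t2 = sequence_delivery(
        plan, RULES, TimingParams(energy_switch_s=2 * 1.91), 4.0
    ).spots.t_end_s.max()
    assert t2 - t1 == pytest.approx(2 * 1.91, rel=1e-9)


def test_spill_budget_forces_new_spill():
    """Beam-on time beyond one extraction budget starts a new spill."""
    n = 300
    spots = [[[i * 5.0, 0.0, 0.3] for i in range(n)]]  # 90 MU -> > 7.9 s beam-on
    plan = _plan(spots)
    tl = sequence_delivery(plan, RULES, TimingParams(), 3.0)
    t = tl.spots
    assert t.spill.max() >= 1
    for spill, g in t.groupby("spill"):
        assert (g.t_end_s - g.t_start_s).sum() <= 7.9 + 1e-9
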