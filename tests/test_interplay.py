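"""Breathing-phase assignment, phase-to-reference mapping, and the 4D
dynamic dose accumulation oracles."""

import numpy as np
import pytest

from impteval.dose import Scenario
from impteval.grids import DoseGrid
from impteval.interplay import (
    BreathingTrace,
    accumulate_dynamic_dose,
    field_start_phase,
    map_to_reference,
    phase_at_time,
)
from impteval.machine import RepaintRules
from impteval.phantom import make_motion_model


def test_phase_at_time_quarter_and_three_quarter_cycle():
    trace = BreathingTrace(period_s=4.0, start_phase=0.0)
    assert phase_at_time(1.0, trace) == "exhale"
    assert phase_at_time(3.0, trace) == "inhale"


def test_half_cycle_start_phase_swaps_labels(rng):
    t = rng.uniform(0, 40, size=200)
    a = BreathingTrace(4.0, 0.0).phase_at_time(t)
    b = BreathingTrace(4.0, 0.5).phase_at_time(t)
    assert np.array_equal(a, ~b)


def test_phases_equally_weighted_over_cycle():
    t = np.linspace(0, 4.0, 4000, endpoint=False)
    inhale = BreathingTrace(4.0, 0.25).phase_at_time(t)
    assert inhale.mean() == pytest.approx(0.5, abs=1e-3)


def test_invalid_trace_rejected():
    with pytest.raises(ValueError):
        BreathingTrace(0.0)
    with pytest.raises(ValueError):
        BreathingTrace(4.0, 1.5)


def test_map_to_reference_identity_for_zero_displacement(phantom, engine, plan_si):
    dose = engine.compute_dose(plan_si)
    mapped = map_to_reference(dose, np.zeros(3))
    np.testing.assert_array_equal(mapped.values, dose.values)


def test_map_to_reference_integer_shift_exact(phantom):
    vals = np.zeros((20, 20, 20))
    vals[8:12, 8:12, 8:12] = 1.0
    dose = DoseGrid(vals, np.full(3, 2.5), np.zeros(3))
    mapped = map_to_reference(dose, np.array([0.0, 0.0, 2.5]))  # one voxel S-I
    np.testing.assert_allclose(mapped.values, np.roll(vals, -1, axis=2), atol=1e-12)


def test_map_to_reference_preserves_integral(phantom, engine, plan_si, motion):
    dose = engine.compute_dose(plan_si, Scenario(phase="inhale"), motion=motion, frame="room")
    mapped = map_to_reference(dose, motion.amplitude_mm)
    assert mapped.values.sum() == pytest.approx(dose.values.sum(), rel=1e-3)


def test_start_phase_reproducible_and_counter_based():
    a = field_start_phase(11, 3, 7, 1)
    assert a == field_start_phase(11, 3, 7, 1)
    assert 0.0 <= a < 1.0
    assert a != field_start_phase(11, 3, 8, 1)
    assert a != field_start_phase(12, 3, 7, 1)


def test_dynamic_dose_seeding_contract(phantom, engine, plan_si, motion):
    r1 = accumulate_dynamic_dose(plan_si, phantom, motion, seed=5, engine=engine)
    r2 = accumulate_dynamic_dose(plan_si, phantom, motion, seed=5, engine=engine)
    r3 = accumulate_dynamic_dose(plan_si, phantom, motion, seed=6, engine=engine)
    np.testing.assert_array_equal(r1.dose.values, r2.dose.values)
    assert not np.array_equal(r1.dose.values, r3.dose.values)
    np.testing.assert_array_equal(r1.start_phases, r2.start_phases)


def test_zero_motion_dynamic_equals_static(phantom, engine, plan_si):
    """With no motion the 4D dynamic dose reproduces the static exhale dose
    up to repainting MU rounding (< 0.5% of the maximum dose)."""
    still = make_motion_model(0.0)
    static = engine.compute_dose(plan_si, Scenario(phase="exhale"), motion=still)
    res = accumulate_dynamic_dose(plan_si, phantom, still, seed=5, engine=engine)
    rel = np.abs(res.dose.values - static.values).max() / static.values.max()
    assert rel < 0.005


def test_aggressive_repainting_reaches_phase_average(phantom, engine, plan_si, motion):
    """As the repaint maximum MU shrinks, the dynamic dose converges to the
    equal-weight two-phase average (CTV mean dose within 1%)."""
    rules = RepaintRules(
        min_mu=2e-4, max_mu_small_motion=0.002, max_mu_large_motion=0.002
    )
    res = accumulate_dynamic_dose(
        plan_si, phantom, motion, rules=rules, seed=5, engine=engine
    )
    ex = engine.compute_dose(plan_si, Scenario(phase="exhale"), motion=motion, frame="room")
    inh = engine.compute_dose(plan_si, Scenario(phase="inhale"), motion=motion, frame="room")
    avg = 0.5 * (ex.values + map_to_reference(inh, motion.amplitude_mm).values)
    ctv = phantom.mask("ctv_low")
    assert res.dose.values[ctv].mean() == pytest.approx(avg[ctv].mean(), rel=0.01)
    # half the MU lands in each phase
    assert res.inhale_mu_fraction == pytest.approx(0.5, abs=0.02)


def test_dynamic_target_coverage_not_better_than_nominal(phantom, engine, plan_si, motion):
    """Interplay can only degrade (or match) boost coverage relative to the
    nominal planning geometry, on average over start phases."""
    from impteval.dvh import dose_at_volume

    static = engine.compute_dose(plan_si, Scenario(phase="averaged"), motion=motion)
    d95_static = dose_at_volume(static.values[phantom.mask("ctv_high")], 95.0)
    d95_dyn = []
    for seed in (1, 2, 3):
        res = accumulate_dynamic_dose(plan_si, phantom, motion, seed=seed, engine=engine)
        d95_dyn.append(dose_at_volume(res.dose.values[phantom.mask("ctv_high")], 95.0))
    assert np.mean(d95_dyn) <= d95_static + 0.1
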