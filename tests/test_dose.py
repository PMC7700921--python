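"""Dose engine: linearity, superposition, Bragg-peak placement, scenario
semantics, normalization."""

import copy

import numpy as np
import pytest

from impteval.dose import (
    DoseEngine,
    Scenario,
    SpotKernel,
    normalize_to_ctvlow_d95,
    spot_dose,
)
from impteval.dvh import dose_at_volume
from impteval.machine import bragg_range_mm
from impteval.phantom import make_motion_model
from impteval.planning import BeamPlan, EnergyLayer, SpotPlan, make_beam_config


def _single_spot_plan(mu, energy=140.0, xy=(0.0, 0.0), gantry=155.0, couch=270.0):
    return SpotPlan(
        beams=[BeamPlan(gantry, couch, [EnergyLayer(energy, np.array([[*xy, mu]]))])],
        isocenter_mm=np.zeros(3),
        n_fractions=1,
    )


def test_zero_mu_gives_zero_dose(engine):
    dose = engine.compute_dose(_single_spot_plan(0.0))
    assert not dose.values.any()


def test_dose_linear_in_mu(engine):
    d1 = engine.compute_dose(_single_spot_plan(1.0))
    d2 = engine.compute_dose(_single_spot_plan(2.0))
    np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)


def test_superposition_over_plan_union(engine, plan_si):
    a = copy.deepcopy(plan_si)
    b = copy.deepcopy(plan_si)
    a.beams = [plan_si.beams[0]]
    b.beams = [plan_si.beams[1]]
    total = engine.compute_dose(plan_si)
    np.testing.assert_allclose(
        total.values,
        engine.compute_dose(a).values + engine.compute_dose(b).values,
        rtol=1e-10,
        atol=1e-12,
    )


@pytest.mark.parametrize("range_scale", [0.97, 1.0, 1.03])
def test_bragg_peak_voxel_at_scaled_range(phantom, engine, range_scale):
    """The depth-dose argmax along the beam lies at R*range_scale within a
    voxel diagonal."""
    direction = make_beam_config("S-I").beams[0].direction
    dose = spot_dose(
        (0.0, 0.0, 1.0), 140.0, direction, phantom,
        Scenario(range_scale=range_scale), engine=engine,
    )
    idx = np.unravel_index(np.argmax(dose.values), dose.values.shape)
    geo = engine.beam_geometry(direction, np.zeros(3))
    peak_depth = float(geo["z"][idx])
    expected = float(bragg_range_mm(140.0)) * range_scale
    assert abs(peak_depth - expected) <= float(np.linalg.norm(phantom.spacing))


def test_range_scale_moves_peak_distally(phantom, engine):
    direction = make_beam_config("S-I").beams[0].direction
    geo = engine.beam_geometry(direction, np.zeros(3))
    depths = []
    for rs in (0.94, 1.0, 1.06):
        dose = spot_dose(
            (0.0, 0.0, 1.0), 150.0, direction, phantom,
            Scenario(range_scale=rs), engine=engine,
        )
        idx = np.unravel_index(np.argmax(dose.values), dose.values.shape)
        depths.append(float(geo["z"][idx]))
    assert depths[0] < depths[1] < depths[2]


def test_patient_shift_equals_counter_shifted_spot_pattern(phantom, engine):
    """+shift of the patient == -shift of the beam-frame spot positions."""
    direction = make_beam_config("R-L").beams[0].direction
    geo = engine.beam_geometry(direction, np.zeros(3))
    shift = np.array([3.0, -2.0, 1.5])
    du, dv = float(shift @ geo["eu"]), float(shift @ geo["ev"])
    shifted_patient = spot_dose(
        (0.0, 0.0, 1.0), 150.0, direction, phantom,
        Scenario(tuple(shift)), engine=engine,
    )
    shifted_spot = spot_dose(
        (-du, -dv, 1.0), 150.0, direction, phantom, Scenario(), engine=engine
    )
    np.testing.assert_allclose(
        shifted_patient.values, shifted_spot.values, rtol=1e-6, atol=1e-12
    )


def test_gridded_fluence_matches_exact_single_spot(phantom, engine):
    """The rasterized-fluence path agrees with the exact kernel up to the
    documented rasterization broadening (a few % of the single-spot peak;
    integral-preserving, so plan-level doses are unaffected after
    normalization)."""
    plan = _single_spot_plan(1.0, energy=150.0, xy=(3.1, -2.7))
    gridded = engine.compute_dose(plan)
    exact = spot_dose(
        (3.1, -2.7, 1.0), 150.0, plan.beams[0].direction, phantom, engine=engine
    )
    peak = exact.values.max()
    assert np.abs(gridded.values - exact.values).max() < 0.06 * peak
    assert gridded.values.sum() == pytest.approx(exact.values.sum(), rel=0.03)


def test_zero_amplitude_phases_identical(engine, plan_si):
    still = make_motion_model(0.0)
    doses = [
        engine.compute_dose(plan_si, Scenario(phase=p), motion=still)
        for p in ("averaged", "exhale", "inhale")
    ]
    np.testing.assert_array_equal(doses[0].values, doses[1].values)
    np.testing.assert_array_equal(doses[1].values, doses[2].values)


def test_dose_nonnegative_and_inside_body_only(engine, plan_si, phantom):
    dose = engine.compute_dose(plan_si)
    assert (dose.values >= 0).all()
    assert dose.values[phantom.mask("ctv_low")].min() > 0


def test_normalization_sets_ctvlow_d95(engine, plan_si, phantom, motion):
    dose = engine.compute_dose(plan_si, Scenario(phase="averaged"), motion=motion)
    scaled, s = normalize_to_ctvlow_d95(dose, phantom)
    vals = scaled.values[phantom.mask("ctv_low")]
    assert dose_at_volume(vals, 95.0) == pytest.approx(45.0, abs=1e-9)
    # the generated plan is already normalized, so s is close to 1
    assert s == pytest.approx(1.0, abs=0.02)


def test_normalization_scale_is_ratio():
    from impteval.grids import DoseGrid
    from tests.conftest import SMALL_CONFIG
    from impteval.phantom import build_phantom

    ph = build_phantom(SMALL_CONFIG, seed=4)
    vals = np.zeros(ph.grid_shape)
    vals[ph.mask("ctv_low")] = 44.0
    dose = DoseGrid(vals, ph.spacing, ph.origin)
    _, s = normalize_to_ctvlow_d95(dose, ph)
    assert s == pytest.approx(45.0 / 44.0)


def test_kernel_validation():
    with pytest.raises(ValueError):
        SpotKernel(plateau_fraction=1.5)
    with pytest.raises(ValueError):
        SpotKernel(sigma_lateral_mm=-1.0)
    with pytest.raises(ValueError):
        Scenario(range_scale=0.0)
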