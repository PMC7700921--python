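"""DVH indices against a literal sort-and-threshold oracle, plus the
constraint-compliance conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impteval.dvh import (
    UndefinedIndexError,
    compute_dvh,
    constraint_report,
    dose_at_volume,
    dose_at_volume_cc,
    volume_at_dose_cc,
    volume_at_dose_pct,
)
from impteval.grids import DoseGrid


def oracle_dose_at_volume(values, pct):
    """Independent sort-and-threshold re-derivation: build the cumulative
    survival curve explicitly (the k hottest voxels occupy volume fraction
    k/n at the k-th descending dose) and invert it with np.interp."""
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    fractions = np.arange(1, v.size + 1) / v.size
    return float(np.interp(pct / 100.0, fractions, v))


def oracle_volume_at_dose(values, d):
    v = np.asarray(values, dtype=float)
    return 100.0 * np.count_nonzero(v >= d) / v.size


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=1000),
    pct=st.floats(min_value=1.0, max_value=100.0),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_dose_at_volume_matches_sort_oracle(n, pct, seed):
    values = np.random.default_rng(seed).uniform(0.0, 60.0, size=n)
    assert dose_at_volume(values, pct) == pytest.approx(
        oracle_dose_at_volume(values, pct), abs=0.05
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=1000),
    d=st.floats(min_value=0.0, max_value=60.0),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_volume_at_dose_matches_counting_oracle(n, d, seed):
    values = np.random.default_rng(seed).uniform(0.0, 60.0, size=n)
    assert volume_at_dose_pct(values, d) == pytest.approx(
        oracle_volume_at_dose(values, d), abs=0.1
    )


def test_uniform_dose_degenerate_indices():
    values = np.full(500, 50.0)
    assert dose_at_volume(values, 95.0) == 50.0
    assert dose_at_volume(values, 5.0) == 50.0
    assert volume_at_dose_pct(values, 50.0) == 100.0
    assert volume_at_dose_pct(values, 50.0001) == 0.0


def test_two_voxel_v50():
    assert volume_at_dose_pct(np.array([40.0, 60.0]), 50.0) == 50.0


def test_d2cc_four_one_cc_voxels():
    """Hottest 2 cc of {10,20,30,40} Gy voxels of 1 cc each -> 30 Gy."""
    values = np.array([10.0, 20.0, 30.0, 40.0])
    assert dose_at_volume_cc(values, 2.0, None, voxel_volume_cm3=1.0) == pytest.approx(
        30.0, abs=0.05
    )


def test_d2cc_undefined_for_small_structure():
    with pytest.raises(UndefinedIndexError):
        dose_at_volume_cc(np.array([10.0]), 2.0, None, voxel_volume_cm3=1.0)


def test_absolute_volume_at_dose():
    values = np.array([10.0, 20.0, 30.0, 40.0])
    assert volume_at_dose_cc(values, 25.0, None, voxel_volume_cm3=0.5) == 1.0


def test_dvh_curve_monotone_and_normalized(phantom, engine, plan_si):
    dose = engine.compute_dose(plan_si)
    curve = compute_dvh(dose, phantom.mask("ctv_low"))
    assert curve.volume_fraction[0] == 1.0
    assert curve.volume_fraction[-1] == 0.0
    assert (np.diff(curve.volume_fraction) <= 1e-12).all()


def test_index_order_relations(rng):
    values = rng.uniform(0, 60, size=800)
    d95 = dose_at_volume(values, 95.0)
    d5 = dose_at_volume(values, 5.0)
    assert d5 >= d95
    assert values.mean() <= values.max()
    # VxGy non-increasing in x
    vols = [volume_at_dose_pct(values, x) for x in (5, 20, 30, 45)]
    assert (np.diff(vols) <= 0).all()


def test_constraint_report_strict_inequality(phantom):
    """A value exactly at the limit fails (strict '<' convention)."""
    vals = np.zeros(phantom.grid_shape)
    vals[phantom.mask("lungs")] = 5.0  # lung V5Gy = 100% -> fail
    vals[phantom.mask("liver")] = 24.9  # liver Dmean 24.9 -> pass
    dose = DoseGrid(vals, phantom.spacing, phantom.origin)
    rep = constraint_report(dose, phantom).set_index("constraint")
    assert bool(rep.loc["liver Dmean", "passed"])
    assert not bool(rep.loc["lungs V5Gy", "passed"])


def test_constraint_report_missing_structure_not_silent(phantom):
    vals = np.zeros(phantom.grid_shape)
    dose = DoseGrid(vals, phantom.spacing, phantom.origin)
    constraints = (("esophagus_upper", "Dmean", None, 30.0, "Gy"),)
    rep = constraint_report(dose, phantom, constraints=constraints)
    assert not rep.evaluable.iloc[0]
    assert not rep.passed.iloc[0]


def test_cord_dmax_limit(phantom):
    vals = np.zeros(phantom.grid_shape)
    cord = phantom.mask("spinal_cord")
    vals[cord] = 1.0
    idx = tuple(a[0] for a in np.nonzero(cord))
    vals[idx] = 45.2
    dose = DoseGrid(vals, phantom.spacing, phantom.origin)
    rep = constraint_report(dose, phantom).set_index("constraint")
    assert not bool(rep.loc["spinal_cord Dmax", "passed"])
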