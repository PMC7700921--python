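"""The 13-scenario setup/range uncertainty set and DVH-bandwidth robustness.

The standard set holds one nominal scenario and 12 perturbed ones: six
±3 mm rigid setup shifts along R-L, A-P and S-I, two ±3% range scalings,
and four combined members pairing the shifts along the dominant-uncertainty
axis (S-I by default) with each range scaling.  A plan's robustness for a
DVH index is the bandwidth — the max-minus-min of the index across all 13
scenarios, evaluated with the nominal normalization factor held fixed.
Smaller bandwidth means better robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import DoseEngine, Scenario
from .dvh import DVHCurve, IndexSpec, compute_dvh
from .phantom import MotionModel, Phantom

N_SCENARIOS = 13


class IncompleteScenarioSetError(ValueError):
    pass


def make_scenarios(
    shift_mm: float = 3.0,
    range_pct: float = 3.0,
    phase: str = "averaged",
    combine_axis: int = 2,
) -> list[Scenario]:
    """The ordered 13-member scenario set.

    Order: nominal, ±x, ±y, ±z shifts, range down/up, then the four
    combinations of ±shift along ``combine_axis`` with each range scaling.
    """
    if shift_mm < 0 or range_pct < 0:
        raise ValueError("shift_mm and range_pct must be non-negative")
    lo, hi = 1.0 - range_pct / 100.0, 1.0 + range_pct / 100.0
    scen = [Scenario(phase=phase)]
    for axis in range(3):
        for sign in (+1.0, -1.0):
            shift = [0.0, 0.0, 0.0]
            shift[axis] = sign * shift_mm
            scen.append(Scenario(tuple(shift), 1.0, phase))
    scen.append(Scenario((0.0, 0.0, 0.0), lo, phase))
    scen.append(Scenario((0.0, 0.0, 0.0), hi, phase))
    for sign in (+1.0, -1.0):
        shift = [0.0, 0.0, 0.0]
        shift[combine_axis] = sign * shift_mm
        for rs in (lo, hi):
            scen.append(Scenario(tuple(shift), rs, phase))
    assert len(scen) == N_SCENARIOS
    return scen


@dataclass
class DVHBand:
    """Per-scenario DVH curves of one structure plus their envelope."""

    structure: str
    dose_gy: np.ndarray
    curves: np.ndarray  # (n_scenarios, n_dose) volume fractions
    nominal: np.ndarray

    @property
    def envelope_low(self) -> np.ndarray:
        return self.curves.min(axis=0)

    @property
    def envelope_high(self) -> np.ndarray:
        return self.curves.max(axis=0)


def scenario_doses(
    plan,
    phantom: Phantom,
    scenarios: list[Scenario],
    motion: MotionModel | None = None,
    engine: DoseEngine | None = None,
    roi_mask: np.ndarray | None = None,
):
    """Yield (scenario, DoseGrid) with the plan's baked-in normalization."""
    eng = engine or DoseEngine(phantom)
    for sc in scenarios:
        yield sc, eng.compute_dose(plan, sc, motion=motion, roi_mask=roi_mask)


def dvh_band(
    plan,
    phantom: Phantom,
    scenarios: list[Scenario],
    structure: str,
    motion: MotionModel | None = None,
    engine: DoseEngine | None = None,
    bin_width_gy: float = 0.05,
) -> DVHBand:
    """DVH band of one structure across the scenario set."""
    mask = phantom.mask(structure)
    per_scenario = []
    dmax = 0.0
    for _, dose in scenario_doses(
        plan, phantom, scenarios, motion=motion, engine=engine, roi_mask=mask
    ):
        vals = dose.values[mask]
        per_scenario.append(vals)
        dmax = max(dmax, float(vals.max()))
    edges = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    curves = np.stack(
        [(v[None, :] >= edges[:, None]).mean(axis=1) for v in per_scenario]
    )
    curves[:, 0] = 1.0
    return DVHBand(structure, edges, curves, nominal=curves[0])


def bandwidth_index(values) -> float:
    """Bandwidth = max - min of an index across the full scenario set."""
    v = np.asarray(values, dtype=float)
    if v.size != N_SCENARIOS or np.isnan(v).any():
        raise IncompleteScenarioSetError(
            f"bandwidth requires {N_SCENARIOS} scenario values, got {v.size}"
        )
    return float(v.max() - v.min())


def scenario_index_table(
    plan,
    phantom: Phantom,
    scenarios: list[Scenario],
    index_specs: list[IndexSpec],
    motion: MotionModel | None = None,
    engine: DoseEngine | None = None,
) -> pd.DataFrame:
    """Long table of every index in every scenario, plus the bandwidths.

    Returns columns [index, scenario, value]; the per-index bandwidth is
    obtainable via ``groupby('index').value.agg(lambda v: v.max()-v.min())``
    or :func:`bandwidth_table`.
    """
    roi = np.zeros(phantom.grid_shape, dtype=bool)
    for spec in index_specs:
        roi |= phantom.mask(spec.structure)
    rows = []
    for i, (sc, dose) in enumerate(
        scenario_doses(plan, phantom, scenarios, motion=motion, engine=engine, roi_mask=roi)
    ):
        for spec in index_specs:
            rows.append(
                dict(index=spec.label, scenario=i, value=spec.evaluate(dose, phantom))
            )
    return pd.DataFrame(rows)


def bandwidth_table(scenario_table: pd.DataFrame) -> pd.Series:
    """Per-index bandwidth from a :func:`scenario_index_table` result."""
    counts = scenario_table.groupby("index").scenario.nunique()
    if (counts != N_SCENARIOS).any():
        raise IncompleteScenarioSetError("some indices are missing scenario values")
    return scenario_table.groupby("index").value.agg(lambda v: v.max() - v.min())
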