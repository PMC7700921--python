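"""Cumulative DVHs, DVH indices, and dose-volume-constraint compliance.

Index conventions: Dx% is the minimum dose received by the hottest x% of
the structure volume, computed by linear interpolation on the sorted
voxel-dose empirical distribution (bin-independent); D2cc is the analogous
index for an absolute hottest 2 cm^3; VxGy is the percentage of the
structure receiving at least x Gy; Dmean and Dmax are computed from the raw
voxel values.  All voxels are weighted equally (uniform grid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import DoseGrid
from .phantom import Phantom


class StructureError(ValueError):
    pass


class UndefinedIndexError(ValueError):
    pass


@dataclass
class DVHCurve:
    structure: str
    dose_gy: np.ndarray  # bin edges (left), ascending, starting at 0
    volume_fraction: np.ndarray  # cumulative fraction receiving >= dose
    volume_cm3: float

    def volume_at_dose(self, d: float) -> float:
        """Fractional volume receiving at least ``d`` Gy (interpolated)."""
        return float(np.interp(d, self.dose_gy, self.volume_fraction))


def compute_dvh(
    dose: DoseGrid | np.ndarray,
    mask: np.ndarray,
    bin_width_gy: float = 0.05,
    structure: str = "",
    voxel_volume_cm3: float | None = None,
) -> DVHCurve:
    """Cumulative DVH; V(0) = 100% and the curve falls to 0 above Dmax."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be positive")
    if isinstance(dose, DoseGrid):
        voxel_volume_cm3 = dose.voxel_volume_cm3
        values = dose.values[mask]
    else:
        values = np.asarray(dose, dtype=float)[mask] if mask is not None else dose
    if values.size == 0:
        raise StructureError("empty structure mask")
    dmax = float(values.max())
    edges = np.arange(0.0, dmax + 2 * bin_width_gy, bin_width_gy)
    frac = (values[None, :] >= edges[:, None]).mean(axis=1)
    frac[0] = 1.0
    return DVHCurve(
        structure=structure,
        dose_gy=edges,
        volume_fraction=frac,
        volume_cm3=values.size * (voxel_volume_cm3 or np.nan),
    )


def _values(dose, mask) -> np.ndarray:
    if isinstance(dose, DoseGrid):
        v = dose.values[mask] if mask is not None else dose.values.ravel()
    else:
        arr = np.asarray(dose, dtype=float)
        v = arr[mask] if mask is not None else arr.ravel()
    if v.size == 0:
        raise StructureError("empty structure mask")
    return v


def dose_at_volume(dose, volume_pct: float, mask=None) -> float:
    """Dx%: minimum dose covering the hottest ``volume_pct`` of the volume.

    The cumulative volume receiving at least the k-th hottest voxel dose is
    k/n; Dx% inverts this survival function with linear interpolation
    between those points (clamped to the hottest voxel for fractions below
    1/n), so e.g. four 1-cc voxels {10,20,30,40} Gy give D2cc = 30 Gy.
    """
    v = _values(dose, mask)
    if not 0 < volume_pct <= 100:
        raise ValueError("volume_pct must lie in (0, 100]")
    v = np.sort(v)[::-1]
    h = np.clip(v.size * volume_pct / 100.0 - 1.0, 0.0, v.size - 1.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, v.size - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def dose_at_volume_cc(dose, volume_cc: float, mask, voxel_volume_cm3: float) -> float:
    """D<cc>: minimum dose covering the hottest ``volume_cc`` cm^3."""
    v = _values(dose, mask)
    total_cc = v.size * voxel_volume_cm3
    if total_cc <= volume_cc:
        raise UndefinedIndexError(
            f"D{volume_cc:g}cc undefined: structure volume {total_cc:.2f} cm^3"
        )
    return dose_at_volume(v, 100.0 * volume_cc / total_cc)


def volume_at_dose_pct(dose, dose_gy: float, mask=None) -> float:
    """VxGy: percentage of the structure receiving at least ``dose_gy``."""
    v = _values(dose, mask)
    return float((v >= dose_gy).mean() * 100.0)


def volume_at_dose_cc(dose, dose_gy: float, mask, voxel_volume_cm3: float) -> float:
    """VxGy(cc): absolute volume receiving at least ``dose_gy``."""
    v = _values(dose, mask)
    return float((v >= dose_gy).sum() * voxel_volume_cm3)


def dvh_index(
    dose,
    mask,
    kind: str,
    argument: float | None = None,
    voxel_volume_cm3: float | None = None,
    prescription_gy: float | None = None,
) -> float:
    """Generic DVH index dispatcher.

    kind: "Dx%" (argument = x), "Dcc" (argument = cc), "Dmean", "Dmax",
    "VxGy" (argument = x, % volume), "VxGycc" (argument = x, absolute cm^3).
    If ``prescription_gy`` is given, D-type results are returned as % of it.
    """
    v = _values(dose, mask)
    if kind == "Dx%":
        out = dose_at_volume(v, argument)
    elif kind == "Dcc":
        out = dose_at_volume_cc(v, argument, None, voxel_volume_cm3)
    elif kind == "Dmean":
        out = float(v.mean())
    elif kind == "Dmax":
        out = float(v.max())
    elif kind == "VxGy":
        return volume_at_dose_pct(v, argument)
    elif kind == "VxGycc":
        return volume_at_dose_cc(v, argument, None, voxel_volume_cm3)
    else:
        raise ValueError(f"unknown DVH index kind {kind!r}")
    if prescription_gy:
        out = 100.0 * out / prescription_gy
    return out


# Institutional dose-volume constraints for the organs at risk; limits are
# strict ("<") as written.  Kinds follow dvh_index; arguments in Gy.
OAR_CONSTRAINTS = (
    ("liver", "Dmean", None, 25.0, "Gy"),
    ("liver", "VxGy", 30.0, 60.0, "%"),
    ("lungs", "VxGy", 5.0, 60.0, "%"),
    ("lungs", "VxGy", 20.0, 15.0, "%"),
    ("lungs", "Dmean", None, 15.0, "Gy"),
    ("spinal_cord", "Dmax", None, 45.0, "Gy"),
    ("spinal_cord", "VxGy", 45.0, 0.1, "%"),
    ("heart", "VxGy", 25.0, 50.0, "%"),
    ("heart", "VxGy", 40.0, 30.0, "%"),
    ("heart", "Dmean", None, 26.0, "Gy"),
    ("kidney_left", "VxGy", 18.0, 10.0, "%"),
    ("kidney_left", "Dmean", None, 18.0, "Gy"),
    ("kidney_right", "VxGy", 18.0, 10.0, "%"),
    ("kidney_right", "Dmean", None, 18.0, "Gy"),
)


def constraint_label(structure: str, kind: str, argument) -> str:
    if kind == "Dmean":
        return f"{structure} Dmean"
    if kind == "Dmax":
        return f"{structure} Dmax"
    if kind == "VxGy":
        return f"{structure} V{argument:g}Gy"
    return f"{structure} {kind}"


def constraint_report(
    dose: DoseGrid, phantom: Phantom, constraints=OAR_CONSTRAINTS
) -> pd.DataFrame:
    """Pass/fail table for the organ-at-risk dose-volume constraints.

    A missing structure yields an ``evaluable=False`` row, never a silent
    pass.  Compliance uses strict inequality: a value exactly at the limit
    fails.
    """
    rows = []
    for structure, kind, arg, limit, unit in constraints:
        try:
            mask = phantom.mask(structure)
        except KeyError:
            rows.append(
                dict(
                    constraint=constraint_label(structure, kind, arg),
                    structure=structure,
                    limit=limit,
                    unit=unit,
                    value=np.nan,
                    passed=False,
                    evaluable=False,
                )
            )
            continue
        value = dvh_index(
            dose, mask, kind, arg, voxel_volume_cm3=dose.voxel_volume_cm3
        )
        rows.append(
            dict(
                constraint=constraint_label(structure, kind, arg),
                structure=structure,
                limit=limit,
                unit=unit,
                value=value,
                passed=bool(value < limit),
                evaluable=True,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IndexSpec:
    """A named DVH index on a named structure, optionally normalized."""

    structure: str
    kind: str
    argument: float | None = None
    normalize_to_gy: float | None = None

    @property
    def label(self) -> str:
        base = constraint_label(self.structure, self.kind, self.argument)
        if self.kind == "Dx%":
            base = f"{self.structure} D{self.argument:g}%"
        elif self.kind == "Dcc":
            base = f"{self.structure} D{self.argument:g}cc"
        elif self.kind == "VxGycc":
            base = f"{self.structure} V{self.argument:g}Gy(cc)"
        return base

    def evaluate(self, dose: DoseGrid, phantom: Phantom) -> float:
        return dvh_index(
            dose,
            phantom.mask(self.structure),
            self.kind,
            self.argument,
            voxel_volume_cm3=dose.voxel_volume_cm3,
            prescription_gy=self.normalize_to_gy,
        )


# The standard evaluation panel: target coverage/homogeneity/hot spot
# (normalized by prescription) and the organ-at-risk indices.
def standard_index_panel(prescriptions=(50.0, 45.0)) -> list[IndexSpec]:
    hi, lo = prescriptions
    return [
        IndexSpec("ctv_high", "Dx%", 95.0, hi),
        IndexSpec("ctv_high", "Dx%", 5.0, hi),
        IndexSpec("ctv_high", "Dcc", 2.0, hi),
        IndexSpec("ctv_low", "Dx%", 95.0, lo),
        IndexSpec("ctv_low", "Dx%", 5.0, lo),
        IndexSpec("spinal_cord", "Dmax"),
        IndexSpec("stomach", "VxGycc", 45.0),
        IndexSpec("heart", "Dmean"),
        IndexSpec("heart", "VxGy", 30.0),
        IndexSpec("heart", "VxGy", 40.0),
        IndexSpec("liver", "Dmean"),
        IndexSpec("liver", "VxGy", 30.0),
        IndexSpec("lungs", "Dmean"),
        IndexSpec("lungs", "VxGy", 5.0),
        IndexSpec("lungs", "VxGy", 20.0),
        IndexSpec("kidney_left", "VxGy", 18.0),
        IndexSpec("kidney_right", "VxGy", 18.0),
    ]
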