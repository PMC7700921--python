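"""Paired statistics: Wilcoxon signed-rank (normal approximation with tie
correction and zero discarding), median (range) summaries, and 1.5-IQR
box-plot statistics.

The signed-rank convention implemented here — zero differences discarded,
average ranks for ties, tie-corrected variance, two-sided normal
approximation without continuity correction — is the unique combination
that reproduces published two-group NTCP comparisons down to the degenerate
single-nonzero-pair case (|z| = 1, p = 0.3173).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    z: float
    p_two_sided: float
    n_effective: int


def wilcoxon_signed_rank(a, b, method: str = "approx") -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    ``method="approx"`` (default) is the tie-corrected normal approximation
    described in the module docstring; ``method="exact"`` delegates to the
    exact null distribution (only valid without zeros or ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise PairingError("paired samples must be equal-length 1D arrays")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(w_plus=0.0, z=0.0, p_two_sided=1.0, n_effective=0)
    if method == "exact":
        res = sps.wilcoxon(a, b, zero_method="wilcox", method="exact")
        return WilcoxonResult(
            w_plus=float(res.statistic), z=np.nan,
            p_two_sided=float(res.pvalue), n_effective=n,
        )
    if method != "approx":
        raise ValueError("method must be 'approx' or 'exact'")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_plus=w_plus, z=0.0, p_two_sided=1.0, n_effective=n)
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_plus=w_plus, z=float(z), p_two_sided=float(min(p, 1.0)), n_effective=n)


def median_range_summary(values) -> dict:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return {"median": float(np.median(v)), "min": float(v.min()), "max": float(v.max())}


def boxplot_stats(values, whisker_factor: float = 1.5) -> dict:
    """Quartiles (linear interpolation), 1.5-IQR whiskers and outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - whisker_factor * iqr, q3 + whisker_factor * iqr
    inliers = v[(v >= lo) & (v <= hi)]
    return {
        "q1": float(q1),
        "q2": float(q2),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": np.sort(v[(v < lo) | (v > hi)]),
    }


def compare_cohort(
    table: pd.DataFrame,
    group_a: str = "S-I",
    group_b: str = "R-L",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired group comparison of a long per-patient metric table.

    ``table`` columns: context, index, group, pair, value.  Returns one row
    per (context, index) with both group medians, the two-sided signed-rank
    p-value and a significance flag; a (context, index) with missing pairs
    in either group is reported with ``complete=False`` and no p-value.
    """
    required = {"context", "index", "group", "pair", "value"}
    if not required.issubset(table.columns):
        raise PairingError(f"table must have columns {sorted(required)}")
    rows = []
    for (context, index), sub in table.groupby(["context", "index"], sort=False):
        piv = sub.pivot_table(index="pair", columns="group", values="value", aggfunc="first")
        ok = (
            group_a in piv.columns
            and group_b in piv.columns
            and piv[[group_a, group_b]].notna().all().all()
        )
        row = dict(context=context, index=index, complete=bool(ok))
        if ok:
            a = piv[group_a].to_numpy()
            b = piv[group_b].to_numpy()
            res = wilcoxon_signed_rank(a, b)
            row.update(
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
                p=res.p_two_sided,
                significant=bool(res.p_two_sided < alpha),
            )
        else:
            row.update(median_a=np.nan, median_b=np.nan, p=np.nan, significant=False)
        rows.append(row)
    return pd.DataFrame(rows)


def load_published_ntcp() -> pd.DataFrame:
    """The packaged published NTCP table for two matched 10-patient groups.

    Columns: group ('S-I'/'R-L'), patient (1..10), and the three endpoint
    NTCP values in percent (pericarditis, liver_failure, pneumonitis), as
    printed in the source beam-angle comparison.
    """
    with resources.files("impteval.data").joinpath("published_ntcp_cohort.csv").open() as fh:
        return pd.read_csv(fh)
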