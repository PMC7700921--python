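"""Signed-rank conventions, summaries, box-plot statistics and the cohort
comparison machinery, cross-checked against scipy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from impteval.stats import (
    PairingError,
    boxplot_stats,
    compare_cohort,
    load_published_ntcp,
    median_range_summary,
    wilcoxon_signed_rank,
)


@pytest.fixture(scope="module")
def published():
    t = load_published_ntcp()
    si = t[t.group == "S-I"].sort_values("patient").reset_index(drop=True)
    rl = t[t.group == "R-L"].sort_values("patient").reset_index(drop=True)
    return si, rl


def test_published_table_shape(published):
    si, rl = published
    assert len(si) == 10 and len(rl) == 10
    assert (si.pneumonitis == 0).all()


def test_signed_rank_agrees_with_scipy_on_random_pairs(rng):
    for _ in range(20):
        n = rng.integers(4, 30)
        a = rng.normal(size=n)
        b = a + rng.normal(scale=0.5, size=n)
        ref = sps.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
        res = wilcoxon_signed_rank(a, b)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)


def test_signed_rank_with_ties_matches_scipy(rng):
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    b = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 4.0])  # tied |d| values
    ref = sps.wilcoxon(a, b, zero_method="wilcox", correction=False, method="approx")
    res = wilcoxon_signed_rank(a, b)
    assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)


def test_single_nonzero_pair_gives_unit_z():
    a = np.zeros(10)
    b = np.zeros(10)
    b[0] = 0.0004
    res = wilcoxon_signed_rank(a, b)
    assert res.n_effective == 1
    assert res.z == pytest.approx(-1.0)
    assert res.p_two_sided == pytest.approx(0.3173, abs=5e-5)


def test_all_zero_differences_give_p_one():
    res = wilcoxon_signed_rank(np.ones(6), np.ones(6))
    assert res.p_two_sided == 1.0
    assert res.n_effective == 0


def test_two_sided_symmetry(rng):
    a = rng.normal(size=12)
    b = rng.normal(size=12)
    r1 = wilcoxon_signed_rank(a, b)
    r2 = wilcoxon_signed_rank(b, a)
    assert r1.p_two_sided == pytest.approx(r2.p_two_sided, rel=1e-12)
    assert r1.z == pytest.approx(-r2.z, rel=1e-12)
    assert 0 < r1.p_two_sided <= 1.0


def test_length_mismatch_rejected():
    with pytest.raises(PairingError):
        wilcoxon_signed_rank(np.ones(3), np.ones(4))


def test_median_range_summary_conventions():
    assert median_range_summary([1.0, 2.0, 3.0, 4.0])["median"] == 2.5
    assert median_range_summary([7.0]) == {"median": 7.0, "min": 7.0, "max": 7.0}


def test_boxplot_outlier_rule():
    s = boxplot_stats(list(range(1, 10)) + [100])
    np.testing.assert_array_equal(s["outliers"], [100.0])
    assert s["whisker_high"] <= 9.0
    s2 = boxplot_stats(np.full(8, 3.0))
    assert s2["outliers"].size == 0
    assert s2["q3"] - s2["q1"] == 0.0


def test_boxplot_symmetric_sample_symmetric_whiskers():
    v = np.concatenate([np.linspace(-5, 5, 21)])
    s = boxplot_stats(v)
    assert s["whisker_low"] == -s["whisker_high"]


def test_compare_cohort_identical_groups_all_p_one():
    rows = []
    for pair in range(6):
        for group in ("S-I", "R-L"):
            rows.append(
                dict(context="nominal", index="liver Dmean", group=group,
                     pair=pair, value=3.0 + pair)
            )
    out = compare_cohort(pd.DataFrame(rows))
    assert (out.p == 1.0).all()
    assert not out.significant.any()


def test_compare_cohort_reports_gaps():
    rows = [
        dict(context="c", index="i", group="S-I", pair=0, value=1.0),
        dict(context="c", index="i", group="S-I", pair=1, value=2.0),
        dict(context="c", index="i", group="R-L", pair=0, value=1.5),
    ]
    out = compare_cohort(pd.DataFrame(rows))
    assert not out.complete.iloc[0]
    assert np.isnan(out.p.iloc[0])


def test_compare_cohort_row_count_is_contexts_times_indices(rng):
    rows = []
    for context in ("a", "b", "c"):
        for index in ("x", "y"):
            for pair in range(4):
                for group in ("S-I", "R-L"):
                    rows.append(
                        dict(context=context, index=index, group=group, pair=pair,
                             value=float(rng.normal()))
                    )
    out = compare_cohort(pd.DataFrame(rows))
    assert len(out) == 6
    assert out.complete.all()
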