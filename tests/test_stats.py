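"""Statistical layer: exact tests vs brute-force enumeration, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mrla.cohort import default_cohort_spec, generate_cohort
from mrla.stats import (StatsError, format_cell, group_compare,
                        paired_compare, parse_cell, relative_expression,
                        summarize)


# ------------------------------------------------- brute-force oracles
def wilcoxon_enumeration(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s)
                   for signs in itertools.product([False, True], repeat=n)])
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lo, hi))


def mannwhitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    r_obs = ranks[:n1].sum()
    u_obs = r_obs - n1 * (n1 + 1) / 2.0
    n = len(pooled)
    us = []
    for idx in itertools.combinations(range(n), n1):
        r = ranks[list(idx)].sum()
        us.append(r - n1 * (n1 + 1) / 2.0)
    us = np.array(us)
    mean_u = n1 * (n - n1) / 2.0
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(lo, hi))


# ------------------------------------------------------- paired Wilcoxon
def test_identical_samples_give_p_one():
    x = [3.0, 1.0, 4.0, 1.5, 9.0]
    assert paired_compare(x, x) == 1.0


def test_extreme_shift_gives_minimal_exact_p():
    x = np.arange(8, dtype=float)
    y = x + 100.0
    assert paired_compare(x, y) == pytest.approx(2.0 / 2**8)


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
def test_signed_rank_matches_enumeration(n, seed):
    rng = np.random.default_rng(100 * n + seed)
    # integer-valued data so ties among |differences| occur
    x = rng.integers(0, 6, size=n).astype(float)
    y = rng.integers(0, 6, size=n).astype(float)
    if np.all(x == y):
        x[0] += 1.0
    assert paired_compare(x, y) == pytest.approx(
        wilcoxon_enumeration(x - y), abs=1e-12)


@settings(max_examples=40, deadline=None)
@given(st.lists(st.integers(-5, 5), min_size=3, max_size=10))
def test_signed_rank_p_in_unit_interval(diffs):
    x = np.zeros(len(diffs))
    y = np.array(diffs, dtype=float)
    p = paired_compare(x, x + y)
    assert 0.0 < p <= 1.0
    # symmetry: swapping the phases leaves p unchanged
    assert paired_compare(x + y, x) == pytest.approx(p)


def test_signed_rank_agrees_with_scipy_on_tie_free_data():
    rng = np.random.default_rng(7)
    for n in (6, 10, 15):
        d = rng.standard_normal(n) + 0.3
        ref = sps.wilcoxon(d, alternative="two-sided",
                           method="exact").pvalue
        assert paired_compare(d, np.zeros(n)) == pytest.approx(float(ref))


def test_large_sample_uses_normal_approximation():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(40)
    y = x + 0.5 + 0.2 * rng.standard_normal(40)
    p = paired_compare(x, y)
    ref = sps.wilcoxon(x - y, alternative="two-sided", correction=True,
                       method="approx").pvalue
    assert p == pytest.approx(float(ref))


def test_paired_compare_input_validation():
    with pytest.raises(StatsError):
        paired_compare([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(StatsError):
        paired_compare([1, 2, 3], [1, 2])


# ------------------------------------------------------- group compare
def test_fully_separated_three_vs_three():
    assert group_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]) == \
        pytest.approx(0.1)


def test_identical_groups_mann_whitney():
    p = group_compare([1.0, 5.0, 9.0, 2.0], [9.0, 1.0, 2.0, 5.0])
    assert p == pytest.approx(1.0, abs=0.05)


@pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (5, 8), (8, 8)])
def test_mann_whitney_matches_enumeration(n1, n2):
    rng = np.random.default_rng(10 * n1 + n2)
    x = rng.standard_normal(n1)
    y = rng.standard_normal(n2) + 0.8
    assert group_compare(x, y) == pytest.approx(
        mannwhitney_enumeration(x, y), abs=1e-12)


def test_t_test_type_one_error_rate():
    """At equal means the Student t test rejects at ~ the nominal level."""
    rng = np.random.default_rng(123)
    reps, n = 10_000, 10
    x = rng.standard_normal((reps, n))
    y = rng.standard_normal((reps, n))
    p = sps.ttest_ind(x, y, axis=1, equal_var=True).pvalue
    rate = np.mean(p < 0.05)
    assert rate == pytest.approx(0.05, abs=0.01)
    # spot-check our wrapper against scipy on one draw
    assert group_compare(x[0], y[0], method="t") == pytest.approx(float(p[0]))


def test_t_test_rejects_zero_variance():
    with pytest.raises(StatsError, match="variance"):
        group_compare([2.0, 2.0, 2.0], [2.0, 2.0], method="t")


def test_unknown_method_rejected():
    with pytest.raises(StatsError, match="method"):
        group_compare([1, 2], [3, 4], method="anova")


# ------------------------------------------------- relative expression
def test_relative_expression_examples():
    assert relative_expression(20.0, 20.0) == 1.0
    assert relative_expression(18.0, 20.0) == 4.0
    assert relative_expression(21.0, 20.0) == 0.5


@settings(max_examples=40, deadline=None)
@given(ct_ref=st.floats(15.0, 35.0),
       d1=st.floats(-5.0, 5.0), d2=st.floats(-5.0, 5.0))
def test_relative_expression_monotone_and_multiplicative(ct_ref, d1, d2):
    base = relative_expression(ct_ref + d1, ct_ref)
    assert relative_expression(ct_ref + d1 + 1.0, ct_ref) < base
    combined = relative_expression(ct_ref + d1 + d2, ct_ref)
    assert combined == pytest.approx(
        base * relative_expression(ct_ref + d2, ct_ref), rel=1e-9)


def test_relative_expression_rejects_nonfinite():
    with pytest.raises(StatsError):
        relative_expression(float("nan"), 20.0)
    with pytest.raises(StatsError):
        relative_expression(20.0, -1.0)


# ------------------------------------------------------------ summaries
def test_summary_cells_and_flags():
    table = generate_cohort(default_cohort_spec(seed=0))
    summary = summarize(table)
    row = summary.data
    base = row[(row.group == "MR-LBBB") & (row.phase == "baseline")]
    assert (~base.tested).all()          # baseline is the comparator
    assert (base.n == 12).all()
    w20 = row[(row.group == "MR-LBBB") & (row.phase == "20w")]
    assert (w20.n == 8).all()
    assert summary.metadata["multiple_testing_correction"] == "none"


def test_acute_reservoir_strain_flagged_significant_in_most_seeds():
    """The configured baseline-to-acute shift (40 -> 51) is large relative
    to the within-phase spread, so the paired test flags it almost always."""
    hits = 0
    for seed in range(25):
        table = generate_cohort(default_cohort_spec(seed=seed))
        summary = summarize(table)
        row = summary.data
        cell = row[(row.group == "MR-LBBB") & (row.phase == "acute")
                   & (row.parameter == "las_r")]
        hits += bool(cell.significant.iloc[0])
    assert hits >= 23  # >= 90% of seeds


def test_degenerate_cohort_has_no_significant_flags():
    from test_cohort import _zero_iqr_spec

    table = generate_cohort(_zero_iqr_spec())
    # make every phase identical to baseline so all differences vanish
    spec = default_cohort_spec()
    rows = []
    for _, r in table.iterrows():
        base = spec.groups[r.group].measurements[r.parameter][
            spec.groups[r.group].phases[0]][0]
        rows.append(dict(r, value=base))
    flat = pd.DataFrame(rows)
    summary = summarize(flat)
    assert not summary.data.significant.any()


def test_cell_format_roundtrip():
    cell = format_cell(40.0, 37.0, 42.0, significant=True)
    assert cell == "40 [37–42]†"
    med, q1, q3, sig = parse_cell(cell)
    assert (med, q1, q3, sig) == (40.0, 37.0, 42.0, True)
    med, q1, q3, sig = parse_cell(format_cell(-7.2, -10.0, -2.1))
    assert (med, q1, q3, sig) == (-7.2, -10.0, -2.1, False)


def test_summary_wide_layout_roundtrips_through_csv(tmp_path):
    table = generate_cohort(default_cohort_spec(seed=4))
    summary = summarize(table)
    path = tmp_path / "summary.csv"
    summary.to_csv(path)
    wide = pd.read_csv(path, index_col=0)
    cell = wide.loc["las_r", "MR-LBBB/baseline"]
    med, q1, q3, _ = parse_cell(cell)
    assert q1 <= med <= q3
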