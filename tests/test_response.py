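"""Responsiveness classification and the statistical conventions: percentile
threshold arithmetic, exact Wilcoxon enumeration, t/ANOVA dispatch and
type-I calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonadocal.response import (
    ResponseParams,
    classify_responsive,
    compare_populations,
    compare_pre_post,
)


def coeffs(values, prefix="c"):
    return {f"{prefix}{i}": v for i, v in enumerate(values)}


def pops_for(cells, population="LH"):
    return {c: population for c in cells}


def test_percentile_threshold_arithmetic():
    """Basal {0.0..0.9}: linear-interpolation 80th percentile is 0.72."""
    basal = coeffs(np.arange(10) / 10.0)
    stim = dict(basal)
    stim["c0"], stim["c1"] = 0.80, 0.50
    summary = classify_responsive(basal, stim, pops_for(basal))
    assert summary.threshold_by_population["LH"] == pytest.approx(0.72)
    per_cell = summary.per_cell.set_index("cell_id")
    assert per_cell.loc["c0", "responsive"] == True  # 0.80 > 0.72
    assert per_cell.loc["c1", "responsive"] == False  # 0.50 <= 0.72


def test_all_cells_above_every_basal_value():
    basal = coeffs(np.linspace(0.1, 0.5, 12))
    stim = coeffs(np.full(12, 0.95))
    summary = classify_responsive(basal, stim, pops_for(basal))
    assert summary.fraction_responsive_pct["LH"] == 100.0


def test_identical_sessions_give_twenty_percent():
    """stim == basal: exactly the values above the 80th percentile respond."""
    basal = coeffs(np.arange(10) / 10.0)
    summary = classify_responsive(basal, dict(basal), pops_for(basal))
    assert summary.fraction_responsive_pct["LH"] == pytest.approx(20.0)


def test_threshold_is_strict_inequality():
    basal = coeffs([0.1, 0.2, 0.3, 0.4, 0.5])
    threshold = np.percentile([0.1, 0.2, 0.3, 0.4, 0.5], 80)
    stim = coeffs([threshold, threshold + 1e-9, 0.0, 0.0, 0.0])
    summary = classify_responsive(basal, stim, pops_for(basal))
    per_cell = summary.per_cell.set_index("cell_id")
    assert per_cell.loc["c0", "responsive"] == False  # equal is not above
    assert per_cell.loc["c1", "responsive"] == True


def test_missing_coefficients_excluded_from_both_sides():
    basal = coeffs([0.1, 0.2, 0.3, np.nan])
    stim = coeffs([0.9, 0.9, 0.0, 0.9])
    summary = classify_responsive(basal, stim, pops_for(basal))
    assert summary.fraction_responsive_pct["LH"] == pytest.approx(100.0 * 2 / 3)


def test_per_population_thresholds_independent():
    basal = {**coeffs([0.1, 0.2, 0.3], "lh"), **coeffs([0.6, 0.7, 0.8], "fsh")}
    stim = {**coeffs([0.5, 0.5, 0.5], "lh"), **coeffs([0.5, 0.5, 0.5], "fsh")}
    populations = {**pops_for(coeffs([0]*3, "lh"), "LH"), **pops_for(coeffs([0]*3, "fsh"), "FSH")}
    summary = classify_responsive(basal, stim, populations)
    assert summary.fraction_responsive_pct["LH"] == 100.0
    assert summary.fraction_responsive_pct["FSH"] == 0.0


def test_no_valid_basal_errors():
    with pytest.raises(ValueError, match="basal"):
        classify_responsive(coeffs([np.nan, np.nan]), coeffs([0.5, 0.5]), pops_for(coeffs([0, 0])))


def test_wilcoxon_uniform_shift_exact_p():
    """Five uniformly positive paired differences: one-sided p = 1/32 exactly."""
    pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    stat, p, n = compare_pre_post(pre, pre + 1.0)
    assert n == 5
    assert p == pytest.approx(1 / 32, abs=1e-12)
    _, p_rev, _ = compare_pre_post(pre, pre - 1.0)
    assert p_rev == pytest.approx(1.0, abs=1e-12)


def test_wilcoxon_all_ties_errors():
    pre = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="zero"):
        compare_pre_post(pre, pre)
    with pytest.raises(ValueError, match="3 pairs"):
        compare_pre_post([1.0, 2.0], [2.0, 3.0])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 10))
def test_wilcoxon_matches_full_enumeration(seed, n):
    """Exact one-sided p equals enumeration over all 2^n sign assignments."""
    rng = np.random.default_rng(seed)
    diffs = rng.standard_normal(n) + 0.5
    diffs[diffs == 0] = 0.5
    # distinct magnitudes keep the ranking unambiguous
    while len(set(np.abs(diffs))) < n:
        diffs += rng.standard_normal(n) * 1e-6
    pre = rng.standard_normal(n)
    post = pre + diffs
    _, p, _ = compare_pre_post(pre, post)
    ranks = np.abs(diffs).argsort().argsort() + 1
    observed = ranks[diffs > 0].sum()
    null = [np.sum(np.array(signs) * ranks) for signs in itertools.product([0, 1], repeat=n)]
    p_enum = np.mean([s >= observed for s in null])
    assert p == pytest.approx(p_enum, abs=1e-12)


def test_two_group_dispatch():
    table = compare_populations({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    row = table.iloc[0]
    assert row.test == "t_unpaired_two_tailed"
    assert row.statistic == 0.0 and row.p_value == 1.0

    table = compare_populations({"a": [0.0, 0.0, 0.0], "b": [1.0, 1.0, 1.0]})
    row = table.iloc[0]
    assert row.p_value < 1e-6
    assert row.statistic < 0  # direction: a below b


def test_three_group_anova_with_tukey():
    rng = np.random.default_rng(0)
    groups = {k: rng.normal(loc, 1.0, 12) for k, loc in [("a", 0.0), ("b", 0.0), ("c", 2.0)]}
    table = compare_populations(groups)
    omnibus = table[table.test == "one_way_anova"].iloc[0]
    assert omnibus.p_value < 0.01
    tukey = table[table.test == "tukey_kramer"].set_index("comparison")
    assert tukey.loc["a vs b", "p_value"] > 0.05
    assert tukey.loc["a vs c", "p_value"] < 0.05


def test_anova_type_one_error_calibrated():
    """Equal-mean groups: rejection rate at alpha 0.05 within [0.035, 0.065]."""
    rng = np.random.default_rng(42)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        groups = {k: rng.standard_normal(10) for k in "abc"}
        table = compare_populations(groups)
        if table[table.test == "one_way_anova"].iloc[0].p_value < 0.05:
            rejections += 1
    assert 0.035 <= rejections / reps <= 0.065


def test_degenerate_group_errors():
    with pytest.raises(ValueError, match="fewer than 2"):
        compare_populations({"a": [1.0], "b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="two groups"):
        compare_populations({"a": [1.0, 2.0]})
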