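"""Cohort statistics: stratification, rank tests, adjustment, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spcpanel.cohort import (
    adjust_for_sex,
    age_stratum,
    bh_adjust,
    classify_bmi,
    compare_by_stratum,
    filter_healthy,
    mann_whitney,
    pearson_r,
    percent_excess,
    stars,
    summary_table,
)


# ---------------------------------------------------------------------------
# stratifiers


@pytest.mark.parametrize(
    "bmi,cls",
    [
        (17.0, "underweight"),
        (18.4, "underweight"),
        (18.5, "normal"),
        (24.99, "normal"),
        (25.0, "overweight"),
        (29.99, "overweight"),
        (30.0, "obese"),
        (45.0, "obese"),
    ],
)
def test_bmi_classes_partition(bmi, cls):
    assert classify_bmi(bmi) == cls


def test_nonpositive_bmi_rejected():
    with pytest.raises(ValueError):
        classify_bmi(0.0)


@pytest.mark.parametrize(
    "age,stratum",
    [
        (20.0, "20-29"),
        (29.9, "20-29"),
        (30.0, "30-39"),
        (59.99, "50-59"),
        (60.0, "60-70"),
        (70.0, "60-70"),
        (19.9, None),
        (70.1, None),
    ],
)
def test_age_strata(age, stratum):
    assert age_stratum(age) == stratum


# ---------------------------------------------------------------------------
# healthy filter


def _records(rows):
    cols = ["participant_id", "cohort", "smoker", "n_conditions", "bp_normal",
            "bmi", "self_rated_health"]
    return pd.DataFrame(rows, columns=cols)


def test_filter_healthy_hand_evaluated_toy_table():
    rows = [
        ("ok", "population", False, 0, True, 24.0, "good"),
        ("smokes", "population", True, 0, True, 24.0, "good"),
        ("sick", "population", False, 2, True, 24.0, "good"),
        ("hypertense", "population", False, 0, False, 24.0, "good"),
        ("obese", "population", False, 0, True, 31.0, "good"),
        ("feels-bad", "population", False, 0, True, 24.0, "fair"),
    ]
    kept = filter_healthy(_records(rows))
    assert kept["participant_id"].tolist() == ["ok"]


def test_basque_records_pass_unconditionally():
    rows = [("b1", "basque", True, 3, False, 32.0, "poor")]
    assert len(filter_healthy(_records(rows))) == 1


def test_filter_healthy_empty_and_idempotent():
    empty = _records([])
    assert filter_healthy(empty).empty
    rows = [
        ("ok", "population", False, 0, True, 24.0, "excellent"),
        ("no", "population", True, 0, True, 24.0, "excellent"),
    ]
    df = _records(rows)
    once = filter_healthy(df)
    pd.testing.assert_frame_equal(filter_healthy(once), once)
    shuffled = filter_healthy(df.iloc[::-1])
    assert set(shuffled["participant_id"]) == set(once["participant_id"])


# ---------------------------------------------------------------------------
# Mann-Whitney


def _exact_mwu_p(a, b):
    """Enumeration oracle: two-sided p over all group labelings."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def test_mwu_separated_groups_exact():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.100, abs=1e-10)
    assert p == pytest.approx(_exact_mwu_p([1, 2, 3], [4, 5, 6]), abs=1e-10)


def test_mwu_identical_constant_groups():
    _, p = mann_whitney([5, 5, 5], [5, 5, 5])
    assert p == 1.0


def test_mwu_midranks_with_ties():
    u, p = mann_whitney([1, 2], [1, 2])
    assert u == 2.0  # n1*n2/2 under midranks
    assert p == 1.0


def test_mwu_rejects_empty_group():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mwu_exact_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.permutation(np.arange(1.0, 7.0))[:4]
    b = rng.permutation(np.arange(10.0, 18.0, 0.7))[:5]
    _, p = mann_whitney(a, b)
    assert p == pytest.approx(_exact_mwu_p(a, b), abs=1e-10)


def test_mwu_normal_approximation_close_to_exact_at_n8():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.5, 1, 8)
    _, p_exact = mann_whitney(a, b)  # min n <= 8, no ties -> exact
    from scipy.stats import mannwhitneyu

    p_approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    assert abs(p_exact - p_approx) <= 0.02


# ---------------------------------------------------------------------------
# BH adjustment and stars


@pytest.mark.parametrize(
    "raw,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.05], [0.05]),
        ([0.04, 0.01], [0.04, 0.02]),
    ],
)
def test_bh_hand_oracle(raw, expected):
    np.testing.assert_allclose(bh_adjust(raw), expected, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_bh_monotone_capped_order_preserving(ps):
    adj = bh_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


@pytest.mark.parametrize(
    "p,levels,expected",
    [
        (0.04, 4, "*"),
        (0.05, 4, ""),
        (0.009, 4, "**"),
        (5e-4, 4, "***"),
        (5e-5, 4, "****"),
        (5e-5, 3, "***"),
        (0.5, 4, ""),
    ],
)
def test_star_annotation(p, levels, expected):
    assert stars(p, levels) == expected


# ---------------------------------------------------------------------------
# stratified comparison


def _toy_samples():
    rows = []
    # stratum A: clean separation; stratum B: interleaved
    for v in (1, 2, 3):
        rows.append(("A", "male", float(v)))
    for v in (4, 5, 6):
        rows.append(("A", "female", float(v)))
    for i, v in enumerate((1, 3, 5, 7, 2, 4, 6, 8)):
        rows.append(("B", "male" if i < 4 else "female", float(v)))
    return pd.DataFrame(rows, columns=["stratum", "sex", "marker"])


def test_compare_by_stratum_matches_hand_bh():
    comps = compare_by_stratum(
        _toy_samples(), "marker", stratifier="stratum", grouping="sex",
        group_order=("male", "female"),
    )
    assert [c.stratum for c in comps] == ["A", "B"]
    p_raw = [c.p_raw for c in comps]
    expected = bh_adjust(p_raw)
    np.testing.assert_allclose([c.p_adjusted for c in comps], expected, atol=1e-12)
    assert comps[0].medians == (2.0, 5.0)


def test_constant_marker_yields_no_stars():
    df = _toy_samples().assign(marker=7.0)
    comps = compare_by_stratum(df, "marker", "stratum", "sex",
                               group_order=("male", "female"))
    assert all(c.p_adjusted == 1.0 and c.stars == "" for c in comps)


def test_empty_group_stratum_skipped():
    df = _toy_samples()
    df = pd.concat(
        [df, pd.DataFrame([("C", "male", 1.0)], columns=df.columns)], ignore_index=True
    )
    comps = compare_by_stratum(df, "marker", "stratum", "sex",
                               group_order=("male", "female"))
    assert [c.stratum for c in comps] == ["A", "B"]


# ---------------------------------------------------------------------------
# sex adjustment


def test_adjust_for_sex_closed_form():
    vals = np.array([10.0, 10.0, 20.0, 20.0])
    sex = np.array(["male", "male", "female", "female"])
    np.testing.assert_allclose(adjust_for_sex(vals, sex), [15.0] * 4, atol=1e-12)


def test_adjust_for_sex_equalises_means_preserves_grand_mean():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(5, 1, 40), rng.normal(8, 2, 60)])
    sex = np.array(["male"] * 40 + ["female"] * 60)
    adj = adjust_for_sex(vals, sex)
    assert adj[sex == "male"].mean() == pytest.approx(adj[sex == "female"].mean(), abs=1e-10)
    assert adj.mean() == pytest.approx(vals.mean(), abs=1e-10)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(2, 30), st.integers(2, 30), st.integers(0, 1000))
def test_adjust_for_sex_preserves_within_sex_order(n_m, n_f, seed):
    rng = np.random.default_rng(seed)
    vals = np.concatenate([rng.normal(0, 3, n_m), rng.normal(2, 3, n_f)])
    sex = np.array(["m"] * n_m + ["f"] * n_f)
    adj = adjust_for_sex(vals, sex)
    for lvl in ("m", "f"):
        sub = sex == lvl
        np.testing.assert_array_equal(np.argsort(adj[sub]), np.argsort(vals[sub]))


def test_adjust_for_sex_rejects_single_sex():
    with pytest.raises(ValueError):
        adjust_for_sex([1.0, 2.0], ["male", "male"])


# ---------------------------------------------------------------------------
# correlations, excess, summaries


def test_pearson_exact_linear_and_null():
    x = np.arange(10.0)
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    assert abs(pearson_r(rng.normal(size=10_000), rng.normal(size=10_000))) < 0.05


def test_pearson_zero_variance_is_nan():
    assert math.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


@pytest.mark.parametrize(
    "f,m,expected",
    [(6837.86, 5123.65, 33.46), (5502.43, 4085.73, 34.67), (5.0, 5.0, 0.0)],
)
def test_percent_excess_arithmetic(f, m, expected):
    assert percent_excess(f, m) == pytest.approx(expected, abs=0.005)


def test_summary_table_against_quantile_oracle():
    df = pd.DataFrame({"g": ["a"] * 3, "v": [1.0, 2.0, 3.0]})
    row = summary_table(df, "v", ["g"]).iloc[0]
    assert (row["median"], row["min"], row["max"]) == (2.0, 1.0, 3.0)
    rng = np.random.default_rng(2)
    big = pd.DataFrame({"g": rng.choice(["a", "b"], 500), "v": rng.normal(size=500)})
    tab = summary_table(big, "v", ["g"]).set_index("g")
    for g, sub in big.groupby("g"):
        assert tab.loc[g, "q1"] == pytest.approx(np.quantile(sub["v"], 0.25))
        assert tab.loc[g, "q3"] == pytest.approx(np.quantile(sub["v"], 0.75))
        assert tab.loc[g, "n"] == len(sub)
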