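"""Outlier screen, decision tree, effect size and power analysis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnskin.univariate import (
    FEATURES,
    PowerQuery,
    cohens_d,
    decide_pair,
    min_sample_size,
    outlier_screen,
    power_two_sample_t,
    run_univariate,
)


def _table(values, feature="mu_MPa", rate=0.3):
    df = pd.DataFrame({f: 1.0 for f in FEATURES}, index=range(len(values)))
    df[feature] = values
    df["rate_mm_per_s"] = rate
    df["sample_id"] = [f"s{i}" for i in range(len(values))]
    return df


# ---------------------------------------------------------------------------
# outlier screen


def test_screen_removes_beyond_upper_fence():
    # Q1 = 2, Q3 = 4, IQR = 2, upper fence = 10 -> only the 100 is removed
    kept, removed = outlier_screen(_table([1.0, 2.0, 3.0, 4.0, 100.0]))
    assert list(removed["mu_MPa"]) == [100.0]
    assert len(kept) == 4


def test_screen_identical_values_keep_everything():
    kept, removed = outlier_screen(_table([3.0] * 6))
    assert len(kept) == 6 and removed.empty


def test_screen_single_pass_fences():
    # after removing 100 the fences would tighten and 9 would fall out too;
    # the single-pass contract keeps it
    kept, _ = outlier_screen(_table([1.0, 1.1, 0.9, 1.0, 9.0, 100.0]))
    assert 9.0 in kept["mu_MPa"].values


def test_screen_right_skew_removes_only_upper_tail():
    """Heavy-tailed positive data: removals sit above the upper fence only."""
    rng = np.random.default_rng(7)
    values = np.exp(1.5 * rng.standard_normal(300))
    kept, removed = outlier_screen(_table(values))
    assert len(removed) > 0
    assert removed["mu_MPa"].min() > kept["mu_MPa"].max()


def test_screen_flags_any_of_five_parameters():
    df = _table([1.0] * 5)
    df.loc[2, "gamma"] = 1e6
    kept, removed = outlier_screen(df)
    assert list(removed["sample_id"]) == ["s2"]


# ---------------------------------------------------------------------------
# decision tree branch logic (stubbed tests isolate the routing)


def _stub(p):
    return lambda *args: (0.0, p)


def test_tree_normal_path_pooled_t():
    trace = decide_pair(
        np.arange(3.0), np.arange(3.0) + 1,
        tests={"shapiro": _stub(0.5), "f": _stub(0.5), "t_pooled": _stub(0.2)},
    )
    assert [s.test for s in trace.steps] == ["shapiro_x", "shapiro_y", "f_var", "t_pooled"]
    assert trace.conclusion == "equal"


def test_tree_normal_path_welch_on_unequal_variance():
    trace = decide_pair(
        np.arange(3.0), np.arange(3.0) + 1,
        tests={"shapiro": _stub(0.5), "f": _stub(0.001), "t_welch": _stub(0.005)},
    )
    assert trace.terminal.test == "t_welch"
    assert trace.conclusion == "not equal"


def test_tree_nonnormal_same_shape_ranksum():
    stubs = {"ks": _stub(0.3), "ranksum": _stub(0.004)}

    def shapiro(s):
        return (0.0, 0.001) if s[0] == 0 else (0.0, 0.5)

    trace = decide_pair(np.arange(3.0), np.arange(3.0) + 1,
                        tests={"shapiro": shapiro, **stubs})
    assert [s.test for s in trace.steps] == ["shapiro_x", "shapiro_y", "ks", "ranksum"]
    assert trace.conclusion == "not equal"


def test_tree_nonnormal_different_shapes_welch():
    trace = decide_pair(
        np.arange(3.0), np.arange(3.0) + 1,
        tests={"shapiro": _stub(0.001), "ks": _stub(0.001), "t_welch": _stub(0.5)},
    )
    assert trace.terminal.test == "t_welch"
    assert trace.conclusion == "equal"


def test_tree_requires_three_observations():
    with pytest.raises(ValueError):
        decide_pair([1.0, 2.0], [1.0, 2.0, 3.0])


def test_every_probability_recorded_is_valid():
    rng = np.random.default_rng(0)
    trace = decide_pair(rng.normal(size=30), rng.normal(size=30))
    assert all(0 <= s.p_value <= 1 for s in trace.steps)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum against exact enumeration


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by brute-force enumeration of all assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    nx = len(x)
    observed = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2
    stats_all = [
        sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), nx)
    ]
    dev = abs(observed - mu)
    count = sum(1 for s in stats_all if abs(s - mu) >= dev - 1e-9)
    return count / len(stats_all)


def test_ranksum_separated_triples_exact():
    # 2 of the C(6,3) = 20 equally likely assignments are as extreme
    from burnskin.univariate import _ranksum

    _, p = _ranksum(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
    assert p == pytest.approx(0.1)
    assert exact_ranksum_p([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]) == pytest.approx(0.1)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.data())
def test_ranksum_matches_enumeration_oracle(data):
    """Exact rank-sum p equals brute-force enumeration for n_x + n_y <= 10."""
    from burnskin.univariate import _ranksum

    nx = data.draw(st.integers(3, 7))
    ny = data.draw(st.integers(3, min(7, 10 - nx)))
    pool = data.draw(
        st.lists(
            st.floats(-50, 50),
            min_size=nx + ny, max_size=nx + ny, unique=True,
        )
    )
    x, y = np.array(pool[:nx]), np.array(pool[nx:])
    _, p = _ranksum(x, y)
    assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-9)


def test_identical_groups_never_reject():
    rng = np.random.default_rng(2)
    x = np.exp(rng.standard_normal(40))
    trace = decide_pair(x, x.copy())
    assert trace.conclusion == "equal"
    assert trace.terminal.p_value > 0.9


# ---------------------------------------------------------------------------
# Cohen's d


def test_cohens_d_hand_values():
    assert cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == pytest.approx(1.0)
    assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_cohens_d_unit_effect():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(2000)
    x = (x - x.mean()) / x.std(ddof=1)
    assert cohens_d(x, x + 1.0) == pytest.approx(1.0, abs=1e-9)


def test_cohens_d_zero_variance_signalled():
    with pytest.raises(ValueError):
        cohens_d([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# power analysis


def test_min_sample_size_reproduces_reported_value():
    assert min_sample_size(PowerQuery(0.4, 0.05, 0.85, 1.0, "one")) == 91


def test_min_sample_size_classic_two_tailed():
    q = PowerQuery(1.0, 0.05, 0.80, 1.0, "two")
    assert min_sample_size(q) == 17
    assert power_two_sample_t(16, q) < 0.80 <= power_two_sample_t(17, q)


@pytest.mark.parametrize(
    "query",
    [
        PowerQuery(0.4, 0.05, 0.85, 1.0, "one"),
        PowerQuery(0.3, 0.01, 0.90, 1.0, "two"),
        PowerQuery(0.8, 0.05, 0.95, 2.0, "two"),
        PowerQuery(0.2, 0.05, 0.80, 1.0, "one"),
    ],
)
def test_min_sample_size_minimality(query):
    n = min_sample_size(query)
    assert power_two_sample_t(n, query) >= query.power
    assert power_two_sample_t(n - 1, query) < query.power


def test_min_sample_size_monotone():
    base = PowerQuery(0.4, 0.05, 0.85, 1.0, "two")
    assert min_sample_size(PowerQuery(0.6, 0.05, 0.85, 1.0, "two")) <= min_sample_size(base)
    assert min_sample_size(PowerQuery(0.4, 0.05, 0.95, 1.0, "two")) >= min_sample_size(base)


def test_power_query_validation():
    with pytest.raises(ValueError):
        PowerQuery(-0.4)
    with pytest.raises(ValueError):
        PowerQuery(0.4, alpha=0.5, power=0.3)


# ---------------------------------------------------------------------------
# cohort-level driver


def _three_rate_cohort(rng, shift=(0.0, 0.0, 0.0), n=(30, 30, 30)):
    frames = []
    for rate, s, ni in zip((0.3, 2.0, 8.0), shift, n):
        df = pd.DataFrame(
            {f: np.exp(s + rng.standard_normal(ni)) for f in FEATURES}
        )
        df["rate_mm_per_s"] = rate
        df["sample_id"] = [f"{rate}-{i}" for i in range(ni)]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def test_run_univariate_shape_and_null_behaviour():
    cohort = _three_rate_cohort(np.random.default_rng(11))
    table, traces = run_univariate(cohort)
    assert len(table) == 15 and len(traces) == 15
    assert set(table["parameter"]) == set(FEATURES)
    # a null cohort at alpha = 0.01 should reject rarely
    assert (table["conclusion"] == "not equal").sum() <= 2


def test_run_univariate_detects_large_shift():
    cohort = _three_rate_cohort(np.random.default_rng(12), shift=(0.0, 0.0, 3.0))
    table, _ = run_univariate(cohort)
    shifted = table[(table["rate_b"] == 8.0) | (table["rate_a"] == 8.0)]
    assert (shifted["conclusion"] == "not equal").all()


def test_run_univariate_requires_three_classes():
    cohort = _three_rate_cohort(np.random.default_rng(13))
    with pytest.raises(ValueError):
        run_univariate(cohort[cohort["rate_mm_per_s"] != 8.0])
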