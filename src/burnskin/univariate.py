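"""Outlier screening, the univariate hypothesis-testing decision tree,
Cohen's d, and minimum-sample-size power analysis.

The decision tree compares one material parameter between two loading-rate
groups at significance alpha = 0.01:

1. Shapiro-Wilk normality on each group.
2. If both retain normality: a two-sample F-test selects the pooled-variance
   (p > alpha) or unequal-variance (p <= alpha) t-test, whose p-value is
   terminal.
3. Otherwise: the two-sample Kolmogorov-Smirnov test probes whether the two
   continuous distributions share a shape.  If it retains (p > alpha), the
   Wilcoxon rank-sum test is terminal; if it rejects, the unequal-variance
   t-test is terminal.

The conclusion is "not equal" iff the terminal p <= alpha.  No multiple-
testing correction is applied: decisions are reported per pair at the raw
alpha, matching how the comparisons are interpreted one at a time.

The standard tests delegate to scipy; the bespoke content of this module is
the branch logic, the 3*IQR screen, and the noncentral-t power search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURES",
    "DecisionStep",
    "DecisionTrace",
    "PowerQuery",
    "outlier_screen",
    "decide_pair",
    "cohens_d",
    "power_two_sample_t",
    "min_sample_size",
    "run_univariate",
]

# the five per-specimen material parameters, in canonical column order
FEATURES = ("ut_stress_MPa", "ut_strain", "toughness_MPa", "mu_MPa", "gamma")

DEFAULT_ALPHA = 0.01
IQR_MULTIPLIER = 3.0
_EXACT_RANKSUM_MAX_N = 25


@dataclass(frozen=True)
class DecisionStep:
    test: str
    statistic: float
    p_value: float
    branch: str


@dataclass(frozen=True)
class DecisionTrace:
    """Full audit trail of one pairwise decision-tree run."""

    parameter: str
    rate_pair: tuple[float, float]
    alpha: float
    steps: tuple[DecisionStep, ...]
    conclusion: str  # "equal" | "not equal"

    @property
    def terminal(self) -> DecisionStep:
        return self.steps[-1]


@dataclass(frozen=True)
class PowerQuery:
    """Two-sample t-test power query (effect size d, alpha, target power)."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.85
    allocation_ratio: float = 1.0
    tails: str = "one"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (self.alpha < self.power < 1):
            raise ValueError("power must lie in (alpha, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size d must be positive")
        if self.allocation_ratio <= 0:
            raise ValueError("allocation ratio must be positive")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# outlier screen


def outlier_screen(
    cohort: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    multiplier: float = IQR_MULTIPLIER,
    scope: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove samples with any parameter beyond 3*IQR of its quartiles.

    Fences [Q1 - m*IQR, Q3 + m*IQR] are computed per parameter with
    linear-interpolation quantiles, by default on the pooled cohort
    (``scope="per_rate"`` recomputes them inside each rate group).  A sample
    is removed iff any of its parameters falls strictly outside its fences;
    the pass is single-shot — fences are not recomputed after removal.

    Returns ``(kept, removed)`` DataFrames preserving the input order.
    """
    if cohort.empty:
        raise ValueError("cohort must be nonempty")
    if scope not in ("pooled", "per_rate"):
        raise ValueError("scope must be 'pooled' or 'per_rate'")

    def out_mask(df: pd.DataFrame) -> pd.Series:
        mask = pd.Series(False, index=df.index)
        for feat in features:
            q1, q3 = df[feat].quantile([0.25, 0.75], interpolation="linear")
            iqr = q3 - q1
            lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
            mask |= (df[feat] < lo) | (df[feat] > hi)
        return mask

    if scope == "pooled":
        removed = out_mask(cohort)
    else:
        removed = cohort.groupby("rate_mm_per_s", group_keys=False).apply(
            out_mask, include_groups=False
        ).reindex(cohort.index)
    return cohort[~removed].copy(), cohort[removed].copy()


# ---------------------------------------------------------------------------
# decision tree


def _f_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample F-test for equality of variances."""
    fstat = np.var(x, ddof=1) / np.var(y, ddof=1)
    dfx, dfy = len(x) - 1, len(y) - 1
    p = 2.0 * min(stats.f.cdf(fstat, dfx, dfy), stats.f.sf(fstat, dfx, dfy))
    return float(fstat), float(min(p, 1.0))


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum via the Mann-Whitney U statistic.

    Exact null distribution when both groups have n <= 25 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(x) <= _EXACT_RANKSUM_MAX_N and len(y) <= _EXACT_RANKSUM_MAX_N
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _default_tests() -> dict[str, Callable]:
    return {
        "shapiro": lambda s: tuple(map(float, stats.shapiro(s))),
        "f": _f_test,
        "t_pooled": lambda x, y: tuple(map(float, stats.ttest_ind(x, y, equal_var=True))),
        "t_welch": lambda x, y: tuple(map(float, stats.ttest_ind(x, y, equal_var=False))),
        "ks": lambda x, y: tuple(map(float, stats.ks_2samp(x, y))),
        "ranksum": _ranksum,
    }


def decide_pair(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    parameter: str = "",
    rate_pair: tuple[float, float] = (float("nan"), float("nan")),
    tests: dict[str, Callable] | None = None,
) -> DecisionTrace:
    """Run the decision tree on one parameter measured in two rate groups.

    ``tests`` allows injecting alternative test callables (keyed
    ``shapiro``, ``f``, ``t_pooled``, ``t_welch``, ``ks``, ``ranksum``, each
    returning ``(statistic, p)``), which the branch-logic tests use.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    t = {**_default_tests(), **(tests or {})}

    steps: list[DecisionStep] = []
    sw_x = t["shapiro"](x)
    sw_y = t["shapiro"](y)
    both_normal = sw_x[1] > alpha and sw_y[1] > alpha
    steps.append(DecisionStep("shapiro_x", *sw_x, "normal" if sw_x[1] > alpha else "non-normal"))
    steps.append(DecisionStep("shapiro_y", *sw_y, "normal" if sw_y[1] > alpha else "non-normal"))

    if both_normal:
        fstat, fp = t["f"](x, y)
        equal_var = fp > alpha
        steps.append(DecisionStep("f_var", fstat, fp, "equal var" if equal_var else "unequal var"))
        name = "t_pooled" if equal_var else "t_welch"
        stat, p = t[name](x, y)
        steps.append(DecisionStep(name, stat, p, "terminal"))
    else:
        ks_stat, ks_p = t["ks"](x, y)
        same_shape = ks_p > alpha
        steps.append(DecisionStep("ks", ks_stat, ks_p, "same shape" if same_shape else "different shapes"))
        name = "ranksum" if same_shape else "t_welch"
        stat, p = t[name](x, y)
        steps.append(DecisionStep(name, stat, p, "terminal"))

    conclusion = "not equal" if p <= alpha else "equal"
    return DecisionTrace(parameter, tuple(rate_pair), alpha, tuple(steps), conclusion)


# ---------------------------------------------------------------------------
# effect size and power


def cohens_d(x, y) -> float:
    """Absolute standardized mean difference with the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        if np.mean(x) == np.mean(y):
            return 0.0
        raise ValueError("pooled variance is zero with unequal means: d undefined")
    return float(abs(np.mean(x) - np.mean(y)) / math.sqrt(pooled_var))


def power_two_sample_t(n1: int, query: PowerQuery) -> float:
    """Exact noncentral-t power of the two-sample t-test at group size n1.

    n2 = round(allocation_ratio * n1); noncentrality
    delta = d*sqrt(n1*n2/(n1+n2)) on df = n1+n2-2.
    """
    n2 = max(2, round(query.allocation_ratio * n1))
    if n1 < 2:
        return 0.0
    df = n1 + n2 - 2
    delta = query.effect_size * math.sqrt(n1 * n2 / (n1 + n2))
    if query.tails == "one":
        tcrit = stats.t.ppf(1 - query.alpha, df)
        return float(stats.nct.sf(tcrit, df, delta))
    tcrit = stats.t.ppf(1 - query.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta))


def min_sample_size(query: PowerQuery, n_max: int = 10**7) -> int:
    """Smallest per-group n1 whose two-sample t-test power reaches the target.

    Bracket by doubling, then bisect; power is monotone nondecreasing in n.
    """
    hi = 2
    while power_two_sample_t(hi, query) < query.power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"requested power unreachable below n = {n_max}")
    lo = max(2, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_sample_t(mid, query) >= query.power:
            hi = mid
        else:
            lo = mid + 1
    return hi


# ---------------------------------------------------------------------------
# cohort-level driver


def run_univariate(
    cohort: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    features: Sequence[str] = FEATURES,
) -> tuple[pd.DataFrame, list[DecisionTrace]]:
    """All pairwise decisions: each parameter at each pair of rates.

    The screened cohort must contain all three rate classes.  Returns a
    tidy results table (one row per parameter x rate pair, with the terminal
    test, its statistic and p-value, the conclusion and Cohen's d) together
    with the full traces.
    """
    rates = sorted(cohort["rate_mm_per_s"].unique())
    if len(rates) != 3:
        raise ValueError(f"expected 3 rate classes, found {rates}")
    groups = {r: cohort[cohort["rate_mm_per_s"] == r] for r in rates}
    pairs = [(rates[0], rates[1]), (rates[0], rates[2]), (rates[1], rates[2])]

    rows, traces = [], []
    for feat in features:
        for ra, rb in pairs:
            trace = decide_pair(
                groups[ra][feat].to_numpy(), groups[rb][feat].to_numpy(),
                alpha=alpha, parameter=feat, rate_pair=(ra, rb),
            )
            traces.append(trace)
            rows.append(
                {
                    "parameter": feat,
                    "rate_a": ra,
                    "rate_b": rb,
                    "terminal_test": trace.terminal.test,
                    "statistic": trace.terminal.statistic,
                    "p_value": trace.terminal.p_value,
                    "conclusion": trace.conclusion,
                    "cohens_d": cohens_d(groups[ra][feat], groups[rb][feat]),
                    "path": ">".join(s.test for s in trace.steps),
                }
            )
    return pd.DataFrame(rows), traces
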