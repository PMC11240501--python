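"""Group-comparison statistics: Welch's t with Bonferroni, one-way ANOVA,
and small-resample percentile bootstrap confidence intervals.

Cellularity is compared between every pair of annotation categories with
Welch's unequal-variance t-test, Bonferroni-corrected over all C(k, 2)
pairs at family-wise alpha 0.05.  Each moment of each nuclear feature is
compared across categories with a classical one-way ANOVA.  Accuracy-type
statistics get 95% percentile-bootstrap intervals from a small, fixed
number of resamples (default 50), resampling items with replacement at
full sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairwiseTestResult",
    "AnovaResult",
    "BootstrapCI",
    "welch_bonferroni",
    "one_way_anova",
    "bootstrap_ci",
    "pairwise_matrix",
]

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseTestResult:
    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    feature: str
    moment: str
    f_statistic: float
    p_value: float


@dataclass(frozen=True)
class BootstrapCI:
    statistic_name: str
    point_estimate: float
    lower_95: float
    upper_95: float
    n_resamples: int
    seed: int


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        return float(a.size + b.size - 2)
    return float(
        (va + vb) ** 2
        / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    )


def welch_bonferroni(groups: dict, alpha: float = ALPHA) -> list[PairwiseTestResult]:
    """Welch's t-test for every unordered pair, Bonferroni-corrected.

    The correction factor is the number of pairs actually tested; groups
    with fewer than two observations are skipped with a warning.  A pair of
    identical constant groups is reported as t = 0, p = 1.
    """
    usable = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            warnings.warn(f"group {name!r} has n < 2; its pairs are skipped")
            continue
        usable[name] = v
    pairs = list(combinations(sorted(usable), 2))
    m = len(pairs)
    out = []
    for a_name, b_name in pairs:
        a, b = usable[a_name], usable[b_name]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        p_adj = min(1.0, float(p) * m)
        out.append(
            PairwiseTestResult(
                group_a=a_name,
                group_b=b_name,
                t_statistic=float(t),
                degrees_of_freedom=_welch_df(a, b),
                p_raw=float(p),
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out


def pairwise_matrix(results: list[PairwiseTestResult]) -> pd.DataFrame:
    """Upper-triangular matrix of adjusted p-values, one row/column per group."""
    names = sorted({r.group_a for r in results} | {r.group_b for r in results})
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for r in results:
        mat.loc[r.group_a, r.group_b] = r.p_adjusted
    return mat


def one_way_anova(groups: dict, feature: str = "", moment: str = "") -> AnovaResult:
    """Classical between/within mean-square F test across k groups.

    Zero within-group variance everywhere with unequal means is flagged as
    an infinite F (p = 0); identical constant groups yield NaN (0/0).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(a.var(ddof=1) == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            return AnovaResult(feature, moment, np.nan, np.nan)
        return AnovaResult(feature, moment, np.inf, 0.0)
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(feature, moment, float(f), float(p))


def bootstrap_ci(
    items,
    statistic,
    n_resamples: int = 50,
    seed: int = 0,
    statistic_name: str = "statistic",
    max_redraws: int = 1000,
) -> BootstrapCI:
    """95% percentile bootstrap CI of ``statistic`` over ``items``.

    Items are resampled with replacement at full size ``n_resamples``
    times; the 2.5/97.5 percentiles of the resample statistics bound the
    interval and the full-sample value is the point estimate.  A resample
    on which the statistic is undefined (NaN or an exception) is redrawn,
    up to a bounded number of retries.
    """
    items = np.asarray(items)
    n = items.shape[0]
    if n < 2:
        raise ValueError("need >= 2 items to bootstrap")
    rng = np.random.default_rng(seed)
    point = float(statistic(items))
    values = []
    redraws = 0
    while len(values) < n_resamples:
        ix = rng.integers(0, n, size=n)
        try:
            v = float(statistic(items[ix]))
        except Exception:
            v = np.nan
        if np.isnan(v):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("statistic undefined on too many resamples")
            continue
        values.append(v)
    lower, upper = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(
        statistic_name=statistic_name,
        point_estimate=point,
        lower_95=float(lower),
        upper_95=float(upper),
        n_resamples=n_resamples,
        seed=seed,
    )


def accuracy(pairs: np.ndarray) -> float:
    """Accuracy of (truth, prediction) rows — the default bootstrap statistic."""
    return float(np.mean(pairs[:, 0] == pairs[:, 1]))
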