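"""Pattern effects on reproductive performance.

For each outcome the comparison across the five feed-intake patterns follows
a distribution-gated one-way design on independent sow-cycle records:

* gate — Kolmogorov-Smirnov normality of the one-way residuals (Lilliefors
  correction, since mean and variance are estimated) plus the median-centered
  (Brown-Forsythe) Levene test of homoscedasticity, both at alpha = 0.05;
* omnibus — a one-way fixed-effect F test when the gate passes, otherwise the
  Kruskal-Wallis rank test with tie correction;
* pairwise letters — unadjusted pairwise comparisons at alpha (pooled-MSE t
  tests on the parametric branch, Mann-Whitney rank tests otherwise),
  compressed to a compact letter display by insert-and-absorb, so groups
  sharing a letter are not significantly different;
* planned contrasts — t contrasts of unweighted set means on the one-way
  model, reported with a percent difference relative to the unweighted mean
  of the reference set.

P-values in (0.05, 0.10] are flagged as tendencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .io_records import ReproRecord

__all__ = [
    "ALPHA",
    "TENDENCY_P",
    "GateDecision",
    "GroupComparison",
    "ContrastResult",
    "group_summaries",
    "normality_and_homoscedasticity",
    "omnibus_test",
    "pairwise_letters",
    "compare_groups",
    "planned_contrast",
    "contrast_from_data",
    "derived_outcomes",
    "stillborn_pct_from_means",
    "farrowing_rate",
]

ALPHA = 0.05
TENDENCY_P = 0.10


def _split(values, groups) -> tuple[list[str], list[np.ndarray]]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    names = sorted(set(g.tolist()), key=str)
    return names, [v[g == name] for name in names]


@dataclass(frozen=True)
class GateDecision:
    """Outcome of the normality/homoscedasticity gate."""

    test_used: Literal["parametric", "kruskal_wallis"]
    ks_p: float
    levene_p: float

    @property
    def parametric(self) -> bool:
        return self.test_used == "parametric"


@dataclass(frozen=True)
class GroupComparison:
    """One outcome's five-pattern comparison: the table-row analogue."""

    variable: str
    group_names: tuple[str, ...]
    group_n: tuple[int, ...]
    group_means: tuple[float, ...]
    pooled_sem: float
    mse: float
    df_resid: int
    gate: GateDecision
    p_value: float
    letters: Mapping[str, str]
    tendency: bool


@dataclass(frozen=True)
class ContrastResult:
    """A planned contrast of two disjoint pattern sets."""

    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    estimate: float  # unweighted mean(set_a) - unweighted mean(set_b)
    percent_difference: float  # 100 * estimate / unweighted mean(set_b)
    se: float
    t_stat: float
    p_value: float


def _pooled_mse(samples: Sequence[np.ndarray]) -> tuple[float, int]:
    n_total = sum(len(s) for s in samples)
    k = len(samples)
    df = n_total - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sse = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    return sse / df, df


def group_summaries(values, groups):
    """Per-group n and mean plus the single pooled SEM of the table convention.

    The pooled SEM is sqrt(MSE / n_h) with n_h the harmonic mean of the
    group sizes, the one-SEM-column convention for unbalanced one-way tables.
    Returns ``(summary_frame, pooled_sem, mse, df_resid)``.
    """
    names, samples = _split(values, groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    mse, df = _pooled_mse(samples)
    n_h = len(samples) / sum(1.0 / len(s) for s in samples)
    sem = float(np.sqrt(mse / n_h))
    frame = pd.DataFrame(
        {
            "group": names,
            "n": [len(s) for s in samples],
            "mean": [float(s.mean()) for s in samples],
        }
    )
    return frame, sem, mse, df


def normality_and_homoscedasticity(values, groups, *, alpha: float = ALPHA) -> GateDecision:
    """Decide the analysis branch for one outcome.

    Normality is tested on the one-way residuals by Kolmogorov-Smirnov with
    the Lilliefors small-sample correction (parameters are estimated);
    homoscedasticity by the median-centered Levene test.  Both must pass at
    ``alpha`` for the parametric branch.
    """
    names, samples = _split(values, groups)
    resid = np.concatenate([s - s.mean() for s in samples])
    if np.allclose(resid, 0):
        ks_p = 1.0
    else:
        _, ks_p = lilliefors(resid, dist="norm", pvalmethod="table")
    try:
        _, levene_p = stats.levene(*samples, center="median")
    except ValueError:  # zero within-group spread
        levene_p = 1.0
    if np.isnan(levene_p):
        levene_p = 1.0
    used = "parametric" if (ks_p > alpha and levene_p > alpha) else "kruskal_wallis"
    return GateDecision(used, float(ks_p), float(levene_p))


def omnibus_test(values, groups, gate: GateDecision) -> float:
    """Omnibus p-value across groups on the branch chosen by ``gate``."""
    _, samples = _split(values, groups)
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        warnings.warn("all values identical; omnibus p set to 1", stacklevel=2)
        return 1.0
    if gate.parametric:
        return float(stats.f_oneway(*samples).pvalue)
    return float(stats.kruskal(*samples).pvalue)


def _pairwise_p(samples: Sequence[np.ndarray], i: int, j: int, parametric: bool,
                mse: float, df: int) -> float:
    a, b = samples[i], samples[j]
    if parametric:
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        if se == 0:
            return 1.0
        t = (a.mean() - b.mean()) / se
        return float(2.0 * stats.t.sf(abs(t), df))
    if np.all(np.concatenate([a, b]) == a[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _letter_display(names: Sequence[str], different: set[tuple[int, int]]) -> dict[str, str]:
    # insert-and-absorb compact letter display
    columns: list[set[int]] = [set(range(len(names)))]
    for (i, j) in sorted(different):
        new_cols: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.extend([col - {i}, col - {j}])
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = [
            c for idx, c in enumerate(new_cols)
            if c and not any(idx != jdx and c < d or (c == d and idx > jdx)
                             for jdx, d in enumerate(new_cols))
        ]
    # stable letter order: by the best (lowest-mean-rank) member
    columns.sort(key=lambda c: (min(c), -len(c)))
    letters = {name: "" for name in names}
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li)
        for idx in sorted(col):
            letters[names[idx]] += ch
    return letters


def pairwise_letters(values, groups, gate: GateDecision, *, alpha: float = ALPHA,
                     bonferroni: bool = False) -> dict[str, str]:
    """Compact letter display of all unadjusted pairwise comparisons at ``alpha``.

    Groups that share a letter are not significantly different.  With
    ``bonferroni`` the per-pair level is divided by the number of pairs.
    """
    names, samples = _split(values, groups)
    mse, df = _pooled_mse(samples)
    pairs = list(combinations(range(len(names)), 2))
    level = alpha / len(pairs) if bonferroni else alpha
    different = {
        (i, j)
        for i, j in pairs
        if _pairwise_p(samples, i, j, gate.parametric, mse, df) < level
    }
    return _letter_display(names, different)


def compare_groups(values, groups, *, variable: str = "", alpha: float = ALPHA,
                   bonferroni: bool = False) -> GroupComparison:
    """Run the full gated comparison of one outcome across patterns."""
    frame, sem, mse, df = group_summaries(values, groups)
    gate = normality_and_homoscedasticity(values, groups, alpha=alpha)
    p = omnibus_test(values, groups, gate)
    letters = pairwise_letters(values, groups, gate, alpha=alpha, bonferroni=bonferroni)
    return GroupComparison(
        variable=variable,
        group_names=tuple(frame["group"]),
        group_n=tuple(int(n) for n in frame["n"]),
        group_means=tuple(float(m) for m in frame["mean"]),
        pooled_sem=sem,
        mse=mse,
        df_resid=df,
        gate=gate,
        p_value=p,
        letters=letters,
        tendency=bool(alpha < p <= TENDENCY_P),
    )


def planned_contrast(
    group_means: Mapping[str, float],
    group_ns: Mapping[str, int],
    mse: float,
    set_a: Sequence[str],
    set_b: Sequence[str],
    *,
    df_resid: Optional[int] = None,
) -> ContrastResult:
    """Contrast of unweighted set means on the one-way model.

    The estimate is ``mean of set_a group means - mean of set_b group means``
    and the percent difference expresses it relative to the unweighted mean
    of ``set_b`` (the comparison/reference set).  The t test uses the pooled
    MSE; with ``df_resid`` omitted it is inferred from the group sizes.
    """
    set_a, set_b = tuple(set_a), tuple(set_b)
    if not set_a or not set_b:
        raise ValueError("contrast sets must be non-empty")
    if set(set_a) & set(set_b):
        raise ValueError("contrast sets must be disjoint")
    for g in (*set_a, *set_b):
        if g not in group_means or g not in group_ns:
            raise KeyError(f"unknown group {g!r}")
    mean_a = float(np.mean([group_means[g] for g in set_a]))
    mean_b = float(np.mean([group_means[g] for g in set_b]))
    estimate = mean_a - mean_b
    pct = 100.0 * estimate / mean_b if mean_b != 0 else np.nan
    coef = {g: 1.0 / len(set_a) for g in set_a}
    coef.update({g: -1.0 / len(set_b) for g in set_b})
    se = float(np.sqrt(mse * sum(c * c / group_ns[g] for g, c in coef.items())))
    if df_resid is None:
        df_resid = sum(group_ns.values()) - len(group_ns)
    if se == 0:
        t = 0.0
        p = 1.0
    else:
        t = estimate / se
        p = float(2.0 * stats.t.sf(abs(t), df_resid))
    return ContrastResult(set_a, set_b, estimate, float(pct), se, t, p)


def contrast_from_data(values, groups, set_a: Sequence[str], set_b: Sequence[str]) -> ContrastResult:
    """Convenience: :func:`planned_contrast` fed from raw per-record data."""
    frame, _, mse, df = group_summaries(values, groups)
    means = dict(zip(frame["group"], frame["mean"]))
    ns = dict(zip(frame["group"], frame["n"]))
    return planned_contrast(means, ns, mse, set_a, set_b, df_resid=df)


def derived_outcomes(records: Sequence[ReproRecord]) -> pd.DataFrame:
    """Per-record derived outcomes: stillborn %, stillborn+mummified %, PWM, weaned.

    Percentages use total born as the denominator; PWM uses the
    post-fostering start litter.  Records with ``total_born == 0`` are
    skipped with a warning.
    """
    rows = []
    skipped = 0
    for r in records:
        if r.total_born == 0:
            skipped += 1
            continue
        rows.append(
            {
                "sow_id": r.sow_id,
                "cycle": r.cycle,
                "stillborn_pct": 100.0 * r.stillborn / r.total_born,
                "sb_mum_pct": 100.0 * (r.stillborn + r.mummified) / r.total_born,
                "pwm_pct": 100.0 * (r.start_piglets - r.weaned) / r.start_piglets,
                "weaned": r.weaned,
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} record(s) with total_born == 0", stacklevel=2)
    return pd.DataFrame(rows, columns=["sow_id", "cycle", "stillborn_pct",
                                       "sb_mum_pct", "pwm_pct", "weaned"])


def stillborn_pct_from_means(stillborn_mean: float, total_born_mean: float) -> float:
    """Stillborn percentage implied by group means, rounded to one decimal."""
    if total_born_mean <= 0:
        raise ValueError("total_born_mean must be positive")
    return round(100.0 * stillborn_mean / total_born_mean, 1)


def omnibus_null_rejection_rates(
    *,
    n_reps: int = 2000,
    n_groups: int = 5,
    n_per_group: int = 40,
    alpha: float = ALPHA,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo type-I error of both omnibus branches under a global null.

    Simulates ``n_reps`` datasets of ``n_groups`` equal-mean normal groups and
    runs both the one-way F test and the Kruskal-Wallis test on each; returns
    the rejection rates at ``alpha``.  Both should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    para = GateDecision("parametric", 1.0, 1.0)
    nonp = GateDecision("kruskal_wallis", 0.0, 0.0)
    rej = {"parametric": 0, "kruskal_wallis": 0}
    for _ in range(n_reps):
        values = rng.normal(0.0, 1.0, size=groups.size)
        rej["parametric"] += omnibus_test(values, groups, para) < alpha
        rej["kruskal_wallis"] += omnibus_test(values, groups, nonp) < alpha
    return {k: v / n_reps for k, v in rej.items()}


def farrowing_rate(farrowed, groups, *, alpha: float = ALPHA):
    """Per-group farrowing rate (%) with a chi-square homogeneity test.

    Returns ``(frame, p_value, letters)``; letters come from pairwise 2x2
    chi-square tests at ``alpha``.  Groups with no bred sows are omitted
    with a warning.
    """
    f = np.asarray(farrowed, dtype=bool)
    g = np.asarray(groups)
    names = sorted(set(g.tolist()), key=str)
    rows, counts = [], []
    for name in names:
        sel = g == name
        bred = int(sel.sum())
        if bred == 0:
            warnings.warn(f"group {name!r} has no bred sows; omitted", stacklevel=2)
            continue
        far = int(f[sel].sum())
        rows.append({"group": name, "bred": bred, "farrowed": far,
                     "rate_pct": 100.0 * far / bred})
        counts.append([far, bred - far])
    frame = pd.DataFrame(rows, columns=["group", "bred", "farrowed", "rate_pct"])
    table = np.asarray(counts)
    if table.shape[0] < 2:
        raise ValueError("need at least two groups with bred sows")
    if np.any(table.sum(axis=0) == 0):  # all farrowed (or none): perfectly homogeneous
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table, correction=False).pvalue)
    kept = list(frame["group"])
    different = set()
    for i, j in combinations(range(len(kept)), 2):
        sub = table[[i, j]]
        if np.any(sub.sum(axis=0) == 0):
            continue
        pij = float(stats.chi2_contingency(sub, correction=False).pvalue)
        if pij < alpha:
            different.add((i, j))
    letters = _letter_display(kept, different)
    return frame, p, letters
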