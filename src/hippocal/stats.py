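"""Longitudinal statistics battery.

Four tests cover the chronic-imaging comparisons, plus the slice-ephys
ANOVA:

* Wilcoxon rank-sum for comparing per-cell firing-rate distributions
  between two recording dates (exact enumeration for small untied
  samples, tie-corrected normal approximation otherwise);
* Mann-Kendall trend test for monotone trends in per-mouse median rates
  across recording dates;
* paired t-test for group-level changes between two dates;
* balanced two-way repeated-measures ANOVA (group between subjects,
  recording day within subjects) for the group x time interaction;
* one-way ANOVA with Bonferroni-adjusted pairwise comparisons.

All p-values are two-sided; significance threshold alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, ParameterError

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "mann_kendall",
    "paired_t",
    "repeated_group_time_model",
    "interaction_permutation_p",
    "one_way_anova_bonferroni",
]


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: Tuple[int, ...]
    method: str = "approximate"  # "exact" | "approximate"
    tie_corrected: bool = False
    extra: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")


@lru_cache(maxsize=64)
def _rank_sum_null(n: int, m: int) -> np.ndarray:
    """Exact null distribution of the Mann-Whitney U statistic.

    ``out[u]`` is the number of rank assignments of the x-sample (size
    ``n``) among ``n + m`` untied observations giving ``U = u``.
    Standard partition-count recursion.
    """
    max_u = n * m
    # dp[i, j, u] = #ways with sample sizes (i, j); recurrence
    # N(u; i, j) = N(u - j; i - 1, j) + N(u; i, j - 1).
    dp = np.zeros((n + 1, m + 1, max_u + 1), dtype=np.float64)
    dp[0, :, 0] = 1.0
    dp[:, 0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j, :] = dp[i, j - 1, :]
            if j <= max_u:
                dp[i, j, j:] += dp[i - 1, j, : max_u + 1 - j]
            else:  # pragma: no cover - j <= max_u always when i >= 1
                pass
    return dp[n, m]


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    With ``method="auto"``, uses exact null enumeration when
    ``min(n, m) <= 8`` and the pooled sample has no ties; otherwise a
    normal approximation with tie-corrected variance and continuity
    correction.  ``method="exact"``/``"approximate"`` force a path
    (exact requires no ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    if method not in ("auto", "exact", "approximate"):
        raise ParameterError(f"unknown method {method!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    use_exact = (
        method == "exact"
        if method != "auto"
        else (not has_ties and min(n, m) <= 8)
    )
    if use_exact and has_ties:
        raise ParameterError("exact enumeration requires untied data")
    if use_exact:
        null = _rank_sum_null(n, m)
        total = null.sum()
        u_int = int(round(u))
        p_le = null[: u_int + 1].sum() / total
        p_ge = null[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(
            test_name="wilcoxon_rank_sum",
            statistic=u,
            p_value=float(p),
            n=(n, m),
            method="exact",
            tie_corrected=False,
        )

    mean_u = n * m / 2.0
    # Tie-corrected variance.
    _, tie_counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
    if var_u <= 0:
        return TestResult(
            test_name="wilcoxon_rank_sum",
            statistic=u,
            p_value=1.0,
            n=(n, m),
            method="approximate",
            tie_corrected=True,
        )
    diff = u - mean_u
    # Continuity correction toward the mean.
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_u) if diff != 0 else 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(
        test_name="wilcoxon_rank_sum",
        statistic=u,
        p_value=float(min(p, 1.0)),
        n=(n, m),
        method="approximate",
        tie_corrected=tie_term > 0,
        extra={"z": float(z)},
    )


def mann_kendall(series: Sequence[float]) -> TestResult:
    """Mann-Kendall monotone-trend test on an ordered series.

    ``S = sum_{i<j} sign(x_j - x_i)``; variance with tie correction; z
    with +/-1 continuity correction; two-sided p.  ``tau`` (reported in
    ``extra``) is ``S / (n(n-1)/2)``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ParameterError("series must have length >= 3")
    diffs = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diffs, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    tau = s / (n * (n - 1) / 2.0)
    if var_s <= 0:
        return TestResult(
            test_name="mann_kendall",
            statistic=s,
            p_value=1.0,
            n=(n,),
            method="approximate",
            tie_corrected=True,
            extra={"tau": tau, "z": 0.0},
        )
    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(
        test_name="mann_kendall",
        statistic=s,
        p_value=float(min(p, 1.0)),
        n=(n,),
        method="approximate",
        tie_corrected=tie_term > 0,
        extra={"tau": tau, "z": float(z)},
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on matched samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ParameterError("samples must be paired with length >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("paired differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    df = d.size - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        test_name="paired_t",
        statistic=t,
        p_value=float(p),
        n=(d.size,),
        method="exact",
        extra={"df": float(df)},
    )


def _check_balanced(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Listwise-exclude subjects missing any analyzed day."""
    days = sorted(table["day"].unique())
    keep = []
    for mouse, grp in table.groupby("mouse_id"):
        if set(grp["day"]) >= set(days) and grp[metric].notna().all():
            keep.append(mouse)
        else:
            warnings.warn(f"subject {mouse} excluded: incomplete days", UserWarning)
    return table[table["mouse_id"].isin(keep)].copy()


def repeated_group_time_model(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Balanced two-way repeated-measures (split-plot) ANOVA.

    ``table`` must contain columns ``group``, ``mouse_id``, ``day`` and
    the metric; each mouse contributes one value per day.  Group is the
    between-subject factor, day the within-subject factor.

    Returns a frame with one row per effect (``group``, ``time``,
    ``group:time``) carrying F, numerator/denominator df, and p.  When
    all responses are identical every F is reported as 0 with p = 1
    (no-effect convention).
    """
    required = {"group", "mouse_id", "day", metric}
    if not required <= set(table.columns):
        raise ParameterError(f"table must contain columns {sorted(required)}")
    table = _check_balanced(table, metric)
    days = sorted(table["day"].unique())
    groups = sorted(table["group"].unique())
    t = len(days)
    a = len(groups)
    if a < 2 or t < 2:
        raise ParameterError("need >= 2 groups and >= 2 days")
    n_per_group = {g: table[table["group"] == g]["mouse_id"].nunique() for g in groups}
    if min(n_per_group.values()) < 2:
        raise ParameterError("need >= 2 subjects per group")

    y = table[metric].astype(float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = table.groupby("mouse_id")[metric].mean()
    subj_group = table.groupby("mouse_id")["group"].first()
    ss_subjects = float(t * ((subj_means - grand) ** 2).sum())

    group_means = table.groupby("group")[metric].mean()
    ss_group = float(
        sum(t * n_per_group[g] * (group_means[g] - grand) ** 2 for g in groups)
    )
    ss_subj_within = ss_subjects - ss_group
    df_sw = sum(n_per_group[g] - 1 for g in groups)

    time_means = table.groupby("day")[metric].mean()
    n_total = sum(n_per_group.values())
    ss_time = float(n_total * ((time_means - grand) ** 2).sum())

    cell_means = table.groupby(["group", "day"])[metric].mean()
    ss_cells = float(
        sum(
            n_per_group[g] * (cell_means[(g, d)] - grand) ** 2
            for g in groups
            for d in days
        )
    )
    ss_int = ss_cells - ss_group - ss_time
    ss_err_within = ss_total - ss_subjects - ss_time - ss_int
    df_ew = df_sw * (t - 1)

    def effect_row(name: str, ss: float, df1: int, ss_err: float, df_err: int):
        ms = ss / df1 if df1 else 0.0
        ms_err = ss_err / df_err if df_err else 0.0
        if ms_err <= 0 or ms <= 0:
            f = 0.0
            p = 1.0
        else:
            f = ms / ms_err
            p = float(sps.f.sf(f, df1, df_err))
        return {"effect": name, "F": f, "df1": df1, "df2": df_err, "p": p}

    rows = [
        effect_row("group", ss_group, a - 1, ss_subj_within, df_sw),
        effect_row("time", ss_time, t - 1, ss_err_within, df_ew),
        effect_row("group:time", ss_int, (a - 1) * (t - 1), ss_err_within, df_ew),
    ]
    return pd.DataFrame(rows)


def interaction_permutation_p(
    table: pd.DataFrame,
    metric: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the group x time interaction.

    Group labels are permuted at the subject (mouse) level; the
    interaction F of :func:`repeated_group_time_model` is the test
    statistic.
    """
    rng = np.random.default_rng(seed)
    obs = repeated_group_time_model(table, metric)
    f_obs = float(obs.loc[obs["effect"] == "group:time", "F"].iloc[0])
    mice = table.groupby("mouse_id")["group"].first()
    labels = mice.values.copy()
    count = 0
    tbl = table.copy()
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        mapping = dict(zip(mice.index, perm))
        tbl["group"] = tbl["mouse_id"].map(mapping)
        res = repeated_group_time_model(tbl, metric)
        f = float(res.loc[res["effect"] == "group:time", "F"].iloc[0])
        if f >= f_obs:
            count += 1
    return (count + 1) / (n_permutations + 1)


def one_way_anova_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> Tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA followed by Bonferroni-adjusted pairwise t-tests.

    Pairwise two-sided p-values are multiplied by the number of
    comparisons and clipped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ParameterError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ParameterError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p = 0.0, 1.0
    omnibus = TestResult(
        test_name="one_way_anova",
        statistic=float(f_stat),
        p_value=float(min(p, 1.0)),
        n=tuple(a.size for a in arrays),
        method="exact",
    )
    k = len(arrays) * (len(arrays) - 1) // 2
    rows: List[dict] = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if np.ptp(np.concatenate([arrays[i], arrays[j]])) == 0:
                raw = 1.0
                t_stat = 0.0
            else:
                t_stat, raw = sps.ttest_ind(arrays[i], arrays[j])
            rows.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "t": float(t_stat),
                    "p_raw": float(raw),
                    "p_adjusted": float(min(1.0, raw * k)),
                }
            )
    return omnibus, pd.DataFrame(rows)
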