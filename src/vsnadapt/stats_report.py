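"""Group-comparison statistics and summary reporting.

A thin layer over established test implementations: one-way ANOVA with
Tukey's HSD, Dunnett's test against a control condition, paired t tests,
and Friedman's rank test followed by the Tukey-Nemenyi post hoc (the
Nemenyi critical-difference comparison is computed directly from rank sums
and the studentized-range distribution).  A Shapiro-Wilk normality check is
reported alongside but never enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

__all__ = [
    "GroupComparison",
    "compare_repeated_amplitudes",
    "friedman_nemenyi",
    "group_summaries",
]


@dataclass
class GroupComparison:
    """Result of an omnibus test plus optional post hoc table."""

    test_name: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None
    group_summaries: pd.DataFrame
    normality: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise AnalysisError("p_value outside [0, 1]")


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        names = [str(c) for c in matrix.columns]
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        names = [f"cond_{i + 1}" for i in range(arr.shape[1])]
    if arr.ndim != 2:
        raise AnalysisError("expected a cells x conditions matrix")
    if np.isnan(arr).any():
        raise AnalysisError("matrix contains missing entries; pairing broken")
    return arr, names


def group_summaries(arr: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Mean +/- SEM (n-1 SD) per condition; n is the number of cells."""
    n = arr.shape[0]
    sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(arr.shape[1])
    return pd.DataFrame(
        {
            "condition": names,
            "mean": arr.mean(axis=0),
            "sem": sd / np.sqrt(n),
            "n": n,
        }
    )


def _shapiro_table(arr: np.ndarray, names: list[str]) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(names):
        col = arr[:, j]
        if col.size >= 3 and np.ptp(col) > 0:
            w, p = stats.shapiro(col)
        else:
            w, p = np.nan, np.nan
        rows.append((name, w, p))
    return pd.DataFrame(rows, columns=["condition", "W", "p"])


def compare_repeated_amplitudes(matrix, family: str = "anova_tukey") -> GroupComparison:
    """Compare repeated response amplitudes across conditions.

    ``matrix`` is cells x conditions with the same cells in every column.
    ``family`` selects the omnibus/post hoc recipe: ``anova_tukey``
    (one-way ANOVA + Tukey's HSD), ``dunnett`` (each condition against the
    first column as control), or ``paired_t`` (exactly two conditions)."""
    arr, names = _as_matrix(matrix)
    k = arr.shape[1]
    if k < 2:
        raise AnalysisError("need at least 2 conditions")
    normality = _shapiro_table(arr, names)
    cols = [arr[:, j] for j in range(k)]

    if family == "paired_t":
        if k != 2:
            raise AnalysisError("paired_t requires exactly 2 conditions")
        if np.ptp(arr[:, 0] - arr[:, 1]) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(cols[0], cols[1])
        return GroupComparison("paired_t", float(t), float(p), None,
                               group_summaries(arr, names), normality)

    if family == "anova_tukey":
        if all(np.ptp(c) == 0 for c in cols) and np.ptp(arr) == 0:
            f, p = 0.0, 1.0
            posthoc = None
        else:
            f, p = stats.f_oneway(*cols)
            hsd = stats.tukey_hsd(*cols)
            rows = [
                (names[i], names[j], float(hsd.statistic[i, j]),
                 float(hsd.pvalue[i, j]))
                for i in range(k) for j in range(k) if i < j
            ]
            posthoc = pd.DataFrame(
                rows, columns=["condition_a", "condition_b", "diff", "p_adj"]
            )
        return GroupComparison("anova_tukey", float(f), float(p), posthoc,
                               group_summaries(arr, names), normality)

    if family == "dunnett":
        res = stats.dunnett(*cols[1:], control=cols[0])
        posthoc = pd.DataFrame(
            {
                "condition": names[1:],
                "control": names[0],
                "statistic": np.atleast_1d(res.statistic),
                "p_adj": np.atleast_1d(res.pvalue),
            }
        )
        stat = float(np.max(np.abs(res.statistic)))
        p = float(np.min(res.pvalue))
        return GroupComparison("dunnett", stat, p, posthoc,
                               group_summaries(arr, names), normality)

    raise AnalysisError(f"unknown test family {family!r}")


def friedman_nemenyi(matrix) -> GroupComparison:
    """Friedman's rank test across conditions (complete blocks required),
    followed by Tukey-Nemenyi pairwise comparisons on rank sums.

    The Nemenyi q statistic for conditions i, j is
    ``|R_i - R_j| / sqrt(k (k + 1) / (12 n))`` with R the mean within-cell
    rank, referred to the studentized-range distribution (infinite df)."""
    arr, names = _as_matrix(matrix)
    n, k = arr.shape
    if k < 2:
        raise AnalysisError("need at least 2 conditions")
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    mean_ranks = ranks.mean(axis=0)
    if np.ptp(arr, axis=1).max() == 0:
        # every block fully tied: no evidence of any difference
        statistic, p = 0.0, 1.0
    elif k == 2:
        # Friedman with k = 2 reduces to a sign-test-like statistic; scipy
        # requires k >= 3, so fall back to the chi-square on rank sums
        statistic = float(
            12.0 * n / (k * (k + 1)) * np.sum((mean_ranks - (k + 1) / 2.0) ** 2)
        )
        p = float(stats.chi2.sf(statistic, df=k - 1))
    else:
        statistic, p = stats.friedmanchisquare(*[arr[:, j] for j in range(k)])
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            # studentized range convention: q_sr = q * sqrt(2)
            p_adj = float(stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
            rows.append((names[i], names[j], mean_ranks[i], mean_ranks[j], q,
                         min(1.0, p_adj)))
    posthoc = pd.DataFrame(
        rows,
        columns=["condition_a", "condition_b", "mean_rank_a", "mean_rank_b",
                 "q", "p_adj"],
    )
    return GroupComparison(
        "friedman_nemenyi", float(statistic), float(p), posthoc,
        group_summaries(arr, names), _shapiro_table(arr, names),
    )


# re-exported here because reporting owns the end-to-end runner
from .workflows import run_pipeline  # noqa: E402,F401

__all__.append("run_pipeline")
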