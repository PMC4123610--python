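"""Method-concordance statistics across breast-density pathways.

Each subject contributes up to five estimates of the same quantity (one
per pathway), so agreement is summarized two ways: Pearson correlation
matrices between methods, and paired mean differences per method pair
with 95% confidence intervals and Benjamini–Hochberg false-discovery-rate
control across the family of pairs.

The paired construction (per-subject differences, paired-t intervals) is
used deliberately: the same subjects underlie every method column, so the
paired contrast removes between-subject variance that a pooled comparison
would leave in.  Missing values are handled pairwise-complete; nothing is
imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

OUTCOMES = ("pct_g", "gv_ml", "fv_ml", "tv_ml")
#: Minimum complete pairs for any statistic.
MIN_COMPLETE = 3


@dataclass(frozen=True)
class PairwiseComparison:
    """Paired mean difference (method_a - method_b) for one outcome."""

    method_a: str
    method_b: str
    n: int
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float
    significant: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_difference <= self.ci_high:
            raise ValueError("confidence interval must bracket the difference")


def load_measures(path) -> pd.DataFrame:
    """Read the long-format measures CSV into a wide (method, outcome) table."""
    long = pd.read_csv(path)
    return measures_to_wide(long)


def measures_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot long rows (subject_id, method, outcomes...) to a wide table.

    The result has subjects as the index and a (method, outcome)
    MultiIndex on the columns.
    """
    wide = long.pivot_table(
        index="subject_id", columns="method", values=list(OUTCOMES),
        aggfunc="mean",
    )
    # reorder levels to (method, outcome)
    wide = wide.swaplevel(axis=1).sort_index(axis=1)
    wide.columns.names = ["method", "outcome"]
    return wide


def _outcome_block(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Subject x method frame for one outcome."""
    if isinstance(table.columns, pd.MultiIndex):
        if outcome not in table.columns.get_level_values(-1):
            raise KeyError(f"outcome {outcome!r} not present in table")
        return table.xs(outcome, axis=1, level=-1)
    return table  # already a plain method table


def correlation_matrix(table: pd.DataFrame, outcome: str = "pct_g") -> pd.DataFrame:
    """Pearson r between every pair of methods for one outcome.

    Pairwise-complete: each cell uses the subjects observed by both
    methods; cells with fewer than :data:`MIN_COMPLETE` complete pairs are
    NaN rather than fabricated.  The matrix is symmetric with unit
    diagonal.
    """
    block = _outcome_block(table, outcome)
    r = block.corr(method="pearson", min_periods=MIN_COMPLETE)
    np.fill_diagonal(r.values, 1.0)
    return r


def paired_difference(
    table: pd.DataFrame, outcome: str, method_a: str, method_b: str
) -> pd.Series:
    """Per-subject differences ``method_a - method_b`` (complete pairs only)."""
    block = _outcome_block(table, outcome)
    return (block[method_a] - block[method_b]).dropna()


def pairwise_mean_differences(
    table: pd.DataFrame, outcome: str = "pct_g", alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Paired-t mean differences for every method pair, BH-FDR adjusted.

    Pairs with fewer than :data:`MIN_COMPLETE` complete observations are
    skipped with a warning.  With zero within-pair variance the interval
    degenerates to the observed constant difference and the p-value is 0
    (nonzero difference) or 1 (identical columns).
    """
    block = _outcome_block(table, outcome)
    methods = [m for m in block.columns if block[m].notna().any()]
    if len(methods) < 2:
        raise ValueError("at least two methods with data are required")

    raw: list[tuple[str, str, int, float, float, float, float]] = []
    for a, b in itertools.combinations(methods, 2):
        d = (block[a] - block[b]).dropna().to_numpy(dtype=float)
        n = d.size
        if n < MIN_COMPLETE:
            logger.warning(
                "skipping pair (%s, %s): only %d complete pairs", a, b, n
            )
            continue
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0.0:
            ci_low = ci_high = mean
            p = 1.0 if mean == 0.0 else 0.0
        else:
            se = sd / np.sqrt(n)
            tcrit = stats.t.ppf(0.975, n - 1)
            ci_low, ci_high = mean - tcrit * se, mean + tcrit * se
            p = float(stats.ttest_1samp(d, 0.0).pvalue)
        raw.append((a, b, n, mean, ci_low, ci_high, p))

    if not raw:
        return []
    pvals = [row[6] for row in raw]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        PairwiseComparison(
            method_a=a, method_b=b, n=n, mean_difference=mean,
            ci_low=lo, ci_high=hi, p_value=p,
            p_adjusted=float(pa), significant=bool(rej),
        )
        for (a, b, n, mean, lo, hi, p), pa, rej in zip(raw, p_adj, reject)
    ]


def comparisons_to_frame(comparisons: list[PairwiseComparison]) -> pd.DataFrame:
    """Tabulate pairwise comparisons for CSV output."""
    return pd.DataFrame(
        [
            {
                "method_a": c.method_a,
                "method_b": c.method_b,
                "n": c.n,
                "mean_difference": c.mean_difference,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
                "p_adjusted": c.p_adjusted,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )


def plot_scatter_matrix(table: pd.DataFrame, outcome: str, path) -> None:
    """Scatter-plot matrix of z-scored method columns with Pearson r labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    block = _outcome_block(table, outcome)
    z = (block - block.mean()) / block.std(ddof=1)
    axes = pd.plotting.scatter_matrix(z, figsize=(2 * len(z.columns),) * 2)
    r = correlation_matrix(table, outcome)
    cols = list(z.columns)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i != j:
                axes[i, j].set_title(f"r={r.loc[a, b]:.2f}", fontsize=7, pad=1)
    plt.suptitle(f"Method agreement: {outcome} (z-scores)")
    plt.savefig(path, dpi=120)
    plt.close("all")
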