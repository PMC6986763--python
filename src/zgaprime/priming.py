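"""Transcriptional-priming statistics.

The central question: does an increase in chromatin accessibility at a
regulatory element between early stages (256-cell to oblong) predict the
later expression of the linked gene, and is this effect carried by the
maternal factors (Pou5f3/Sox19b/Nanog) whose loss depletes accessibility?

Implemented statistics:

* quintile binning (20% bins) of accessibility increase with per-bin
  outcome distributions and one-sided Wilcoxon rank-sum tests between bins;
* the 5 x 5 priming grid crossing accessibility-increase bins with
  mutant-effect bins, each cell the median (or mean z-score) outcome;
* TF ChIP signal enrichment across mutant-effect quintiles;
* Welch comparison of element-level mutant effects between regulated and
  non-regulated target genes;
* mutant effects stratified by the bound-TF combination (P, S, N, PS, PN,
  SN, PSN).

Quantile bins are equal-frequency: items are stably sorted by (value, id)
and split so bin sizes differ by at most one, ties going to the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic_name: str
    statistic: float
    p_value: float
    direction: str


# ---------------------------------------------------------------------------
# rank tests

def _rank_sum_exact(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact one/two-sided rank-sum p-value by enumeration of all
    assignments of the pooled (mid-)ranks to group a."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    stats_all = np.array([sum(ranks[list(idx)])
                          for idx in combinations(range(len(pooled)), n_a)])
    eps = 1e-9
    if alternative == "greater":        # a stochastically greater
        p = np.mean(stats_all >= obs - eps)
    elif alternative == "less":
        p = np.mean(stats_all <= obs + eps)
    else:
        hi = np.mean(stats_all >= obs - eps)
        lo = np.mean(stats_all <= obs + eps)
        p = min(1.0, 2 * min(hi, lo))
    return float(p)


def wilcoxon_one_sided(sample_a, sample_b, alternative: str = "greater",
                       exact_max_n: int = 8) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test of a against b.

    ``alternative='greater'`` tests whether a is stochastically greater
    than b.  Exact enumeration over all rank assignments is used when both
    samples have <= ``exact_max_n`` observations; otherwise the
    tie-corrected normal approximation (with continuity correction).  When
    every pooled value is tied the test is uninformative and p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        import warnings
        warnings.warn("all values tied across both samples; p = 1")
        return GroupComparison("a", "b", "wilcoxon_one_sided", 0.0, 1.0, alternative)
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        p = _rank_sum_exact(a, b, alternative)
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        return GroupComparison("a", "b", "wilcoxon_exact", float(u), p, alternative)
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return GroupComparison("a", "b", "wilcoxon_normal", float(res.statistic),
                           float(res.pvalue), alternative)


# ---------------------------------------------------------------------------
# quantile binning

def quantile_bins(values, n_bins: int = 5, ids=None) -> np.ndarray:
    """Equal-frequency bin index 1..n_bins per item.

    Items are stably sorted by (value, id) and cut into bins whose sizes
    differ by at most one; ties at bin boundaries therefore go to the lower
    bin, and the result is invariant to input order.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} items, got {n}")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), values))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins // n) + 1


def quintile_outcome(delta_access, outcome, n_bins: int = 5,
                     min_items: int = 10, ids=None):
    """Outcome distributions by accessibility-increase quintile.

    Returns ``(summary, tests)``: per-bin n/median/mean, and one-sided
    Wilcoxon tests (higher bin stochastically greater) for all adjacent bin
    pairs plus bin 1 vs bin ``n_bins``.
    """
    delta_access = np.asarray(delta_access, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if len(delta_access) < min_items:
        raise ValueError(f"refusing to bin {len(delta_access)} items into "
                         f"{n_bins} quantile bins (min_items={min_items})")
    bins = quantile_bins(delta_access, n_bins=n_bins, ids=ids)
    summary = pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "n": [int((bins == b).sum()) for b in range(1, n_bins + 1)],
        "median_outcome": [float(np.median(outcome[bins == b])) for b in range(1, n_bins + 1)],
        "mean_outcome": [float(np.mean(outcome[bins == b])) for b in range(1, n_bins + 1)],
    })
    pairs = [(b, b + 1) for b in range(1, n_bins)] + [(1, n_bins)]
    tests = []
    for lo, hi in pairs:
        cmp = wilcoxon_one_sided(outcome[bins == hi], outcome[bins == lo], "greater")
        tests.append((lo, hi, cmp.statistic_name, cmp.statistic, cmp.p_value))
    tests = pd.DataFrame(tests, columns=["bin_low", "bin_high", "test", "statistic", "p_value"])
    return summary, tests


def priming_grid(delta_access, mutant_log2fc, outcome, statistic: str = "median",
                 n_bins: int = 5, ids=None):
    """5 x 5 grid: rows = mutant-effect bins, columns = increase bins.

    Row bin 1 holds the most negative mutant log2 fold changes (largest
    loss); column bin ``n_bins`` the largest accessibility increases.  Cell
    values are the median outcome (``statistic='median'``) or the mean of
    the z-scored outcome (``statistic='zscore'``, z-scoring across all items
    before aggregation).  Returns ``(grid, counts)`` DataFrames; empty
    cells are NaN, with count 0.
    """
    delta_access = np.asarray(delta_access, dtype=float)
    mutant_log2fc = np.asarray(mutant_log2fc, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    col = quantile_bins(delta_access, n_bins=n_bins, ids=ids)
    row = quantile_bins(mutant_log2fc, n_bins=n_bins, ids=ids)
    if statistic == "zscore":
        outcome = (outcome - outcome.mean()) / outcome.std(ddof=0)
        agg = np.mean
    elif statistic == "median":
        agg = np.median
    elif statistic == "mean":
        agg = np.mean
    else:
        raise ValueError("statistic must be 'median', 'mean' or 'zscore'")
    grid = np.full((n_bins, n_bins), np.nan)
    counts = np.zeros((n_bins, n_bins), dtype=int)
    for r in range(1, n_bins + 1):
        for c in range(1, n_bins + 1):
            sel = (row == r) & (col == c)
            counts[r - 1, c - 1] = int(sel.sum())
            if sel.any():
                grid[r - 1, c - 1] = float(agg(outcome[sel]))
    idx = [f"effect_bin{r}" for r in range(1, n_bins + 1)]
    cols = [f"increase_bin{c}" for c in range(1, n_bins + 1)]
    return (pd.DataFrame(grid, index=idx, columns=cols),
            pd.DataFrame(counts, index=idx, columns=cols))


def tf_enrichment_by_bin(mutant_log2fc, tf_signal, input_signal=None,
                         normalization: str = "chip_over_input",
                         n_bins: int = 5, ids=None):
    """TF binding signal across mutant-effect quintiles.

    Bin 1 holds the regions with the greatest accessibility loss in the
    mutants.  ``normalization='chip_over_input'`` divides by a matched
    input signal; ``'genome_mean'`` divides by the mean over all regions
    (for factors lacking an input library).  Returns ``(summary, tests)``
    with one-sided Wilcoxon tests that greater-loss bins carry higher
    signal (each bin vs the last bin, and adjacent pairs).
    """
    mutant_log2fc = np.asarray(mutant_log2fc, dtype=float)
    tf_signal = np.asarray(tf_signal, dtype=float)
    if normalization == "chip_over_input":
        if input_signal is None:
            raise ValueError("no input signal available: use normalization='genome_mean'")
        signal = tf_signal / np.asarray(input_signal, dtype=float)
    elif normalization == "genome_mean":
        signal = tf_signal / tf_signal.mean()
    else:
        raise ValueError("normalization must be 'chip_over_input' or 'genome_mean'")
    bins = quantile_bins(mutant_log2fc, n_bins=n_bins, ids=ids)
    summary = pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "n": [int((bins == b).sum()) for b in range(1, n_bins + 1)],
        "median_signal": [float(np.median(signal[bins == b])) for b in range(1, n_bins + 1)],
    })
    tests = []
    pairs = [(b, b + 1) for b in range(1, n_bins)] + [(1, n_bins)]
    for lo, hi in pairs:
        cmp = wilcoxon_one_sided(signal[bins == lo], signal[bins == hi], "greater")
        tests.append((lo, hi, cmp.statistic, cmp.p_value))
    tests = pd.DataFrame(tests, columns=["bin_loss", "bin_other", "statistic", "p_value"])
    return summary, tests


def mutant_effect_by_target(mutant_log2fc, regulated_flag) -> GroupComparison:
    """Welch t-test of element log2FC between regulated and non-regulated
    target genes (one-sided: regulated more depleted)."""
    mutant_log2fc = np.asarray(mutant_log2fc, dtype=float)
    regulated = np.asarray(regulated_flag, dtype=bool)
    a = mutant_log2fc[regulated]
    b = mutant_log2fc[~regulated]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each gene class needs >= 2 elements")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return GroupComparison("regulated", "not_regulated", "welch_t",
                           float(res.statistic), float(res.pvalue), "less")


def bound_site_effect_by_combination(mutant_log2fc, bound_sets,
                                     tf_order=("Pou5f1", "Sox2", "Nanog")):
    """Mutant-effect distributions per bound-TF combination.

    Groups the 7 non-empty subsets of the three core factors (P, S, N, PS,
    PN, SN, PSN) plus the unbound reference; empty groups are skipped.
    Returns ``(summary, tests)`` where tests compare every bound
    combination against the unbound reference (one-sided: bound more
    depleted).
    """
    mutant_log2fc = np.asarray(mutant_log2fc, dtype=float)
    short = {tf: tf[0].upper() for tf in tf_order}
    labels = []
    for bset in bound_sets:
        members = [tf for tf in tf_order if tf in bset]
        labels.append("".join(short[tf] for tf in members) if members else "unbound")
    labels = np.array(labels)
    combos = ["P", "S", "N", "PS", "PN", "SN", "PSN"]
    rows, tests = [], []
    unbound = mutant_log2fc[labels == "unbound"]
    rows.append(("unbound", len(unbound),
                 float(np.median(unbound)) if len(unbound) else np.nan))
    for combo in combos:
        vals = mutant_log2fc[labels == combo]
        if len(vals) == 0:
            continue
        rows.append((combo, len(vals), float(np.median(vals))))
        if len(unbound) > 0:
            cmp = wilcoxon_one_sided(vals, unbound, "less")
            tests.append((combo, "unbound", cmp.statistic, cmp.p_value))
    summary = pd.DataFrame(rows, columns=["combination", "n", "median_log2fc"])
    tests = pd.DataFrame(tests, columns=["group", "reference", "statistic", "p_value"])
    return summary, tests


def paired_t_one_sided(before, after) -> GroupComparison:
    """Paired one-sided t-test that ``after`` is lower than ``before``
    (accessibility loss in mutants at matched elements)."""
    res = stats.ttest_rel(np.asarray(after, float), np.asarray(before, float),
                          alternative="less")
    return GroupComparison("after", "before", "paired_t",
                           float(res.statistic), float(res.pvalue), "less")
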