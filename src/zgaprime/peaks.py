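"""Accessible-region calling against a genomic-DNA control, replicate
confirmation, and cross-stage consensus peaks.

The caller is a per-bin Poisson enrichment test: the control (a naked-DNA
Tn5 digestion) is scaled to the treatment library, a local background rate
is estimated per bin and floored at the genome-wide control mean, and the
upper-tail Poisson p-value of the treatment count is BH-adjusted across all
bins.  Significant bins are merged within a gap tolerance and short peaks
discarded.  All interval overlap logic is strict >= 1 shared base under
0-based half-open arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .fragments import CoverageTrack

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "summit"]


def call_peaks(treatment: CoverageTrack, control: CoverageTrack,
               fdr: float = 0.05, min_width: int = 100,
               gap_bins: int = 1, local_bins: int = 50,
               name_prefix: str = "peak") -> pd.DataFrame:
    """Poisson enrichment peaks of treatment counts over a control track.

    Per bin, lambda is the maximum of the locally averaged scaled-control
    rate (window of ``2*local_bins+1`` bins) and the genome-wide scaled
    control mean; p = P(Poisson(lambda) >= count).  BH at ``fdr`` across all
    bins; runs of significant bins separated by <= ``gap_bins`` are merged;
    peaks narrower than ``min_width`` bp are dropped.  The summit is the bp
    offset of the maximum treatment bin (bin center).
    """
    if not treatment.same_grid(control):
        raise ValueError("treatment and control must share a bin grid")
    t_total, c_total = treatment.total(), control.total()
    if t_total == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    scale = t_total / c_total if c_total > 0 else 0.0

    chroms = list(treatment.values)
    t_all = np.concatenate([treatment.values[c] for c in chroms])
    genome_mean = max(float(t_all.mean()), 1e-9) if c_total == 0 else \
        max(float(np.concatenate([control.values[c] for c in chroms]).mean()) * scale, 1e-9)

    rows = []
    bs = treatment.bin_size
    pvals, keys = [], []
    for chrom in chroms:
        t = treatment.values[chrom]
        c = control.values[chrom] * scale
        lam = ndimage.uniform_filter1d(c, size=2 * local_bins + 1, mode="nearest")
        lam = np.maximum(lam, genome_mean)
        p = stats.poisson.sf(t - 1, lam)     # P(X >= t)
        p[t <= lam] = 1.0                    # only enrichment is of interest
        pvals.append(p)
        keys.append((chrom, len(t)))
    p_flat = np.concatenate(pvals)
    reject, q_flat, _, _ = multipletests(p_flat, alpha=fdr, method="fdr_bh")

    offset = 0
    for chrom, n in keys:
        rej = reject[offset:offset + n]
        q = q_flat[offset:offset + n]
        t = treatment.values[chrom]
        offset += n
        if not rej.any():
            continue
        # merge significant bins across gaps <= gap_bins
        filled = rej.copy()
        if gap_bins > 0:
            idx = np.flatnonzero(rej)
            gaps = np.diff(idx)
            for i, g in zip(idx[:-1], gaps):
                if 1 < g <= gap_bins + 1:
                    filled[i:i + g] = True
        lab, nlab = ndimage.label(filled)
        for k in range(1, nlab + 1):
            bins = np.flatnonzero(lab == k)
            start, end = int(bins[0]) * bs, (int(bins[-1]) + 1) * bs
            end = min(end, treatment.chrom_sizes[chrom])
            if end - start < min_width:
                continue
            summit_bin = bins[np.argmax(t[bins])]
            summit = int(summit_bin - bins[0]) * bs + bs // 2
            score = float(-np.log10(max(q[bins].min(), 1e-300)))
            rows.append((chrom, start, end, "", score, min(summit, end - start - 1)))
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    df["name"] = [f"{name_prefix}_{i}" for i in range(len(df))]
    return df


def _overlaps_any(peaks: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    """Boolean per row of ``peaks``: overlaps >= 1 bp with any row of ``others``."""
    hit = np.zeros(len(peaks), dtype=bool)
    by_chrom = {c: g.sort_values("start") for c, g in others.groupby("chrom", observed=True)} \
        if len(others) else {}
    for chrom, grp in peaks.groupby("chrom", observed=True):
        o = by_chrom.get(chrom)
        if o is None:
            continue
        o_starts = o["start"].to_numpy()
        # max end seen up to each sorted interval handles nested intervals
        o_maxend = np.maximum.accumulate(o["end"].to_numpy())
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        # candidate: any other-interval with start < e and running max end > s
        i = np.searchsorted(o_starts, e, side="left")  # intervals starting before e
        ok = (i > 0) & (np.where(i > 0, o_maxend[np.maximum(i - 1, 0)], 0) > s)
        hit[peaks.index.get_indexer(grp.index)] = ok
    return hit


def confirm_replicated(pooled: pd.DataFrame,
                       replicate_peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Keep pooled peaks confirmed (>= 1 bp overlap) in every replicate."""
    if not replicate_peak_sets:
        raise ValueError("need at least one replicate peak set")
    keep = np.ones(len(pooled), dtype=bool)
    pooled = pooled.reset_index(drop=True)
    for rep in replicate_peak_sets:
        keep &= _overlaps_any(pooled, rep)
    return pooled[keep].reset_index(drop=True)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Single-linkage merge at >= 1 bp overlap (abutting intervals stay apart)."""
    rows = []
    for chrom, grp in intervals.groupby("chrom", observed=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        cur_s = cur_e = None
        for s, e in grp[["start", "end"]].to_numpy():
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:          # strict: >= 1 shared base
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def build_consensus(stage_peak_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge replicated peaks from all stages; flag per-stage presence.

    Returns the consensus intervals with a ``name`` column plus one boolean
    ``present_<stage>`` column per stage: true iff the consensus interval
    overlaps (>= 1 bp) a replicated peak called in that stage.
    """
    non_empty = [df for df in stage_peak_sets.values() if len(df)]
    if not non_empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    merged = merge_intervals(pd.concat(non_empty, ignore_index=True)[["chrom", "start", "end"]])
    merged["name"] = [f"consensus_{i}" for i in range(len(merged))]
    for stage, peaks in stage_peak_sets.items():
        merged[f"present_{stage}"] = _overlaps_any(merged, peaks)
    return merged
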