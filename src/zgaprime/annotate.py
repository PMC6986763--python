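"""Regulatory-element definition and enhancer-gene linking.

Promoters are 2 kb windows centered on the TSS.  Putative enhancers are
distal consensus peaks (>= 1 kb from every TSS) overlapping at least one
core pluripotency-factor ChIP peak (Pou5f1/Pou5f3, Sox2/SoxB1 or Nanog) and
at least one additional developmental TF ChIP peak (Smad2, FoxH1, Mxtx2,
Eomesodermin, Ta, Tbx16 or Mixl1).  Elements are linked to the nearest TSS
within 20 kb.  The distance between an interval and a TSS is 0 when the
TSS falls inside the interval, otherwise the gap to the nearest edge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PROMOTER_WINDOW = 2000
DISTAL_MIN = 1000
LINK_MAX = 20_000


def define_promoters(tss: pd.DataFrame, window: int = PROMOTER_WINDOW,
                     chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """One ``window``-wide promoter centered on each TSS, clipped at
    chromosome bounds (clipped rows flagged)."""
    half = window // 2
    out = pd.DataFrame({
        "element_id": "prom_" + tss["gene_id"].astype(str),
        "chrom": tss["chrom"],
        "start": tss["tss"] - half,
        "end": tss["tss"] + half,
        "element_class": "promoter",
        "gene_id": tss["gene_id"],
        "strand": tss["strand"] if "strand" in tss.columns else "+",
    })
    clipped = out["start"] < 0
    out["start"] = out["start"].clip(lower=0)
    if chrom_sizes is not None:
        limits = out["chrom"].map(chrom_sizes)
        clipped |= out["end"] > limits
        out["end"] = np.minimum(out["end"], limits)
    out["clipped"] = clipped
    return out.reset_index(drop=True)


def tss_distance(intervals: pd.DataFrame, tss: pd.DataFrame
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each interval to its nearest TSS, plus that gene.

    Distance is 0 if a TSS lies inside the interval, else the gap to the
    nearest interval edge.  Ties (two TSSs equidistant) are broken by lower
    TSS coordinate, then lexicographic gene id.
    """
    dist = np.full(len(intervals), np.inf)
    gene = np.array([""] * len(intervals), dtype=object)
    tsorted = tss.sort_values(["chrom", "tss", "gene_id"], kind="stable")
    by_chrom = {c: g for c, g in tsorted.groupby("chrom", observed=True)}
    for chrom, grp in intervals.groupby("chrom", observed=True):
        t = by_chrom.get(chrom)
        if t is None:
            continue
        pos = t["tss"].to_numpy()
        gids = t["gene_id"].to_numpy()
        for i, (s, e) in zip(grp.index, grp[["start", "end"]].to_numpy()):
            j = np.searchsorted(pos, s)
            # candidates: nearest TSS left of start, any inside, nearest right
            inside = pos[(pos >= s) & (pos < e)]
            if len(inside):
                k = np.searchsorted(pos, inside[0])
                dist[intervals.index.get_loc(i)] = 0
                gene[intervals.index.get_loc(i)] = gids[k]
                continue
            best_d, best_pos, best_g = np.inf, None, None
            for k in (j - 1, j):
                if 0 <= k < len(pos):
                    p = pos[k]
                    d = s - p if p < s else p - (e - 1)
                    if (d < best_d) or (d == best_d and (p, gids[k]) < (best_pos, best_g)):
                        best_d, best_pos, best_g = d, p, gids[k]
            loc = intervals.index.get_loc(i)
            dist[loc] = best_d
            gene[loc] = best_g if best_g is not None else ""
    return dist, gene


def _overlap_support(peaks: pd.DataFrame, chip_sets: dict[str, pd.DataFrame]) -> pd.Series:
    """Per peak, the comma-joined subset of TFs whose ChIP peaks overlap it."""
    from .peaks import _overlaps_any

    support = [[] for _ in range(len(peaks))]
    for tf, chip in chip_sets.items():
        if chip is None or not len(chip):
            continue
        hit = _overlaps_any(peaks.reset_index(drop=True), chip)
        for i in np.flatnonzero(hit):
            support[i].append(tf)
    return pd.Series([",".join(s) for s in support], index=peaks.index)


def define_enhancers(consensus: pd.DataFrame, tss: pd.DataFrame,
                     core_chip: dict[str, pd.DataFrame],
                     dev_chip: dict[str, pd.DataFrame],
                     distal_min: int = DISTAL_MIN) -> pd.DataFrame:
    """Distal, doubly-ChIP-supported consensus peaks.

    Kept iff the peak is >= ``distal_min`` bp from every TSS and overlaps
    (>= 1 bp) at least one core-TF and at least one developmental-TF ChIP
    peak; supporting TFs are recorded.  Empty ChIP collections yield an
    empty enhancer set (with a warning).
    """
    import warnings

    consensus = consensus.reset_index(drop=True)
    if not any(len(df) for df in core_chip.values()) or \
       not any(len(df) for df in dev_chip.values()):
        warnings.warn("empty ChIP peak collection: no enhancers can be supported")
        return consensus.head(0).assign(element_class="enhancer",
                                        core_support="", dev_support="")
    dist, _ = tss_distance(consensus, tss)
    distal = dist >= distal_min
    core = _overlap_support(consensus, core_chip)
    dev = _overlap_support(consensus, dev_chip)
    keep = distal & (core != "") & (dev != "")
    out = consensus[keep].copy()
    out["element_class"] = "enhancer"
    out["core_support"] = core[keep]
    out["dev_support"] = dev[keep]
    out["element_id"] = "enh_" + out["name"].astype(str) if "name" in out.columns \
        else ["enh_%d" % i for i in range(len(out))]
    return out.reset_index(drop=True)


def link_to_genes(elements: pd.DataFrame, tss: pd.DataFrame,
                  link_max: int = LINK_MAX) -> pd.DataFrame:
    """Assign each element to its nearest TSS if within ``link_max`` bp.

    Returns element_id, gene_id, distance; unlinked elements are omitted.
    """
    dist, gene = tss_distance(elements, tss)
    ids = elements["element_id"] if "element_id" in elements.columns else elements["name"]
    out = pd.DataFrame({"element_id": ids.to_numpy(), "gene_id": gene,
                        "distance": dist})
    out = out[(out["distance"] <= link_max) & (out["gene_id"] != "")]
    out["distance"] = out["distance"].astype(int)
    return out.reset_index(drop=True)


def classify_gene_sets(expression: pd.DataFrame, stages: list[str],
                       expressed_min: float = 1.0, silent_max: float = 0.1,
                       reference_stage: str = "sphere",
                       later_stage: str = "shield") -> pd.DataFrame:
    """Per-stage expressed flags plus late-activated and never-expressed sets.

    A gene is expressed at a stage when RPKM >= ``expressed_min``;
    late-activated when expressed at ``later_stage`` but not at
    ``reference_stage``; never-expressed when its summed RPKM over all
    stages is below ``silent_max``.
    """
    missing = [s for s in stages if s not in expression.columns]
    if missing:
        raise ValueError(f"expression table lacks stage columns: {missing}")
    out = pd.DataFrame({"gene_id": expression["gene_id"]})
    for s in stages:
        out[f"expressed_{s}"] = expression[s] >= expressed_min
    out["late_activated"] = out[f"expressed_{later_stage}"] & ~out[f"expressed_{reference_stage}"]
    out["never_expressed"] = expression[stages].sum(axis=1) < silent_max
    return out
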