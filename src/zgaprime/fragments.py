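"""ATAC fragment processing: Tn5 cut-site correction, nucleosome-free
splitting, coverage tracks and region signal matrices.

Fragments are DataFrames with ``chrom``, ``start``, ``end`` (0-based,
half-open) and optionally ``mapq`` and ``strand``.  The Tn5 transposase
inserts in a staggered fashion, so alignment ends are shifted +4 bp (start)
and -5 bp (end) to recover insertion points; fragments whose adjusted
length would be < 1 are dropped and counted.  Sub-nucleosomal fragments
(length <= 130 bp after adjustment) mark nucleosome-free regions (NFR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NFR_CUTOFF = 130
TN5_SHIFT_START = 4
TN5_SHIFT_END = 5


def adjust_cut_sites(fragments: pd.DataFrame, min_mapq: int | None = None
                     ) -> tuple[pd.DataFrame, int]:
    """Apply the +4/-5 bp Tn5 cut-site correction.

    Returns ``(adjusted, n_dropped)``; degenerate fragments (adjusted
    length < 1) are dropped, and rows failing an optional mapq filter are
    excluded before adjustment (not counted as dropped).
    """
    if (fragments["start"] >= fragments["end"]).any():
        raise ValueError("fragment with start >= end")
    df = fragments
    if min_mapq is not None and "mapq" in df.columns:
        df = df[df["mapq"] >= min_mapq]
    df = df.copy()
    df["start"] = df["start"] + TN5_SHIFT_START
    df["end"] = df["end"] - TN5_SHIFT_END
    keep = df["start"] < df["end"]
    n_dropped = int((~keep).sum())
    df = df[keep].reset_index(drop=True)
    df["length"] = df["end"] - df["start"]
    return df, n_dropped


def split_by_size(adjusted: pd.DataFrame, nfr_cutoff: int = NFR_CUTOFF
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition adjusted fragments into (NFR, nucleosomal) by length.

    A fragment is NFR iff its adjusted length <= ``nfr_cutoff``.
    """
    if nfr_cutoff < 1:
        raise ValueError("nfr_cutoff must be >= 1")
    length = adjusted["length"] if "length" in adjusted.columns \
        else adjusted["end"] - adjusted["start"]
    is_nfr = length <= nfr_cutoff
    return (adjusted[is_nfr].reset_index(drop=True),
            adjusted[~is_nfr].reset_index(drop=True))


def length_histogram(adjusted: pd.DataFrame, max_length: int = 600) -> pd.DataFrame:
    """Fragment-length histogram used to inspect the NFR cutoff choice."""
    length = (adjusted["length"] if "length" in adjusted.columns
              else adjusted["end"] - adjusted["start"]).clip(upper=max_length)
    counts = length.value_counts().sort_index()
    return pd.DataFrame({"length": counts.index, "count": counts.to_numpy()})


@dataclass
class CoverageTrack:
    """Fixed-bin genomic signal; ``values[chrom][i]`` covers
    ``[i*bin_size, (i+1)*bin_size)``."""

    values: dict[str, np.ndarray]
    bin_size: int
    chrom_sizes: dict[str, int]
    normalization: str = "raw"
    library_size: int | None = None
    n_clipped: int = 0
    fragment_filter: str = "all"
    meta: dict = field(default_factory=dict)

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (self.bin_size == other.bin_size
                and self.chrom_sizes == other.chrom_sizes)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def _n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


def make_coverage(fragments: pd.DataFrame, chrom_sizes: dict[str, int],
                  bin_size: int = 20, normalization: str = "rpkm",
                  library_size: int | None = None,
                  fragment_filter: str = "all") -> CoverageTrack:
    """Full-fragment-width coverage at fixed bin size.

    Each bin accumulates the number of fragment bases overlapping it
    (fragments extended to their full width).  With ``normalization='rpkm'``
    bins are scaled by ``1e9 / (bin_size * library_size)``: the mean
    fragment depth in the bin, per kilobase of bin, per million library
    fragments.  Fragments extending past chromosome ends are clipped and
    counted in ``n_clipped``.
    """
    if normalization not in ("raw", "rpkm"):
        raise ValueError("normalization must be 'raw' or 'rpkm'")
    if library_size is None:
        library_size = len(fragments)
    values: dict[str, np.ndarray] = {}
    n_clipped = 0
    groups = dict(iter(fragments.groupby("chrom", observed=True))) if len(fragments) else {}
    for chrom, size in chrom_sizes.items():
        nb = _n_bins(size, bin_size)
        base = np.zeros(nb * bin_size + 1)
        sub = groups.get(chrom)
        if sub is not None and len(sub):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            clipped = (starts < 0) | (ends > size)
            n_clipped += int(clipped.sum())
            starts = np.clip(starts, 0, size)
            ends = np.clip(ends, 0, size)
            np.add.at(base, starts, 1.0)
            np.add.at(base, ends, -1.0)
        depth = np.cumsum(base[:-1])
        values[chrom] = depth.reshape(nb, bin_size).sum(axis=1)
    if normalization == "rpkm":
        scale = 1e9 / (bin_size * max(library_size, 1))
        values = {c: v * scale for c, v in values.items()}
    return CoverageTrack(values=values, bin_size=bin_size, chrom_sizes=dict(chrom_sizes),
                         normalization=normalization, library_size=library_size,
                         n_clipped=n_clipped, fragment_filter=fragment_filter)


def event_count_track(fragments: pd.DataFrame, chrom_sizes: dict[str, int],
                      bin_size: int = 20, point: str = "midpoint") -> CoverageTrack:
    """Integer per-bin counts of one point event per fragment.

    Counting a single point (midpoint by default) per fragment gives
    approximately independent per-bin counts, which is what the Poisson
    enrichment caller consumes; full-width coverage would spread every
    fragment over several bins and break the count model.
    """
    values = {}
    groups = dict(iter(fragments.groupby("chrom", observed=True))) if len(fragments) else {}
    for chrom, size in chrom_sizes.items():
        nb = _n_bins(size, bin_size)
        arr = np.zeros(nb)
        sub = groups.get(chrom)
        if sub is not None and len(sub):
            if point == "midpoint":
                pos = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            elif point == "start":
                pos = sub["start"].to_numpy()
            else:
                raise ValueError("point must be 'midpoint' or 'start'")
            pos = np.clip(pos, 0, size - 1)
            np.add.at(arr, pos // bin_size, 1.0)
        values[chrom] = arr
    return CoverageTrack(values=values, bin_size=bin_size, chrom_sizes=dict(chrom_sizes),
                         normalization="raw", library_size=len(fragments))


def log2_ratio_track(track_a: CoverageTrack, track_b: CoverageTrack,
                     pseudocount: float = 1.0) -> CoverageTrack:
    """Per-bin ``log2((a + eps) / (b + eps))`` on a shared grid."""
    if not track_a.same_grid(track_b):
        raise ValueError("tracks are on different bin grids")
    values = {c: np.log2((track_a.values[c] + pseudocount)
                         / (track_b.values[c] + pseudocount))
              for c in track_a.values}
    return CoverageTrack(values=values, bin_size=track_a.bin_size,
                         chrom_sizes=dict(track_a.chrom_sizes),
                         normalization=f"log2_ratio(eps={pseudocount})")


def region_matrix(track: CoverageTrack, regions: pd.DataFrame,
                  anchor: str = "center", window_bp: int = 2000,
                  target_width_bp: int = 1000, fill: float = 0.0) -> np.ndarray:
    """Region x positional-bin signal matrix from a coverage track.

    ``anchor='center'``: a fixed ``window_bp`` window centered on the
    region's anchor point (``anchor_pos`` column if present, else the
    midpoint), minus-strand rows reversed, out-of-chromosome bins filled
    with ``fill``.  ``anchor='scale'``: each region's bins linearly
    resampled to represent ``target_width_bp``.
    """
    bs = track.bin_size
    if anchor == "center":
        ncol = window_bp // bs
    elif anchor == "scale":
        ncol = target_width_bp // bs
    else:
        raise ValueError("anchor must be 'center' or 'scale'")
    out = np.full((len(regions), ncol), fill, dtype=float)
    strands = regions["strand"].to_numpy() if "strand" in regions.columns \
        else np.array(["+"] * len(regions))
    for i, row in enumerate(regions.itertuples()):
        vals = track.values[row.chrom]
        if anchor == "center":
            point = getattr(row, "anchor_pos", None)
            if point is None or (isinstance(point, float) and np.isnan(point)):
                point = (row.start + row.end) // 2
            first = int(point) // bs - ncol // 2
            lo, hi = max(first, 0), min(first + ncol, len(vals))
            if hi > lo:
                out[i, lo - first: hi - first] = vals[lo:hi]
        else:
            b0, b1 = row.start // bs, max(-(-row.end // bs), row.start // bs + 1)
            seg = vals[b0:b1]
            if len(seg) == ncol:
                out[i] = seg
            elif len(seg) > 0:
                x_src = np.linspace(0.0, 1.0, num=len(seg))
                x_dst = np.linspace(0.0, 1.0, num=ncol)
                out[i] = np.interp(x_dst, x_src, seg)
        if strands[i] == "-":
            out[i] = out[i, ::-1]
    return out
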