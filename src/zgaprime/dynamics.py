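"""Accessibility-trajectory clustering and summary profiles.

Peaks x stages FPKM matrices are clustered with k-means (k = 5, 10 random
starts, up to 1000 iterations by default), labels are renumbered by
descending final-stage centroid so cluster 1 is the most open at the end
of the time course, and the fraction of total variance explained by the
between-cluster differences is reported alongside the exact decomposition
identity (between + within = total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ClusterResult:
    labels: np.ndarray                 # 1..k per row
    centroids: np.ndarray              # k x n_stages (after relabelling)
    between_variance_fraction: float
    total_ss: float
    between_ss: float
    within_ss: float
    k: int
    n_starts: int
    max_iter: int
    seed: int | None


def cluster_dynamics(matrix: pd.DataFrame | np.ndarray, k: int = 5,
                     n_starts: int = 10, max_iter: int = 1000,
                     seed: int | None = 0, log_transform: bool = False
                     ) -> ClusterResult:
    """K-means over per-peak stage trajectories; best of ``n_starts``.

    ``log_transform`` clusters log2(x+1) values instead of raw FPKM.
    Labels are renumbered by descending centroid value at the last stage.
    """
    X = np.asarray(matrix, dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    if k > len(np.unique(X, axis=0)):
        raise ValueError("k exceeds the number of distinct rows")
    km = KMeans(n_clusters=k, n_init=n_starts, max_iter=max_iter,
                random_state=seed)
    raw_labels = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_[:, -1], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw_labels]
    centroids = km.cluster_centers_[order]

    grand = X.mean(axis=0)
    total_ss = float(((X - grand) ** 2).sum())
    within_ss = float(km.inertia_)
    between_ss = total_ss - within_ss
    frac = between_ss / total_ss if total_ss > 0 else 0.0
    return ClusterResult(labels=labels, centroids=centroids,
                         between_variance_fraction=frac, total_ss=total_ss,
                         between_ss=between_ss, within_ss=within_ss,
                         k=k, n_starts=n_starts, max_iter=max_iter, seed=seed)


def quantile_bin(matrix: pd.DataFrame | np.ndarray, n_quantiles: int = 100) -> np.ndarray:
    """Joint rank-based binning of all matrix entries into 0..n_quantiles.

    ``bin(x) = floor(F(x) * n_quantiles)`` with F the empirical CDF
    (proportion of entries <= x) over the flattened matrix, so the minimum
    maps near 0, the maximum to ``n_quantiles``, ties share a bin and the
    mapping is monotone.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    flat = np.sort(X.ravel())
    n = flat.size
    r = np.searchsorted(flat, X, side="right")     # rank = #{y <= x}
    return (r * n_quantiles) // n                  # exact integer floor


def cv_profile(matrix: pd.DataFrame, classes: pd.Series,
               ddof: int = 1) -> pd.DataFrame:
    """Coefficient of variation of each peak's trajectory, grouped by class.

    CV = sd / mean across stages per peak (sample sd, ddof = 1, by
    default).  Zero-mean peaks are excluded and counted in ``.attrs``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two stages")
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=ddof)
    ok = mean > 0
    out = pd.DataFrame({
        "element_id": np.asarray(matrix.index)[ok] if hasattr(matrix, "index") else np.flatnonzero(ok),
        "element_class": np.asarray(classes)[ok],
        "cv": sd[ok] / mean[ok],
    })
    out.attrs["n_excluded_zero_mean"] = int((~ok).sum())
    return out


def mean_increase_profile(stage_tracks: dict[str, "object"],
                          region_classes: dict[str, pd.DataFrame],
                          bin_size: int = 200) -> pd.DataFrame:
    """Average per-bin accessibility change between consecutive stages.

    Tracks are rebinned to ``bin_size`` bp; for each consecutive stage pair
    the per-bin change is averaged genome-wide and within each supplied
    region class (a dict of name -> interval DataFrame).  Returns a tidy
    table (stage_from, stage_to, class, mean_change).
    """
    stages = list(stage_tracks)
    first = stage_tracks[stages[0]]
    factor = bin_size // first.bin_size
    if factor < 1 or bin_size % first.bin_size:
        raise ValueError("bin_size must be a multiple of the track bin size")

    def rebin(track):
        out = {}
        for chrom, v in track.values.items():
            n = len(v) // factor * factor
            out[chrom] = v[:n].reshape(-1, factor).mean(axis=1)
        return out

    rebinned = {s: rebin(t) for s, t in stage_tracks.items()}
    chroms = list(first.values)
    masks = {"genome": {c: np.ones(len(rebinned[stages[0]][c]), dtype=bool) for c in chroms}}
    for name, regions in region_classes.items():
        m = {c: np.zeros(len(rebinned[stages[0]][c]), dtype=bool) for c in chroms}
        for row in regions.itertuples():
            if row.chrom in m:
                lo, hi = row.start // bin_size, -(-row.end // bin_size)
                m[row.chrom][lo:min(hi, len(m[row.chrom]))] = True
        masks[name] = m

    rows = []
    for s_from, s_to in zip(stages[:-1], stages[1:]):
        for name, mask in masks.items():
            deltas = [rebinned[s_to][c][mask[c]] - rebinned[s_from][c][mask[c]]
                      for c in chroms]
            allv = np.concatenate(deltas) if deltas else np.array([0.0])
            rows.append((s_from, s_to, name, float(allv.mean()) if allv.size else 0.0))
    return pd.DataFrame(rows, columns=["stage_from", "stage_to", "region_class", "mean_change"])
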