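"""Region-level signal quantification and normalization.

Occupancy matrices are built by averaging a per-base track in equal bins of a
fixed window around each summit (4 kb / 100 bins by default, i.e. 40-bp
bins).  Per factor, values are percentile-clipped (top 2% of bins to the
98th percentile, bottom 1% to the 1st) and min-max scaled to [0, 1] over the
pooled matrix.  Regions are partitioned by k-means (k = 2 by default, fixed
seed) on concatenated per-track features and ordered within clusters by the
total signal of a designated ranking track.  Fixed-window mean coverage
(±250 bp) and log-scale Spearman correlation between tracks complete the
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "BinnedSignalMatrix",
    "track_window_values",
    "bin_signal",
    "clip_scale",
    "cluster_regions",
    "coverage_at",
    "log_rank_correlation",
]


@dataclass
class BinnedSignalMatrix:
    """Region x bin occupancy values with their processing state."""

    regions: list[str]
    values: np.ndarray  # shape (n_regions, n_bins)
    half_window: int
    n_bins: int
    state: str = "raw"  # raw | scaled

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), self.n_bins):
            raise ValueError("values shape inconsistent with regions/n_bins")
        if (2 * self.half_window) % self.n_bins:
            raise ValueError("n_bins must divide the window width")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{i + 1:04d}" for i in range(self.n_bins)]
        return pd.DataFrame(self.values, index=pd.Index(self.regions, name="region"), columns=cols)


def track_window_values(track: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base values of a bedGraph track over [start, end); gaps are 0."""
    if end <= start:
        raise ValueError("empty window")
    out = np.zeros(end - start, dtype=float)
    sub = track[(track["chrom"] == chrom) & (track["end"] > start) & (track["start"] < end)]
    for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
        out[max(int(s) - start, 0) : min(int(e) - start, end - start)] = v
    return out


def _track_bounds(track: pd.DataFrame, chrom: str) -> tuple[int, int]:
    sub = track[track["chrom"] == chrom]
    if sub.empty:
        return (0, 0)
    return int(sub["start"].min()), int(sub["end"].max())


def bin_signal(
    track: pd.DataFrame,
    summits: pd.DataFrame,
    half_window: int = 2000,
    n_bins: int = 100,
) -> BinnedSignalMatrix:
    """Mean per-base signal in ``n_bins`` equal bins centred on each summit.

    ``summits`` needs columns region_id, chrom, summit.  Regions whose window
    exceeds the track extent are dropped with a warning.
    """
    if (2 * half_window) % n_bins:
        raise ValueError(f"n_bins={n_bins} does not divide window width {2 * half_window}")
    width = (2 * half_window) // n_bins
    regions, rows, dropped = [], [], []
    for _, r in summits.iterrows():
        lo, hi = int(r["summit"]) - half_window, int(r["summit"]) + half_window
        blo, bhi = _track_bounds(track, r["chrom"])
        if lo < blo or hi > bhi:
            dropped.append(r["region_id"])
            continue
        vals = track_window_values(track, r["chrom"], lo, hi)
        rows.append(vals.reshape(n_bins, width).mean(axis=1))
        regions.append(r["region_id"])
    if dropped:
        warnings.warn(f"dropped {len(dropped)} regions exceeding track bounds: {dropped[:5]}")
    return BinnedSignalMatrix(regions, np.array(rows).reshape(len(regions), n_bins),
                              half_window, n_bins)


def clip_scale(
    matrix: BinnedSignalMatrix, hi_pct: float = 98.0, lo_pct: float = 1.0
) -> BinnedSignalMatrix:
    """Percentile-clip then min-max scale a raw matrix to [0, 1].

    Percentiles are computed over all bins of the matrix pooled (per factor),
    with linear interpolation.  Values above the ``hi_pct`` percentile are set
    to it, values below ``lo_pct`` to it, then the whole matrix is scaled to
    [0, 1].  A constant matrix maps to all zeros with a warning.
    """
    if matrix.state != "raw":
        raise ValueError(f"clip_scale expects a raw matrix, got state={matrix.state!r}")
    v = matrix.values
    hi = np.percentile(v, hi_pct)
    lo = np.percentile(v, lo_pct)
    clipped = np.clip(v, lo, hi)
    rng = clipped.max() - clipped.min()
    if rng == 0:
        warnings.warn("constant signal matrix: scaled output is all zeros")
        scaled = np.zeros_like(clipped)
    else:
        scaled = (clipped - clipped.min()) / rng
    return replace(matrix, values=scaled, state="scaled")


def cluster_regions(
    matrices: Sequence[BinnedSignalMatrix],
    k: int = 2,
    seed: int = 0,
    ranking: BinnedSignalMatrix | None = None,
) -> pd.DataFrame:
    """k-means partition of regions on concatenated scaled track features.

    All matrices must share region order and be in scaled state.  Returns a
    table (region, cluster, order) where ``order`` sorts regions within each
    cluster by total signal of the ``ranking`` matrix (default: the first),
    descending.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    regions = matrices[0].regions
    for m in matrices:
        if m.regions != regions:
            raise ValueError("matrices do not share region order")
        if m.state != "scaled":
            raise ValueError("cluster_regions expects scaled matrices")
    if len(regions) < k:
        raise ValueError(f"fewer regions ({len(regions)}) than clusters ({k})")
    X = np.hstack([m.values for m in matrices])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    rank_mat = ranking if ranking is not None else matrices[0]
    totals = rank_mat.values.sum(axis=1)
    df = pd.DataFrame({"region": regions, "cluster": labels, "total_signal": totals})
    df = df.sort_values(["cluster", "total_signal"], ascending=[True, False], kind="mergesort")
    df["order"] = np.arange(len(df))
    return df.set_index("region").loc[regions].reset_index()


def coverage_at(
    regions: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    halfwidth: int = 250,
) -> pd.DataFrame:
    """Mean per-base signal in [center − halfwidth, center + halfwidth).

    ``regions`` needs columns region_id, chrom, center.  Raises when the
    window is empty (halfwidth <= 0) or falls outside the track bounds.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive (empty window)")
    data = {}
    for name, track in tracks.items():
        vals = []
        for _, r in regions.iterrows():
            lo, hi = int(r["center"]) - halfwidth, int(r["center"]) + halfwidth
            blo, bhi = _track_bounds(track, r["chrom"])
            if lo < blo or hi > bhi:
                raise ValueError(
                    f"region {r['region_id']} window [{lo}, {hi}) outside track {name} bounds"
                )
            vals.append(track_window_values(track, r["chrom"], lo, hi).mean())
        data[name] = vals
    return pd.DataFrame(data, index=pd.Index(regions["region_id"], name="region_id"))


def log_rank_correlation(
    coverage: pd.DataFrame, pseudocount: float | None = None
) -> pd.DataFrame:
    """Pairwise Spearman correlation of log-transformed coverage between tracks.

    The pseudocount defaults to the smallest positive coverage value (or 1 if
    none).  Constant tracks have undefined ranks: they are flagged with a
    warning and get NaN off-diagonal entries.
    """
    if coverage.shape[1] < 2:
        raise ValueError("need at least two tracks")
    v = coverage.to_numpy(dtype=float)
    if pseudocount is None:
        pos = v[v > 0]
        pseudocount = float(pos.min()) if pos.size else 1.0
    logv = np.log(v + pseudocount)
    cols = list(coverage.columns)
    constant = [c for i, c in enumerate(cols) if np.ptp(logv[:, i]) == 0]
    if constant:
        warnings.warn(f"constant tracks have undefined ranks: {constant}")
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cols[i] in constant or cols[j] in constant:
                r = np.nan
            else:
                r = stats.spearmanr(logv[:, i], logv[:, j]).statistic
            out.iat[i, j] = out.iat[j, i] = r
    return out
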