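"""Pooled CRISPRi screen analysis: normalization, per-guide statistics,
exponential fitness modelling, region-level rank aggregation and hit calling.

Two normalization paths are exposed and never composed: control-median
scaling (validation-screen path; the per-sample median of control guides is
set to a fixed target, 1000 by default) and TMM (trimmed mean of M-values,
primary-screen path).  Guide dropout is summarized as log2 fold change vs
day 0, tested per guide with a replicate t-test, and modelled per region by
the exponential fitness model

    x_t = x_0 * exp(alpha * t)        t in {8, 15, 22}

fitted on the natural-log scale by least squares with one intercept per
guide and a single shared slope alpha (the region fitness score; negative =
growth inhibition).  Region-level evidence is aggregated with a modified
robust rank aggregation statistic (minimum Beta order-statistic tail over
the region's guide percentiles) with a permutation p-value, and hits are
called across four cell models (two per lineage): common = scoring in >=3
models, lineage-specific = scoring in both models of one lineage and
neither of the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .workflow_io import sample_metadata

__all__ = [
    "FitnessResult",
    "normalize_to_controls",
    "tmm_factors",
    "tmm_normalize",
    "min_nonzero",
    "guide_lfc",
    "guide_depletion_test",
    "fit_fitness",
    "fit_fitness_all",
    "aggregate_region_rra",
    "differential_lineage",
    "call_hits_secondary",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_to_controls(
    counts: pd.DataFrame, control_ids: Sequence[str], target: float = 1000.0
) -> pd.DataFrame:
    """Scale each sample so the median of control-guide counts equals ``target``.

    Within-sample guide ratios are preserved (pure per-sample scaling).
    Raises if a sample's control median is zero.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids must be non-empty")
    missing = set(control_ids) - set(counts.index)
    if missing:
        raise ValueError(f"control guides absent from matrix: {sorted(missing)[:5]}")
    med = counts.loc[control_ids].median(axis=0)
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise ValueError(f"zero control median in samples: {bad[:5]}")
    return counts.div(med, axis=1).mul(target)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float
) -> float:
    """Doubly trimmed, inverse-variance-weighted mean of M-values for one
    sample pair (the classical TMM pair statistic)."""
    n_o, n_r = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / n_o, ref[keep] / n_r
    logr = np.log2(o / r)
    abse = 0.5 * np.log2(o * r)
    w = (n_o - obs[keep]) / (n_o * obs[keep]) + (n_r - ref[keep]) / (n_r * ref[keep])
    if logr.size < 10:
        raise ValueError("degenerate sample: too few guides expressed in both samples")
    if np.max(np.abs(logr)) < 1e-6:
        return 1.0
    n = logr.size
    lo_l = np.floor(n * trim_M) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_A) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(logr)
    rank_s = stats.rankdata(abse)
    keep2 = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep2.any():
        raise ValueError("trimming removed all guides; samples too degenerate for TMM")
    f = 2.0 ** (np.sum(logr[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))
    return float(f)


def tmm_factors(
    counts: pd.DataFrame, trim_M: float = 0.3, trim_A: float = 0.05
) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  ``trim_M`` and ``trim_A`` are the
    per-tail trim fractions on log-ratios and average log-abundance.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    Y = counts.to_numpy(dtype=float)
    if not (Y.sum(axis=0) > 0).all():
        raise ValueError("a sample has all-zero counts")
    lib = Y.sum(axis=0)
    uq = np.array([np.percentile(Y[:, j] / lib[j], 75) for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array(
        [
            1.0 if j == ref else _tmm_pair(Y[:, j], Y[:, ref], trim_M, trim_A)
            for j in range(Y.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def tmm_normalize(counts: pd.DataFrame, trim_M: float = 0.3, trim_A: float = 0.05) -> pd.DataFrame:
    """Counts scaled by effective library size (library size x TMM factor),
    re-centred to the mean library size so values stay count-like."""
    f = tmm_factors(counts, trim_M, trim_A)
    lib = counts.sum(axis=0)
    eff = lib * f
    return counts.div(eff, axis=1).mul(lib.mean())


def min_nonzero(norm: pd.DataFrame) -> float:
    """Smallest nonzero value of the matrix (the log pseudocount policy)."""
    v = norm.to_numpy(dtype=float)
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive values")
    return float(pos.min())


# ---------------------------------------------------------------------------
# per-guide statistics
# ---------------------------------------------------------------------------

def guide_lfc(norm: pd.DataFrame, pseudocount: float | str = "min_nonzero") -> pd.DataFrame:
    """Per-replicate log2 fold change vs day 0.

    Returns a tidy table (guide_id, cell_line, replicate, day, lfc) with one
    row per guide and post-day-0 sample: log2((c_t + c)/(c_0 + c)) where the
    pseudocount c is the smallest nonzero value of the matrix under the
    default policy, or any fixed float.
    """
    c = min_nonzero(norm) if pseudocount == "min_nonzero" else float(pseudocount)
    meta = sample_metadata(norm.columns)
    if not (meta["day"] == 0).any():
        raise ValueError("no day-0 samples present")
    frames = []
    for (cl, rep), grp in meta.groupby(["cell_line", "replicate"]):
        d0 = grp.loc[grp["day"] == 0, "sample"]
        if d0.empty:
            raise ValueError(f"missing day-0 replicate for {cl} rep{rep}")
        base = norm[d0.iloc[0]].to_numpy(dtype=float) + c
        for _, row in grp[grp["day"] > 0].iterrows():
            lfc = np.log2((norm[row["sample"]].to_numpy(dtype=float) + c) / base)
            frames.append(
                pd.DataFrame(
                    {
                        "guide_id": norm.index,
                        "cell_line": cl,
                        "replicate": rep,
                        "day": row["day"],
                        "lfc": lfc,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def summarize_lfc(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged log2FC per (guide, cell line, day)."""
    return (
        per_rep.groupby(["guide_id", "cell_line", "day"], sort=False)["lfc"]
        .mean()
        .reset_index()
        .rename(columns={"lfc": "log2fc"})
    )


#: p-value floor used when replicate log2FCs are identical but nonzero.
P_FLOOR = 1e-300


def guide_depletion_test(per_rep: pd.DataFrame, day: int | None = None) -> pd.DataFrame:
    """Two-sided one-sample t-test of replicate log2FC against 0.

    Returns (guide_id, cell_line, day, log2fc, t, p, degenerate).  Groups
    with zero replicate variance get p = 1 when the mean is 0 and a floored
    near-zero p (flagged ``degenerate``) otherwise.
    """
    sub = per_rep if day is None else per_rep[per_rep["day"] == day]
    n_rep = sub.groupby(["guide_id", "cell_line", "day"])["lfc"].size()
    if (n_rep < 2).any():
        raise ValueError("depletion test needs >=2 replicates per guide")
    rows = []
    for (gid, cl, d), grp in sub.groupby(["guide_id", "cell_line", "day"], sort=False):
        v = grp["lfc"].to_numpy(dtype=float)
        m = v.mean()
        sd = v.std(ddof=1)
        degenerate = False
        if sd == 0.0:
            if m == 0.0:
                t, p = 0.0, 1.0
            else:
                t = np.inf if m > 0 else -np.inf
                p = P_FLOOR
                degenerate = True
        else:
            t, p = stats.ttest_1samp(v, 0.0)
        rows.append((gid, cl, d, m, float(t), float(p), degenerate))
    return pd.DataFrame(
        rows, columns=["guide_id", "cell_line", "day", "log2fc", "t", "p", "degenerate"]
    )


# ---------------------------------------------------------------------------
# exponential fitness model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitnessResult:
    """Region fitness fit: per-day rate alpha, its SE and two-sided p-value."""

    alpha: float
    se: float
    p: float
    n_points: int
    union_id: str = ""
    cell_line: str = ""


def fit_fitness(
    region_norm: pd.DataFrame,
    pseudocount: float = 0.0,
    include_day0: bool = True,
    union_id: str = "",
    cell_line: str = "",
) -> FitnessResult:
    """Fit ln(x_t) = intercept_g + alpha * t over one region's guides.

    ``region_norm`` holds the normalized counts of the region's guides
    (rows) across the samples of one cell line (columns named
    ``<cellline>_rep<int>_day<int>``).  All (guide, replicate, timepoint)
    observations are stacked; each guide gets its own intercept (absorbing
    unequal abundances) and one slope alpha is shared — the region fitness
    score.  Day-0 samples enter at t = 0 unless ``include_day0`` is False.
    Observations that are non-positive after the pseudocount are dropped.
    """
    meta = sample_metadata(region_norm.columns)
    if not include_day0:
        meta = meta[meta["day"] > 0]
    y_parts, t_parts, g_parts = [], [], []
    for gi, gid in enumerate(region_norm.index):
        vals = region_norm.loc[gid, meta["sample"]].to_numpy(dtype=float) + pseudocount
        ok = vals > 0
        y_parts.append(np.log(vals[ok]))
        t_parts.append(meta["day"].to_numpy(dtype=float)[ok])
        g_parts.append(np.full(ok.sum(), gi))
    y = np.concatenate(y_parts)
    t = np.concatenate(t_parts)
    g = np.concatenate(g_parts).astype(int)
    if len(np.unique(t)) < 2:
        raise ValueError("need >=2 distinct timepoints with positive counts")

    n_guides = len(region_norm.index)
    X = np.zeros((y.size, n_guides + 1))
    X[np.arange(y.size), g] = 1.0
    X[:, -1] = t
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - rank
    alpha = float(beta[-1])
    if dof <= 0:
        return FitnessResult(alpha, np.nan, np.nan, y.size, union_id, cell_line)
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(s2 * xtx_inv[-1, -1], 0.0)))
    # numerically perfect fit: the log-linear model explains the data exactly
    if np.sqrt(s2) <= 1e-10 * max(1.0, float(np.abs(y).max())):
        p = 1.0 if abs(alpha) <= 1e-10 else 0.0
    elif se == 0.0:
        p = 1.0 if alpha == 0.0 else 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(alpha) / se, dof))
    return FitnessResult(alpha, se, p, int(y.size), union_id, cell_line)


def fit_fitness_all(
    norm: pd.DataFrame,
    guide_to_region: Mapping[str, str] | pd.Series,
    pseudocount: float = 0.0,
    include_day0: bool = True,
) -> pd.DataFrame:
    """Region fitness fits for every (region, cell line) of a screen matrix.

    Returns a table with columns union_id, cell_line, alpha, se, p, n_points.
    """
    g2r = pd.Series(guide_to_region)
    g2r = g2r[g2r.astype(bool)]
    meta = sample_metadata(norm.columns)
    rows = []
    for cl, grp in meta.groupby("cell_line", sort=True):
        cols = list(grp["sample"])
        for rid, guides in g2r.groupby(g2r):
            sub = norm.loc[norm.index.intersection(guides.index), cols]
            if sub.empty:
                continue
            res = fit_fitness(
                sub, pseudocount=pseudocount, include_day0=include_day0,
                union_id=rid, cell_line=cl,
            )
            rows.append((rid, cl, res.alpha, res.se, res.p, res.n_points))
    return pd.DataFrame(rows, columns=["union_id", "cell_line", "alpha", "se", "p", "n_points"])


# ---------------------------------------------------------------------------
# region rank aggregation
# ---------------------------------------------------------------------------

def _rra_rho(u_sorted: np.ndarray, alpha0: float) -> float:
    """Modified RRA score: minimum Beta(k, m-k+1) lower tail over the ordered
    percentiles below alpha0; 1.0 when no percentile clears the cutoff."""
    m = u_sorted.size
    k = np.arange(1, m + 1)
    mask = u_sorted < alpha0
    if not mask.any():
        return 1.0
    vals = stats.beta.cdf(u_sorted[mask], k[mask], m - k[mask] + 1)
    return float(min(vals.min(), 1.0))


def aggregate_region_rra(
    guide_p: pd.Series,
    guide_to_region: Mapping[str, str] | pd.Series,
    alpha0: float = 0.25,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Region score by modified robust rank aggregation.

    Guide p-values are ranked over the whole matrix (average ranks on ties)
    and converted to percentiles u = rank / n.  For a region with m guides,
    rho is the minimum over k of the Beta(k, m−k+1) lower-tail probability at
    the k-th smallest percentile, restricted to percentiles below ``alpha0``.
    The permutation p-value compares rho against random guide sets of the
    same size drawn (with replacement) from the percentile pool, shared
    across regions of equal size.

    Returns (union_id, m, rho, p_perm).
    """
    if guide_p.isna().any():
        raise ValueError("guide p-values contain NaN")
    g2r = pd.Series(guide_to_region)
    g2r = g2r[g2r.astype(bool)]
    n = guide_p.size
    ranks = stats.rankdata(guide_p.to_numpy(dtype=float))
    u = pd.Series(ranks / n, index=guide_p.index)

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    pool = u.to_numpy()

    rows = []
    for rid, guides in g2r.groupby(g2r):
        members = guide_p.index.intersection(guides.index)
        if len(members) == 0:
            raise ValueError(f"region {rid} has no guides in the p-value table")
        um = np.sort(u.loc[members].to_numpy())
        rho = _rra_rho(um, alpha0)
        m = um.size
        if m not in null_cache:
            draws = rng.choice(pool, size=(n_permutations, m))
            draws.sort(axis=1)
            k = np.arange(1, m + 1)
            bet = stats.beta.cdf(draws, k, m - k + 1)
            bet[draws >= alpha0] = np.inf
            null = bet.min(axis=1)
            null[~np.isfinite(null)] = 1.0
            null_cache[m] = null
        null = null_cache[m]
        p_perm = (1.0 + float(np.sum(null <= rho))) / (n_permutations + 1.0)
        rows.append((rid, m, rho, p_perm))
    return pd.DataFrame(rows, columns=["union_id", "m", "rho", "p_perm"])


# ---------------------------------------------------------------------------
# differential comparison and secondary hit calling
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def differential_lineage(
    per_rep_a: pd.DataFrame,
    per_rep_b: pd.DataFrame,
    day: int = 22,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Differential guide dropout between two cell lines at one timepoint.

    Inputs are per-replicate lfc tables from :func:`guide_lfc` (one cell line
    each).  Per guide: delta = mean lfc(A) − mean lfc(B), Welch two-sample
    t-test across replicates, BH FDR across guides; differential when
    |delta| > ``lfc_thresh`` and FDR < ``fdr_thresh``, labelled by the cell
    line with the stronger depletion (more negative lfc).
    """
    a = per_rep_a[per_rep_a["day"] == day]
    b = per_rep_b[per_rep_b["day"] == day]
    ga = {g: v["lfc"].to_numpy(dtype=float) for g, v in a.groupby("guide_id")}
    gb = {g: v["lfc"].to_numpy(dtype=float) for g, v in b.groupby("guide_id")}
    if set(ga) != set(gb):
        raise ValueError("guide universes of the two tables disagree")
    cl_a = a["cell_line"].iloc[0]
    cl_b = b["cell_line"].iloc[0]
    guides = sorted(ga)
    delta = np.empty(len(guides))
    pvals = np.empty(len(guides))
    for i, g in enumerate(guides):
        va, vb = ga[g], gb[g]
        delta[i] = va.mean() - vb.mean()
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            pvals[i] = 1.0 if va.mean() == vb.mean() else P_FLOOR
        else:
            pvals[i] = stats.ttest_ind(va, vb, equal_var=False).pvalue
    fdr = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "guide_id": guides,
            "delta_log2fc": delta,
            "p": pvals,
            "fdr": fdr,
        }
    )
    out["differential"] = (np.abs(out["delta_log2fc"]) > lfc_thresh) & (out["fdr"] < fdr_thresh)
    out["label"] = np.where(
        out["differential"], np.where(out["delta_log2fc"] < 0, cl_a, cl_b), ""
    )
    return out


def call_hits_secondary(
    fitness: pd.DataFrame,
    lineage_map: Mapping[str, str],
    alpha_p: float = 0.05,
) -> pd.DataFrame:
    """Region hit categories across four cell models (two per lineage).

    A region *scores* in a model when alpha < 0 and p < ``alpha_p``.
    Category: common = scores in >=3 of 4 models; lineage-specific = scores
    in both models of one lineage and in neither model of the other; else
    none.

    ``fitness`` has columns union_id, cell_line, alpha, p (one row per
    region x model); ``lineage_map`` maps cell line -> lineage label.
    """
    cells = sorted(lineage_map)
    lineages = sorted(set(lineage_map.values()))
    if len(cells) != 4 or len(lineages) != 2:
        raise ValueError("secondary hit calling expects 4 models across 2 lineages")
    have = set(fitness["cell_line"].unique())
    if not set(cells) <= have:
        raise ValueError(f"fitness table missing models: {sorted(set(cells) - have)}")

    piv_a = fitness.pivot(index="union_id", columns="cell_line", values="alpha")
    piv_p = fitness.pivot(index="union_id", columns="cell_line", values="p")
    scores = (piv_a < 0) & (piv_p < alpha_p)
    by_lin = {
        lin: [cl for cl in cells if lineage_map[cl] == lin] for lin in lineages
    }
    n_total = scores[cells].sum(axis=1)
    cat = pd.Series("none", index=scores.index, dtype=object)
    for lin in lineages:
        own = scores[by_lin[lin]].all(axis=1)
        other = [c for c in cells if lineage_map[c] != lin]
        none_other = ~scores[other].any(axis=1)
        cat[own & none_other] = f"lineage-{lin}"
    cat[n_total >= 3] = "common"
    out = pd.DataFrame(
        {
            "union_id": scores.index,
            "category": cat.to_numpy(),
            "n_scoring": n_total.to_numpy(),
            "supporting_models": [
                ",".join(c for c in cells if scores.loc[r, c]) for r in scores.index
            ],
        }
    )
    return out.reset_index(drop=True)
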