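"""Tiling sgRNA library design over consensus regulatory peaks.

Implements the design procedure of a tiling CRISPRi library: a data-driven
peak significance cutoff (smoothing-spline inflection of the −log10 FDR
ECDF), transitive peak union across cell lines with stable Union_IDs and
min-FDR summit propagation, candidate sgRNA enumeration around summits (NGG
PAM scan on both strands), restriction-site / off-target / spacing filters,
two-pool library assembly with control pools, 60-nt oligo emission with
cloning flanks, and validation-library design from primary-screen per-guide
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "NoKneeError",
    "GuideCandidate",
    "select_peak_cutoff",
    "union_peaks",
    "enumerate_candidates",
    "filter_candidates",
    "assemble_library",
    "emit_oligos",
    "design_validation_library",
    "FLANK_5",
    "FLANK_3",
    "BBSI_SITES",
]

#: Cloning flanks of the 60-nt oligo; each carries a BbsI recognition site by
#: design, so the BbsI filter applies to the variable 20-nt protospacer only.
FLANK_5 = "GCCATCCAGAAGACTTACCG"
FLANK_3 = "GTTTCCGTCTTCACGACTGC"

#: BbsI recognition sequence and its reverse complement.
BBSI_SITES = ("GAAGAC", "GTCTTC")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class NoKneeError(RuntimeError):
    """The ECDF second derivative has no qualifying sign change (no knee)."""


# ---------------------------------------------------------------------------
# significance cutoff
# ---------------------------------------------------------------------------

def _penalized_spline(x: np.ndarray, y: np.ndarray, n_knots: int, df: float) -> BSpline:
    """Cubic P-spline with ``n_knots`` uniformly spaced interior knots,
    penalty weight chosen by bisection so the effective degrees of freedom
    (trace of the hat matrix) match ``df``."""
    interior = np.linspace(x[0], x[-1], n_knots + 2)[1:-1]
    t = np.concatenate([[x[0]] * 4, interior, [x[-1]] * 4])
    B = BSpline.design_matrix(x, t, 3).toarray()
    p = B.shape[1]
    D = np.diff(np.eye(p), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B + 1e-10 * np.eye(p)
    Bty = B.T @ y

    target = float(np.clip(df, 2.0, p))

    def edf(loglam: float) -> float:
        lam = 10.0 ** loglam
        return float(np.trace(np.linalg.solve(BtB + lam * P, BtB)))

    lo, hi = -10.0, 14.0
    if edf(lo) <= target:
        lam = 10.0 ** lo
    elif edf(hi) >= target:
        lam = 10.0 ** hi
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if edf(mid) > target:
                lo = mid
            else:
                hi = mid
        lam = 10.0 ** (0.5 * (lo + hi))
    coef = np.linalg.solve(BtB + lam * P, Bty)
    return BSpline(t, coef, 3)


def select_peak_cutoff(
    fdr_values: Sequence[float],
    knots: int = 20,
    df: float = 15.0,
    grid_size: int = 2001,
    min_rel_amplitude: float = 0.01,
    fit_points: int = 512,
) -> float:
    """Data-driven peak significance threshold from the ECDF knee.

    Computes the ECDF of −log10(FDR), fits a cubic smoothing spline (``knots``
    uniformly spaced interior knots, penalty matched to ``df`` effective
    degrees of freedom) to the ECDF evaluated on a uniform ``fit_points``
    grid — uniform abscissae keep the sparse high-significance tail from
    being starved of resolution — then evaluates the second derivative on a
    dense grid and returns the −log10(FDR) at the inflection point (the
    downward, + to −, sign change) nearest the high-significance tail.
    Peaks above the returned threshold are the retained set.

    Sign changes whose preceding curvature bump is below ``min_rel_amplitude``
    of the global curvature maximum are treated as boundary noise and skipped.

    Raises :class:`NoKneeError` when no qualifying sign change exists (e.g.
    all values equal).
    """
    v = np.asarray(list(fdr_values), dtype=float)
    if v.size < 100:
        raise ValueError("need at least 100 FDR values for cutoff selection")
    if np.any(v <= 0) or np.any(v > 1):
        raise ValueError("FDR values must lie in (0, 1]")
    x = np.sort(-np.log10(v))
    if x[-1] - x[0] <= 1e-12:
        raise NoKneeError("all FDR values identical: ECDF has no curvature")
    gx = np.linspace(x[0], x[-1], fit_points)
    gy = np.searchsorted(x, gx, side="right") / x.size

    spl = _penalized_spline(gx, gy, knots, df)
    grid = np.linspace(x[0], x[-1], grid_size)
    s2 = spl.derivative(2)(grid)

    # downward zero crossings of f'' whose preceding positive bump is real
    pos_max = float(s2.max())
    if pos_max <= 0:
        raise NoKneeError("second derivative never positive: no knee found")
    candidates: list[float] = []
    run_max = -np.inf
    for i in range(len(grid) - 1):
        run_max = max(run_max, s2[i])
        if s2[i] > 0 >= s2[i + 1]:
            if run_max >= min_rel_amplitude * pos_max:
                # linear interpolation of the zero crossing
                frac = s2[i] / (s2[i] - s2[i + 1])
                candidates.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
            run_max = -np.inf
    if not candidates:
        raise NoKneeError("no qualifying second-derivative sign change (no knee)")
    return max(candidates)


# ---------------------------------------------------------------------------
# peak union
# ---------------------------------------------------------------------------

def union_peaks(peaksets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Transitive union of per-cell-line peaks into consensus peaks.

    Peaks overlapping by >=1 bp are merged transitively (chains collapse into
    one consensus interval spanning the envelope).  The consensus summit is
    the summit of the member with the smallest FDR (ties: smaller start, then
    cell-line name).  Union IDs are assigned deterministically by sorted
    coordinate.

    Each peakset DataFrame needs columns chrom, start, end, summit,
    neglog10_fdr and (optionally) cell_line; 0-based half-open coordinates.
    """
    if not peaksets:
        raise ValueError("need at least one peakset")
    frames = []
    for cl, df in peaksets.items():
        d = df.copy()
        if "cell_line" not in d.columns:
            d["cell_line"] = cl
        frames.append(d)
    allp = pd.concat(frames, ignore_index=True)
    bad = allp["end"] <= allp["start"]
    if bad.any():
        raise ValueError(f"malformed intervals (end <= start) at rows {list(allp.index[bad])[:5]}")
    inside = (allp["start"] <= allp["summit"]) & (allp["summit"] < allp["end"])
    if not inside.all():
        raise ValueError("summit outside its peak interval")

    allp = allp.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        cur: list[int] = []
        cur_end = -1
        for idx in grp.index:
            s, e = int(grp.at[idx, "start"]), int(grp.at[idx, "end"])
            if cur and s < cur_end:
                cur.append(idx)
                cur_end = max(cur_end, e)
            else:
                if cur:
                    rows.append((chrom, cur))
                cur = [idx]
                cur_end = e
        if cur:
            rows.append((chrom, cur))

    records = []
    for chrom, members in rows:
        sub = allp.loc[members]
        best = sub.sort_values(
            ["neglog10_fdr", "start", "cell_line"], ascending=[False, True, True]
        ).iloc[0]
        records.append(
            {
                "chrom": chrom,
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "summit": int(best["summit"]),
                "neglog10_best_fdr": float(sub["neglog10_fdr"].max()),
                "best_fdr": float(10.0 ** -min(sub["neglog10_fdr"].max(), 300.0)),
                "member_cell_lines": ",".join(sorted(set(sub["cell_line"]))),
                "n_members": len(sub),
            }
        )
    out = pd.DataFrame.from_records(records).sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "union_id", [f"UR{i + 1:06d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# candidate enumeration and filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer candidate next to an NGG PAM.

    ``target_pos`` is the canonical SpCas9 cut position, 3 bp 5' of the PAM
    (between protospacer bases 17 and 18), in absolute coordinates.
    """

    protospacer: str
    strand: str
    target_pos: int
    distance_to_summit: int
    bbsi_free: bool = True
    offtarget_unique: bool = True
    spacing_ok: bool = False

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be exactly 20 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _has_bbsi(protospacer: str) -> bool:
    return any(site in protospacer for site in BBSI_SITES)


def enumerate_candidates(
    sequence: str,
    summit: int,
    window: int = 300,
    seq_start: int = 0,
) -> list[GuideCandidate]:
    """All NGG-adjacent 20-nt protospacers within ±``window`` bp of the summit.

    ``sequence`` is the locus sequence whose first base sits at absolute
    coordinate ``seq_start``; it must cover
    [summit − window − 25, summit + window + 25].  Both strands are scanned:
    a forward PAM is any GG dinucleotide with 20 nt of sequence 5' of its N;
    a reverse PAM appears as CC on the forward strand.  Candidates are sorted
    by target position.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    seq = sequence.upper()
    lo_needed = summit - window - 25
    hi_needed = summit + window + 25
    if seq_start > lo_needed or seq_start + len(seq) < hi_needed:
        raise ValueError(
            f"sequence [{seq_start}, {seq_start + len(seq)}) does not cover "
            f"the design window [{lo_needed}, {hi_needed})"
        )

    cands: list[GuideCandidate] = []
    # forward strand: PAM = seq[i-1 : i+2] (NGG) with GG at (i, i+1)
    for i in range(21, len(seq) - 1):
        if seq[i] == "G" and seq[i + 1] == "G":
            pam_n = i - 1
            proto = seq[pam_n - 20 : pam_n]
            pos = seq_start + pam_n - 3  # cut between protospacer bases 17|18
            if abs(pos - summit) > window:
                continue
            cands.append(
                GuideCandidate(proto, "+", pos, pos - summit, bbsi_free=not _has_bbsi(proto))
            )
    # reverse strand: PAM appears as CCN at (j, j+1, j+2); protospacer is the
    # reverse complement of the 20 nt 3' of the PAM on the forward strand
    for j in range(0, len(seq) - 23):
        if seq[j] == "C" and seq[j + 1] == "C":
            proto = _revcomp(seq[j + 3 : j + 23])
            pos = seq_start + j + 5  # mirror of the forward cut-site convention
            if abs(pos - summit) > window:
                continue
            cands.append(
                GuideCandidate(proto, "-", pos, pos - summit, bbsi_free=not _has_bbsi(proto))
            )
    cands.sort(key=lambda c: (c.target_pos, c.strand))
    return cands


def filter_candidates(
    cands: Sequence[GuideCandidate], min_gap: int = 20
) -> list[GuideCandidate]:
    """BbsI / off-target / spacing filters over position-sorted candidates.

    Removes candidates whose protospacer contains a BbsI site (GAAGAC or
    GTCTTC) or that are flagged non-unique, then runs a greedy left-to-right
    spacing pass keeping a candidate only if its target position exceeds the
    last kept one by more than ``min_gap`` bp.
    """
    positions = [c.target_pos for c in cands]
    if positions != sorted(positions):
        raise ValueError("candidates must be sorted by target_pos")
    kept: list[GuideCandidate] = []
    last = None
    for c in cands:
        if not c.bbsi_free or not c.offtarget_unique:
            continue
        if last is not None and c.target_pos - last <= min_gap:
            continue
        kept.append(replace(c, spacing_ok=True))
        last = c.target_pos
    return kept


# ---------------------------------------------------------------------------
# library assembly and oligo emission
# ---------------------------------------------------------------------------

def assemble_library(
    consensus: pd.DataFrame,
    candidates: Mapping[str, Sequence[GuideCandidate]],
    pool_cutoffs: tuple[float, float] = (92.0, 49.0),
    controls: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Assemble the designed library: two experimental pools plus controls.

    ``pool_cutoffs`` are (strict, loose) −log10(FDR) bounds: consensus peaks
    beyond the strict cutoff go to pool 1, peaks between the cutoffs to
    pool 2, and peaks below the loose cutoff are excluded.  ``controls`` maps
    a control class (NT/PL/HS/YT) to its protospacer list; classes must be
    disjoint.

    Returns a library table with columns guide_id, protospacer, strand,
    chrom, target_pos, union_id, distance_to_summit, pool, control_class.
    """
    strict, loose = pool_cutoffs
    if strict < loose:
        raise ValueError("pool cutoffs must be ordered (strict >= loose)")
    controls = dict(controls or {})
    seen: dict[str, str] = {}
    for cls, guides in controls.items():
        for g in guides:
            if g in seen:
                raise ValueError(f"control classes overlap: {g!r} in {seen[g]} and {cls}")
            seen[g] = cls

    rows = []
    n_exp = 0
    for _, peak in consensus.iterrows():
        score = peak["neglog10_best_fdr"]
        if score > strict:
            pool = "pool1"
        elif score > loose:
            pool = "pool2"
        else:
            continue
        for k, c in enumerate(candidates.get(peak["union_id"], [])):
            rows.append(
                {
                    "guide_id": f"{peak['union_id']}_g{k + 1:02d}",
                    "protospacer": c.protospacer,
                    "strand": c.strand,
                    "chrom": peak["chrom"],
                    "target_pos": c.target_pos,
                    "union_id": peak["union_id"],
                    "distance_to_summit": c.distance_to_summit,
                    "pool": pool,
                    "control_class": "",
                }
            )
            n_exp += 1
    if n_exp == 0:
        warnings.warn("no experimental guides passed the pool cutoffs; library is controls only")
    for cls, guides in controls.items():
        for k, proto in enumerate(guides):
            rows.append(
                {
                    "guide_id": f"{cls}_{k + 1:05d}",
                    "protospacer": proto,
                    "strand": "+",
                    "chrom": "",
                    "target_pos": -1,
                    "union_id": "",
                    "distance_to_summit": 0,
                    "pool": "control",
                    "control_class": cls,
                }
            )
    lib = pd.DataFrame(
        rows,
        columns=[
            "guide_id",
            "protospacer",
            "strand",
            "chrom",
            "target_pos",
            "union_id",
            "distance_to_summit",
            "pool",
            "control_class",
        ],
    )
    dup = lib.duplicated(subset=["pool", "protospacer"])
    if dup.any():
        lib = lib[~dup].reset_index(drop=True)
    return lib


def emit_oligos(library: pd.DataFrame) -> list[str]:
    """60-nt single-stranded oligos: 5' flank + 20-nt protospacer + 3' flank.

    Order matches the library order.  Raises on any protospacer whose length
    is not exactly 20.
    """
    oligos = []
    for _, row in library.iterrows():
        proto = row["protospacer"]
        if len(proto) != 20:
            raise ValueError(f"protospacer {row['guide_id']} has length {len(proto)} != 20")
        oligos.append(FLANK_5 + proto + FLANK_3)
    return oligos


# ---------------------------------------------------------------------------
# validation library
# ---------------------------------------------------------------------------

def design_validation_library(
    primary_stats: pd.DataFrame,
    top_k: int = 4,
    p_depleted: float = 0.1,
    p_significant: float = 0.05,
) -> pd.DataFrame:
    """Validation-library design from primary-screen per-guide statistics.

    ``primary_stats`` has one row per (guide, cell line) with columns
    guide_id, union_id, cell_line, log2fc, p.  A guide is *depleting* in a
    cell line if log2fc < 0 and p < ``p_depleted``.  A region is a
    lineage-specific hit if, in exactly one cell line, it has >=2 depleting
    guides with >=1 at p < ``p_significant``; a common hit if it has >=3
    depleting guides with >=1 at p < ``p_significant`` in both cell lines.
    For each hit the ``top_k`` depleting guides with most negative log2fc are
    selected (ties: smaller p, then guide id).

    Returns a table with columns union_id, category, cell_line (scoring line
    or 'both'), guide_id, log2fc, p.
    """
    required = {"guide_id", "union_id", "cell_line", "log2fc", "p"}
    missing = required - set(primary_stats.columns)
    if missing:
        raise ValueError(f"primary stats missing columns: {sorted(missing)}")
    if primary_stats[["log2fc", "p"]].isna().any().any():
        raise ValueError("primary stats contain missing log2fc or p values")
    cells = sorted(primary_stats["cell_line"].unique())
    if len(cells) != 2:
        raise ValueError("primary stats must contain exactly two cell lines")

    st = primary_stats.copy()
    st["depleting"] = (st["log2fc"] < 0) & (st["p"] < p_depleted)
    st["significant"] = st["depleting"] & (st["p"] < p_significant)

    out_rows = []
    for rid, grp in st.groupby("union_id", sort=True):
        per_cl = {}
        for cl in cells:
            sub = grp[grp["cell_line"] == cl]
            dep = sub[sub["depleting"]]
            per_cl[cl] = {
                "n_dep": len(dep),
                "any_sig": bool(dep["significant"].any()),
                "dep": dep,
            }
        common = all(
            per_cl[cl]["n_dep"] >= 3 and per_cl[cl]["any_sig"] for cl in cells
        )
        lineage_cl = None
        if not common:
            qualifying = [
                cl
                for cl in cells
                if per_cl[cl]["n_dep"] >= 2 and per_cl[cl]["any_sig"]
            ]
            if len(qualifying) == 1:
                lineage_cl = qualifying[0]
        if not common and lineage_cl is None:
            continue

        if common:
            cat, label, pool = "common", "both", pd.concat([per_cl[c]["dep"] for c in cells])
            # rank each guide by its most negative log2fc across cell lines
            key = (
                pool.groupby("guide_id")
                .agg(log2fc=("log2fc", "min"), p=("p", "min"))
                .reset_index()
            )
        else:
            cat, label = "lineage-specific", lineage_cl
            key = per_cl[lineage_cl]["dep"][["guide_id", "log2fc", "p"]].copy()
        key = key.sort_values(["log2fc", "p", "guide_id"]).head(top_k)
        for _, r in key.iterrows():
            out_rows.append(
                {
                    "union_id": rid,
                    "category": cat,
                    "cell_line": label,
                    "guide_id": r["guide_id"],
                    "log2fc": r["log2fc"],
                    "p": r["p"],
                }
            )
    return pd.DataFrame(
        out_rows, columns=["union_id", "category", "cell_line", "guide_id", "log2fc", "p"]
    )
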