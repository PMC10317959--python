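"""Synthetic inputs for CRISPRi tiling-screen pipelines.

Generates the three inputs the analysis consumes — per-cell-line peak sets,
genome-like locus sequences, and guide x sample count matrices — with the
statistical structure the downstream methods assume:

* peak significances (−log10 FDR) follow a two-regime mixture whose ECDF has
  a knee at a configurable location, so the data-driven cutoff selection has
  something real to find;
* sequences are uniform ACGT with a guaranteed density of NGG PAM sites
  around the summit, so tiling enumeration never starves;
* counts follow a negative-binomial model around exponential dropout
  x_t = x_0 * exp(alpha * t), with designated control pools (non-targeting,
  pan-lethal, pathway, target-gene) and lineage-specific planted fitness
  effects across four simulated cell models (two per lineage).

Every output is fully determined by the config seed.  Ground truth (per-guide
and per-region alpha, hit category) is returned alongside the counts for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectModel",
    "SimulationConfig",
    "simulate_peaks",
    "simulate_sequences",
    "assign_true_effects",
    "simulate_screen",
    "CONTROL_CLASSES",
]

#: Control pool labels: non-targeting, pan-lethal, pathway (Hippo-signaling),
#: canonical target genes.  Experimental guides carry the empty string.
CONTROL_CLASSES = ("NT", "PL", "HS", "YT")

_LINEAGES = ("MPM", "UM")


@dataclass(frozen=True)
class EffectModel:
    """Distribution of true per-day fitness effects (alpha).

    Fractions partition experimental regions into common hits (depleting in
    all cell lines), lineage-A / lineage-B specific hits (depleting only in
    the two models of one lineage) and inert regions (alpha = 0).  Alphas are
    drawn uniformly from the stated (lo, hi) ranges, independently per region
    and per active cell line.
    """

    frac_common: float = 0.14
    frac_lineage_a: float = 0.04
    frac_lineage_b: float = 0.04
    alpha_hit: tuple[float, float] = (-0.20, -0.05)
    alpha_pan_lethal: tuple[float, float] = (-0.25, -0.10)
    alpha_pathway: tuple[float, float] = (-0.15, -0.05)
    alpha_target_gene: tuple[float, float] = (-0.10, -0.02)

    def __post_init__(self) -> None:
        tot = self.frac_common + self.frac_lineage_a + self.frac_lineage_b
        if not 0 <= tot <= 1:
            raise ValueError("hit fractions must sum to at most 1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screen.

    The negative-binomial noise uses variance = mu + mu^2 * dispersion.
    ``timepoints`` are days post-infection and must start at 0 (the library
    representation sample).
    """

    n_regions: int = 500
    guides_per_region: int = 6
    n_cell_lines: int = 4
    replicates: int = 2
    timepoints: tuple[int, ...] = (0, 8, 15, 22)
    depth: float = 500.0
    dispersion: float = 0.05
    effect_model: EffectModel = field(default_factory=EffectModel)
    knee_neglogfdr: float = 50.0
    shared_fraction: float = 0.7
    strong_fraction: float = 0.75
    n_nt: int = 496
    n_pl: int = 1030
    n_hs: int = 419
    n_yt: int = 605
    share_day0_across_cell_lines: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        tps = tuple(self.timepoints)
        if list(tps) != sorted(tps) or tps[0] != 0:
            raise ValueError("timepoints must be sorted ascending and include day 0")
        if self.n_cell_lines < 2 or self.n_cell_lines % 2:
            raise ValueError("n_cell_lines must be an even count >= 2 (two lineages)")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        self.timepoints = tps

    def cell_lines(self) -> list[str]:
        """Cell model names, half per lineage (e.g. MPM1, MPM2, UM1, UM2)."""
        per = self.n_cell_lines // 2
        return [f"{lin}{i + 1}" for lin in _LINEAGES for i in range(per)]

    def lineage_of(self) -> dict[str, str]:
        return {cl: ("MPM" if cl.startswith("MPM") else "UM") for cl in self.cell_lines()}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mu + mu^2*dispersion (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-cell-line peak sets with a two-regime significance structure.

    Each region has a latent −log10(FDR): a weak bulk component
    Normal(0.2*knee, 0.06*knee) or, with probability ``strong_fraction``, a
    strong component Normal(knee, 3).  Per-cell-line values add N(0, 0.5)
    noise, so the per-line ECDF keeps its curvature maximum at the knee.
    A ``shared_fraction`` of regions has identical coordinates in every cell
    line; the rest are jittered per line and present with probability 0.8.

    Returns a mapping cell line -> DataFrame with columns
    (chrom, start, end, name, neglog10_fdr, fdr, strand, summit, cell_line),
    coordinates 0-based half-open, summit absolute.
    """
    if config.n_regions < 10:
        raise ValueError("n_regions must be >= 10")
    rng = _rng(config.seed, 1)
    n = config.n_regions
    knee = config.knee_neglogfdr

    # base region geometry on one synthetic chromosome, spaced so distinct
    # regions never overlap even after jitter
    widths = rng.integers(400, 1201, size=n)
    starts = 10_000 + np.arange(n) * 5_000
    ends = starts + widths
    summit_frac = rng.uniform(0.2, 0.8, size=n)

    strong = rng.random(n) < config.strong_fraction
    latent = np.where(
        strong,
        rng.normal(knee, 3.0, size=n),
        rng.normal(0.2 * knee, 0.06 * knee, size=n),
    )
    shared = rng.random(n) < config.shared_fraction

    out: dict[str, pd.DataFrame] = {}
    for cl in config.cell_lines():
        score = latent + rng.normal(0.0, 0.5, size=n)
        score = np.maximum(score, 0.05)
        jitter = np.where(shared, 0, rng.integers(-200, 201, size=n))
        present = shared | (rng.random(n) < 0.8)
        s = starts + jitter
        e = ends + jitter
        summit = (s + np.round(summit_frac * widths)).astype(int)
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": s,
                "end": e,
                "name": [f"{cl}_peak_{i:05d}" for i in range(n)],
                "neglog10_fdr": score,
                "fdr": np.power(10.0, -np.minimum(score, 300.0)),
                "strand": ".",
                "summit": summit,
                "cell_line": cl,
            }
        )[present]
        out[cl] = df.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def simulate_sequences(
    n_loci: int,
    length: int,
    seed: int,
    gc: float = 0.41,
    min_pams: int = 8,
    window: int = 300,
    max_tries: int = 200,
) -> dict[str, str]:
    """Uppercase ACGT locus sequences guaranteeing PAM density near the midpoint.

    Each locus is rejection-sampled until at least ``min_pams`` NGG PAM
    occurrences (GG on the forward strand or CC on the reverse-strand
    representation) fall within ±``window`` bp of the midpoint.
    """
    if length < 700:
        raise ValueError("length must be >= 700 to host a ±300 bp design window")
    if gc <= 0:
        raise ValueError("GC fraction must be positive: without G/C no NGG PAM can occur")
    rng = _rng(seed, 2)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    mid = length // 2
    lo, hi = max(0, mid - window), min(length, mid + window)

    out: dict[str, str] = {}
    for i in range(n_loci):
        for _ in range(max_tries):
            seq = "".join(alphabet[rng.choice(4, size=length, p=p)])
            core = seq[lo:hi]
            n_pam = core.count("GG") + core.count("CC")
            if n_pam >= min_pams:
                out[f"locus_{i:05d}"] = seq
                break
        else:  # pragma: no cover - requires pathological gc
            raise RuntimeError(
                f"could not place {min_pams} PAM sites in locus {i} after {max_tries} tries"
            )
    return out


# ---------------------------------------------------------------------------
# screen counts
# ---------------------------------------------------------------------------

def assign_true_effects(
    library: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ground-truth alphas for every guide in every cell line.

    ``library`` needs columns guide_id, union_id, control_class (empty string
    for experimental guides).  Regions are partitioned into hit categories by
    the config's effect model; every guide of a region inherits the region's
    per-cell-line alpha.  Control classes get class-specific alphas: NT is
    exactly 0 everywhere; PL/HS deplete in all lines; YT depletes mildly in
    all lines.

    Returns (guide_truth, region_truth).  guide_truth has one row per guide
    with columns guide_id, union_id, control_class, category and one
    ``alpha_<cell_line>`` column per model.
    """
    rng = _rng(config.seed, 3)
    cells = config.cell_lines()
    lineage = config.lineage_of()
    em = config.effect_model

    regions = (
        library.loc[library["control_class"] == "", "union_id"].drop_duplicates().tolist()
    )
    n = len(regions)
    cats = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    n_c = int(round(em.frac_common * n))
    n_a = int(round(em.frac_lineage_a * n))
    n_b = int(round(em.frac_lineage_b * n))
    cats[order[:n_c]] = "common"
    cats[order[n_c : n_c + n_a]] = "lineage-MPM"
    cats[order[n_c + n_a : n_c + n_a + n_b]] = "lineage-UM"

    region_alpha = pd.DataFrame(0.0, index=pd.Index(regions, name="union_id"), columns=cells)
    lo, hi = em.alpha_hit
    for i, (rid, cat) in enumerate(zip(regions, cats)):
        if cat == "none":
            continue
        for cl in cells:
            active = cat == "common" or cat == f"lineage-{lineage[cl]}"
            if active:
                region_alpha.loc[rid, cl] = rng.uniform(lo, hi)
    region_truth = region_alpha.add_prefix("alpha_").reset_index()
    region_truth.insert(1, "category", cats)

    class_ranges = {
        "NT": None,
        "PL": em.alpha_pan_lethal,
        "HS": em.alpha_pathway,
        "YT": em.alpha_target_gene,
    }
    rows = []
    for _, g in library.iterrows():
        cc = g["control_class"]
        if cc == "":
            a = region_alpha.loc[g["union_id"]].to_numpy()
            cat = cats[regions.index(g["union_id"])]
        elif cc == "NT":
            a = np.zeros(len(cells))
            cat = "control"
        else:
            rng_range = class_ranges[cc]
            a = np.full(len(cells), rng.uniform(*rng_range))
            cat = "control"
        rows.append([g["guide_id"], g["union_id"], cc, cat, *a])
    guide_truth = pd.DataFrame(
        rows, columns=["guide_id", "union_id", "control_class", "category"]
        + [f"alpha_{c}" for c in cells]
    )
    return guide_truth, region_truth


def simulate_screen(
    library: pd.DataFrame,
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the guide x sample count matrix of a dropout screen.

    Day-0 counts per (guide, replicate) are drawn once from
    NB(depth, dispersion) — the library representation of one infected
    pool — and each later harvest is an independent NB draw around the
    exponential dropout trajectory, mean depth * exp(alpha * t).  Cell
    lines get independent day-0 pools unless
    ``share_day0_across_cell_lines`` is set (one infection split across
    models).

    Returns (counts, guide_truth, region_truth).  Count columns follow the
    grammar ``<cellline>_rep<int>_day<int>``.
    """
    if library.empty:
        raise ValueError("library is empty")
    cells = config.cell_lines()
    if truth is None:
        guide_truth, region_truth = assign_true_effects(library, config)
    else:
        guide_truth, region_truth = truth, None
    missing = set(library["guide_id"]) - set(guide_truth["guide_id"])
    if missing:
        raise ValueError(f"missing true alpha for guides: {sorted(missing)[:5]} ...")
    alpha_cols = [f"alpha_{c}" for c in cells]
    if any(c not in guide_truth.columns for c in alpha_cols):
        raise ValueError("guide truth lacks per-cell-line alpha columns")

    gt = guide_truth.set_index("guide_id").loc[library["guide_id"]]
    rng = _rng(config.seed, 4)
    n_g = len(library)
    data: dict[str, np.ndarray] = {}
    for rep in range(1, config.replicates + 1):
        shared_day0 = _nb_draw(rng, np.full(n_g, config.depth), config.dispersion)
        for cl in cells:
            if config.share_day0_across_cell_lines:
                day0 = shared_day0
            else:
                day0 = _nb_draw(rng, np.full(n_g, config.depth), config.dispersion)
            alpha = gt[f"alpha_{cl}"].to_numpy()
            for t in config.timepoints:
                col = f"{cl}_rep{rep}_day{t}"
                if t == 0:
                    data[col] = day0
                else:
                    mean = config.depth * np.exp(alpha * t)
                    data[col] = _nb_draw(rng, mean, config.dispersion)
    counts = pd.DataFrame(data, index=pd.Index(library["guide_id"], name="guide_id"))
    if region_truth is None:
        return counts, guide_truth, pd.DataFrame()
    return counts, guide_truth, region_truth


def nt_logratio_check(counts: pd.DataFrame, nt_ids: Sequence[str], day: int = 22) -> float:
    """Mean per-guide log-ratio day/day0 over non-targeting guides.

    Diagnostic used by calibration tests: approaches 0 as depth grows.
    """
    from .workflow_io import sample_metadata

    meta = sample_metadata(counts.columns)
    sub = counts.loc[list(nt_ids)]
    vals = []
    for (cl, rep), grp in meta.groupby(["cell_line", "replicate"]):
        c0 = sub[grp.loc[grp["day"] == 0, "sample"].iloc[0]].to_numpy(float)
        ct = sub[grp.loc[grp["day"] == day, "sample"].iloc[0]].to_numpy(float)
        ok = (c0 > 0) & (ct > 0)
        vals.append(np.log(ct[ok] / c0[ok]))
    return float(np.mean(np.concatenate(vals)))
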