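"""End-to-end orchestration: simulate -> design -> analyze -> signal.

Each stage reads its inputs from, and writes its outputs to, the configured
output directory, so stages can be re-run independently; a stage whose
inputs are missing raises :class:`DependencyError`.  All randomness flows
from the config seed, every output file is listed in a manifest with a
content hash, and two runs with equal configs produce byte-identical
outputs.

Stage contents
--------------
simulate
    Per-cell-line peak sets (BED6+2).  Locus sequences and screen counts are
    generated later, inside design and analyze, because they depend on the
    consensus peak set and on the designed library.
design
    Per-cell-line significance cutoff (ECDF knee), retained-peak union,
    locus sequences, candidate enumeration + filtering, pool assembly with
    control pools, oligo emission.
analyze
    Screen count simulation with ground truth, control-median normalization,
    per-guide log2FC + depletion tests, per-region exponential fitness fits,
    rank aggregation, differential guides between lineage representatives,
    secondary hit calling, and a recovery summary against the planted truth.
signal
    Synthetic occupancy/mark tracks over the consensus peaks, binned
    matrices with percentile clipping and 0-1 scaling, k-means clustering,
    ±250 bp coverage and log-scale Spearman correlations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, library_design as ld, region_signal as rs
from . import screen_analysis as sa
from . import synthetic_data as sd
from . import workflow_io as io

__all__ = ["DependencyError", "run_pipeline"]

log = logging.getLogger("crisprtile.pipeline")


class DependencyError(RuntimeError):
    """A stage's required input is missing (earlier stage not run)."""


def _sim_config(cfg: io.PipelineConfig) -> sd.SimulationConfig:
    return sd.SimulationConfig(
        n_regions=cfg.n_regions,
        guides_per_region=cfg.guides_per_region,
        n_cell_lines=cfg.n_cell_lines,
        replicates=cfg.replicates,
        timepoints=cfg.timepoints,
        depth=cfg.depth,
        dispersion=cfg.dispersion,
        effect_model=sd.EffectModel(
            frac_common=cfg.frac_common,
            frac_lineage_a=cfg.frac_lineage_a,
            frac_lineage_b=cfg.frac_lineage_b,
        ),
        knee_neglogfdr=cfg.knee_neglogfdr,
        shared_fraction=cfg.shared_fraction,
        strong_fraction=cfg.strong_fraction,
        n_nt=cfg.n_nt,
        n_pl=cfg.n_pl,
        n_hs=cfg.n_hs,
        n_yt=cfg.n_yt,
        seed=cfg.seed,
    )


def _register(manifest: dict, out: Path, *paths: Path) -> None:
    for p in paths:
        manifest["outputs"][str(p.relative_to(out))] = io.sha256_of(p)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: io.PipelineConfig, out: Path, manifest: dict) -> None:
    sim = _sim_config(cfg)
    peaks = sd.simulate_peaks(sim)
    for cl, df in peaks.items():
        path = out / f"peaks_{cl}.bed"
        io.write_bed_peaks(df, path)
        _register(manifest, out, path)
    log.info("simulate: wrote %d peak sets (n_regions=%d, knee=%.1f)",
             len(peaks), cfg.n_regions, cfg.knee_neglogfdr)


def _random_protospacers(n: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    """Unique BbsI-free random 20-mers for control pools."""
    alphabet = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        seq = "".join(alphabet[rng.integers(0, 4, size=20)])
        if seq in taken or any(site in seq for site in ld.BBSI_SITES):
            continue
        taken.add(seq)
        out.append(seq)
    return out


def stage_design(cfg: io.PipelineConfig, out: Path, manifest: dict) -> None:
    sim = _sim_config(cfg)
    peak_files = {cl: out / f"peaks_{cl}.bed" for cl in sim.cell_lines()}
    missing = [str(p) for p in peak_files.values() if not p.exists()]
    if missing:
        raise DependencyError(f"design needs peak files from the simulate stage: {missing}")

    retained: dict[str, pd.DataFrame] = {}
    cutoffs: dict[str, float] = {}
    for cl, path in peak_files.items():
        df = io.read_bed_peaks(path)
        cut = ld.select_peak_cutoff(df["fdr"], knots=cfg.knots, df=cfg.df)
        cutoffs[cl] = cut
        retained[cl] = df[df["neglog10_fdr"] >= cut].reset_index(drop=True)
        log.info("design: %s cutoff -log10(FDR)=%.2f retains %d/%d peaks",
                 cl, cut, len(retained[cl]), len(df))
    consensus = ld.union_peaks(retained)

    loci = sd.simulate_sequences(
        n_loci=len(consensus), length=cfg.locus_length, seed=cfg.seed,
        min_pams=4 * cfg.guides_per_region, window=cfg.window,
    )
    sequences: dict[str, str] = {}
    candidates: dict[str, list[ld.GuideCandidate]] = {}
    for (_, peak), (locus_name, seq) in zip(consensus.iterrows(), loci.items()):
        seq_start = int(peak["summit"]) - cfg.locus_length // 2
        cands = ld.enumerate_candidates(seq, int(peak["summit"]), cfg.window, seq_start)
        kept = ld.filter_candidates(cands, cfg.min_gap)
        candidates[peak["union_id"]] = kept[: cfg.guides_per_region]
        sequences[peak["union_id"]] = seq

    rng = np.random.default_rng([cfg.seed, 5])
    taken: set[str] = set()
    controls = {
        "NT": _random_protospacers(cfg.n_nt, rng, taken),
        "PL": _random_protospacers(cfg.n_pl, rng, taken),
        "HS": _random_protospacers(cfg.n_hs, rng, taken),
        "YT": _random_protospacers(cfg.n_yt, rng, taken),
    }
    library = ld.assemble_library(
        consensus, candidates, (cfg.pool_cutoff_strict, cfg.pool_cutoff_loose), controls
    )
    oligos = ld.emit_oligos(library)

    consensus_path = out / "consensus_peaks.tsv"
    consensus.to_csv(consensus_path, sep="\t", index=False)
    cutoff_path = out / "peak_cutoffs.json"
    cutoff_path.write_text(json.dumps(cutoffs, indent=2, sort_keys=True))
    loci_path = out / "loci.fasta"
    io.write_fasta(sequences, loci_path)
    lib_path = out / "library.tsv"
    io.write_library(library, lib_path)
    oligo_path = out / "oligos.fasta"
    io.write_fasta(dict(zip(library["guide_id"], oligos)), oligo_path)
    _register(manifest, out, consensus_path, cutoff_path, loci_path, lib_path, oligo_path)
    log.info("design: %d consensus regions, %d library entries",
             len(consensus), len(library))


def _recovery_summary(hits: pd.DataFrame, region_truth: pd.DataFrame) -> dict:
    """Planted-vs-called hit comparison for the demo screen."""
    truth = region_truth.set_index("union_id")["category"]
    called = hits.set_index("union_id")["category"].reindex(truth.index, fill_value="none")
    planted_common = truth == "common"
    planted_lineage = truth.str.startswith("lineage")
    planted_none = truth == "none"
    n_hits = int((planted_common | planted_lineage).sum())

    rec_common = float((called[planted_common] == "common").mean()) if planted_common.any() else float("nan")
    rec_lineage = (
        float((called[planted_lineage] == truth[planted_lineage]).mean())
        if planted_lineage.any()
        else float("nan")
    )
    confused = int((called[planted_common].str.startswith("lineage")).sum()) + int(
        (called[planted_lineage] == "common").sum()
    )
    return {
        "n_regions": int(len(truth)),
        "n_planted_common": int(planted_common.sum()),
        "n_planted_lineage": int(planted_lineage.sum()),
        "recovery_common": rec_common,
        "recovery_lineage": rec_lineage,
        "confusion_rate": confused / n_hits if n_hits else float("nan"),
        "null_call_rate": float((called[planted_none] != "none").mean())
        if planted_none.any()
        else float("nan"),
    }


def stage_analyze(cfg: io.PipelineConfig, out: Path, manifest: dict) -> None:
    lib_path = out / "library.tsv"
    if not lib_path.exists():
        raise DependencyError("analyze needs library.tsv from the design stage")
    library = io.read_library(lib_path)
    sim = _sim_config(cfg)

    counts, guide_truth, region_truth = sd.simulate_screen(library, sim)
    io.write_counts(counts, out / "counts.tsv")
    guide_truth.to_csv(out / "truth_guides.tsv", sep="\t", index=False)
    region_truth.to_csv(out / "truth_regions.tsv", sep="\t", index=False)

    nt_ids = library.loc[library["control_class"] == "NT", "guide_id"]
    norm = sa.normalize_to_controls(counts, nt_ids, target=cfg.norm_target)
    per_rep = sa.guide_lfc(norm)
    final_day = max(cfg.timepoints)
    dep = sa.guide_depletion_test(per_rep, day=final_day)
    dep.to_csv(out / "guide_stats.tsv", sep="\t", index=False)

    g2r = library.set_index("guide_id")["union_id"]
    fitness = sa.fit_fitness_all(norm, g2r)
    fitness.to_csv(out / "fitness.tsv", sep="\t", index=False)

    lineage_map = sim.lineage_of()
    hits = sa.call_hits_secondary(fitness, lineage_map, alpha_p=cfg.alpha_p)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)

    rra_frames = []
    for cl in sim.cell_lines():
        p = dep[dep["cell_line"] == cl].set_index("guide_id")["p"]
        r = sa.aggregate_region_rra(
            p, g2r, alpha0=cfg.rra_alpha0,
            n_permutations=cfg.rra_permutations, seed=cfg.seed,
        )
        r.insert(1, "cell_line", cl)
        rra_frames.append(r)
    pd.concat(rra_frames, ignore_index=True).to_csv(out / "region_rra.tsv", sep="\t", index=False)

    cells = sim.cell_lines()
    rep_a = per_rep[per_rep["cell_line"] == cells[0]]
    rep_b = per_rep[per_rep["cell_line"] == cells[sim.n_cell_lines // 2]]
    diff = sa.differential_lineage(
        rep_a, rep_b, day=final_day,
        lfc_thresh=cfg.lfc_thresh, fdr_thresh=cfg.fdr_thresh,
    )
    diff.to_csv(out / "differential.tsv", sep="\t", index=False)

    # genome-browser display track: -log10(min fitness p across models)
    consensus = pd.read_csv(out / "consensus_peaks.tsv", sep="\t")
    min_p = fitness.groupby("union_id")["p"].min()
    track = consensus[["chrom", "start", "end", "union_id"]].copy()
    track["value"] = -np.log10(np.maximum(min_p.reindex(track["union_id"]).to_numpy(), 1e-300))
    io.write_bedgraph(track, out / "hits.bedgraph")

    recovery = _recovery_summary(hits, region_truth)
    (out / "recovery.json").write_text(json.dumps(recovery, indent=2, sort_keys=True))
    log.info("analyze: %s", recovery)
    _register(
        manifest, out,
        out / "counts.tsv", out / "truth_guides.tsv", out / "truth_regions.tsv",
        out / "guide_stats.tsv", out / "fitness.tsv", out / "hits.tsv",
        out / "region_rra.tsv", out / "differential.tsv", out / "hits.bedgraph",
        out / "recovery.json",
    )


def _gaussian_track(
    summits: pd.DataFrame, amps: np.ndarray, sd_bp: float, step: int, pad: int
) -> pd.DataFrame:
    """Piecewise-constant bedGraph of Gaussian bumps at summits (one chrom)."""
    lo = int(summits["summit"].min()) - pad
    hi = int(summits["summit"].max()) + pad
    grid = np.arange(lo, hi, step)
    vals = np.zeros(grid.size)
    for s, a in zip(summits["summit"], amps):
        vals += a * np.exp(-0.5 * ((grid + step / 2 - s) / sd_bp) ** 2)
    return pd.DataFrame(
        {
            "chrom": summits["chrom"].iloc[0],
            "start": grid,
            "end": grid + step,
            "value": np.round(vals, 4),
        }
    )


def stage_signal(cfg: io.PipelineConfig, out: Path, manifest: dict) -> None:
    cons_path = out / "consensus_peaks.tsv"
    if not cons_path.exists():
        raise DependencyError("signal needs consensus_peaks.tsv from the design stage")
    consensus = pd.read_csv(cons_path, sep="\t")
    rng = np.random.default_rng([cfg.seed, 6])
    pad = cfg.half_window + 500

    # two planted region classes (promoter-like vs enhancer-like) drive the
    # mark tracks; occupancy amplitude follows peak significance
    promoter_like = rng.random(len(consensus)) < 0.5
    occ_amp = consensus["neglog10_best_fdr"].to_numpy() / 10.0
    prom_amp = np.where(promoter_like, 8.0, 1.0) * (1 + 0.1 * rng.random(len(consensus)))
    enh_amp = np.where(promoter_like, 1.0, 8.0) * (1 + 0.1 * rng.random(len(consensus)))

    tracks = {
        "occupancy": _gaussian_track(consensus, occ_amp, 300.0, 25, pad),
        "mark_promoter": _gaussian_track(consensus, prom_amp, 400.0, 25, pad),
        "mark_enhancer": _gaussian_track(consensus, enh_amp, 400.0, 25, pad),
    }
    for name, tr in tracks.items():
        io.write_bedgraph(tr, out / f"track_{name}.bedgraph")

    summits = consensus.rename(columns={"union_id": "region_id"})[
        ["region_id", "chrom", "summit"]
    ]
    mats = {
        name: rs.clip_scale(
            rs.bin_signal(tr, summits, cfg.half_window, cfg.n_bins),
            cfg.hi_pct, cfg.lo_pct,
        )
        for name, tr in tracks.items()
    }
    clusters = rs.cluster_regions(
        [mats["mark_promoter"], mats["mark_enhancer"]],
        k=cfg.k_clusters, seed=cfg.seed, ranking=mats["occupancy"],
    )
    matrix = mats["occupancy"].to_frame()
    matrix.insert(0, "cluster", clusters.set_index("region")["cluster"].reindex(matrix.index))
    matrix.to_csv(out / "signal_matrix.tsv", sep="\t")
    clusters.to_csv(out / "signal_clusters.tsv", sep="\t", index=False)

    centers = consensus.rename(columns={"union_id": "region_id", "summit": "center"})[
        ["region_id", "chrom", "center"]
    ]
    cov = rs.coverage_at(centers, tracks, halfwidth=cfg.coverage_halfwidth)
    cov.to_csv(out / "coverage.tsv", sep="\t")
    corr = rs.log_rank_correlation(cov)
    corr.to_csv(out / "correlation.tsv", sep="\t")
    _register(
        manifest, out,
        *(out / f"track_{n}.bedgraph" for n in tracks),
        out / "signal_matrix.tsv", out / "signal_clusters.tsv",
        out / "coverage.tsv", out / "correlation.tsv",
    )
    log.info("signal: %d regions binned into %d bins", len(matrix), cfg.n_bins)


_STAGES = {
    "simulate": stage_simulate,
    "design": stage_design,
    "analyze": stage_analyze,
    "signal": stage_signal,
}

_ORDER = ("simulate", "design", "analyze", "signal")


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the output manifest.

    The manifest records the config, package version, and a sha256 content
    hash for every output file; it is also written to ``manifest.json`` in
    the output directory.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": {},
    }
    for stage in _ORDER:
        if stage in config.stages:
            log.info("running stage %s (seed=%d)", stage, config.seed)
            _STAGES[stage](config, out, manifest)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list))
    return manifest
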