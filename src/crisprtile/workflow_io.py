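"""File formats and configuration for the tiling-screen pipeline.

Genomic intervals are 0-based half-open throughout; summits are stored as
absolute coordinates.  Peak files are BED6+2 (chrom, start, end, name,
score = −log10 FDR, strand, summit, cell line).  Count matrices are TSV with
a guide_id index and sample columns following the grammar
``<cellline>_rep<int>_day<int>`` so sample metadata parses from headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BedFormatError",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_counts",
    "write_counts",
    "parse_sample_name",
    "sample_metadata",
    "read_library",
    "write_library",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "PipelineConfig",
    "sha256_of",
]

_SAMPLE_RE = re.compile(r"^(?P<cell_line>[^_]+)_rep(?P<replicate>\d+)_day(?P<day>\d+)$")

_PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "neglog10_fdr",
    "strand",
    "summit",
    "cell_line",
]


class BedFormatError(ValueError):
    """Malformed BED peak line, reported with its line number."""


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED6+2 peak file (score column = −log10 FDR, field 7 = absolute
    summit, field 8 = cell line)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise BedFormatError(
                    f"{path}:{lineno}: expected 8 tab-separated fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
                score = float(parts[4])
                summit = int(parts[6])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise BedFormatError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            if not (start <= summit < end):
                raise BedFormatError(
                    f"{path}:{lineno}: summit {summit} outside [{start}, {end})"
                )
            rows.append((parts[0], start, end, parts[3], score, parts[5], summit, parts[7]))
    df = pd.DataFrame(rows, columns=_PEAK_COLUMNS)
    df["fdr"] = 10.0 ** -df["neglog10_fdr"].clip(upper=300.0)
    return df


def write_bed_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.to_csv(path, sep="\t", header=False, index=False, columns=_PEAK_COLUMNS)


def parse_sample_name(name: str) -> tuple[str, int, int]:
    """Parse ``<cellline>_rep<int>_day<int>`` into (cell_line, replicate, day)."""
    m = _SAMPLE_RE.match(name)
    if not m:
        raise ValueError(f"sample name {name!r} does not match <cellline>_rep<int>_day<int>")
    return m["cell_line"], int(m["replicate"]), int(m["day"])


def sample_metadata(columns: Iterable[str]) -> pd.DataFrame:
    """Sample table (sample, cell_line, replicate, day) parsed from headers."""
    rows = [(c, *parse_sample_name(c)) for c in columns]
    return pd.DataFrame(rows, columns=["sample", "cell_line", "replicate", "day"])


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    sample_metadata(df.columns)  # validates the header grammar
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="guide_id")


def read_library(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"control_class": str})


def write_library(library: pd.DataFrame, path: str | Path) -> None:
    library.to_csv(path, sep="\t", index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], comment="#"
    )


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(
        path, sep="\t", header=False, index=False, columns=["chrom", "start", "end", "value"]
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """All tunables of the simulate -> design -> analyze -> signal pipeline.

    Round-trips losslessly through YAML; unknown keys are rejected.
    """

    outdir: str = "pipeline_out"
    stages: tuple[str, ...] = ("simulate", "design", "analyze", "signal")
    seed: int = 7

    # synthetic screen conditions
    n_regions: int = 500
    guides_per_region: int = 6
    n_cell_lines: int = 4
    replicates: int = 2
    timepoints: tuple[int, ...] = (0, 8, 15, 22)
    depth: float = 500.0
    dispersion: float = 0.05
    knee_neglogfdr: float = 50.0
    shared_fraction: float = 0.7
    strong_fraction: float = 0.75
    frac_common: float = 0.14
    frac_lineage_a: float = 0.04
    frac_lineage_b: float = 0.04
    n_nt: int = 496
    n_pl: int = 1030
    n_hs: int = 419
    n_yt: int = 605

    # design parameters
    knots: int = 20
    df: float = 15.0
    window: int = 300
    min_gap: int = 20
    pool_cutoff_strict: float = 55.0
    pool_cutoff_loose: float = 40.0
    locus_length: int = 800

    # analysis parameters
    norm_target: float = 1000.0
    alpha_p: float = 0.05
    lfc_thresh: float = 1.0
    fdr_thresh: float = 0.05
    rra_alpha0: float = 0.25
    rra_permutations: int = 2000

    # signal parameters
    half_window: int = 2000
    n_bins: int = 100
    hi_pct: float = 98.0
    lo_pct: float = 1.0
    k_clusters: int = 2
    coverage_halfwidth: int = 250

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.timepoints = tuple(self.timepoints)
        known = {"simulate", "design", "analyze", "signal"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a flat key-value mapping")
        names = {f.name for f in fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["timepoints"] = list(self.timepoints)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
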