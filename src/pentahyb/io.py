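"""Readers, writers and run configuration.

All tables are tab-separated UTF-8 with ``#`` comment lines; genomic
features are BED6 (0-based half-open); sequences are plain FASTA via
Biopython.  Every writer prepends a provenance header carrying the tool
version, the configuration hash and the seed, so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_intensity_tsv",
    "write_intensity_tsv",
    "write_bed",
    "read_sample_sheet",
    "write_sample_sheet",
    "provenance_header",
]


@dataclass
class RunConfig:
    """Validated design/fit parameters (flat key=value file format)."""

    probe_length: int = 25
    tiling_step: int = 1
    max_mm: int = 3
    max_gaps: int = 1
    probeset_window: int = 400
    probeset_min: int = 3
    probeset_max: int = 6
    min_separation: int = 8
    lasso_folds: int = 10
    fit_tol: float = 1e-6
    fit_max_iter: int = 100
    q_threshold: float = 0.01
    fc_threshold: float = 2.0
    intensity_floor: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.tiling_step <= 4:
            raise ValueError("tiling_step must be in [1, 4]")
        if not 3 <= self.probeset_min <= self.probeset_max <= 6:
            raise ValueError("need 3 <= probeset_min <= probeset_max <= 6")
        if self.probeset_window <= self.probe_length:
            raise ValueError("probeset_window must exceed probe_length")
        if self.lasso_folds < 2:
            raise ValueError("lasso_folds must be >= 2")
        if self.max_mm < 0 or self.max_gaps < 0:
            raise ValueError("alignment budgets must be non-negative")

    def config_hash(self) -> str:
        payload = ";".join(f"{f.name}={getattr(self, f.name)!r}" for f in fields(self))
        return hashlib.md5(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            kwargs[key] = float(val) if "float" in str(casts[key]) else int(val)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text(provenance_header(self) + "\n".join(lines) + "\n")


def provenance_header(config: RunConfig | None = None, seed: int | None = None) -> str:
    h = config.config_hash() if config is not None else "none"
    s = seed if seed is not None else (config.seed if config is not None else "NA")
    return f"# pentahyb {__version__} | config {h} | seed {s}\n"


def read_fasta(path) -> dict:
    """FASTA records as an ordered id->sequence dict; duplicate ids rejected."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(records: dict, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()),
        str(path),
        "fasta",
    )


def read_intensity_tsv(path) -> pd.DataFrame:
    """Probe x array intensity matrix; rectangular with finite cells."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty intensity matrix")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    na = df.isna()
    if na.any().any():
        r = df.index[na.any(axis=1)][0]
        c = df.columns[na.loc[r]][0]
        raise ValueError(f"{path}: missing intensity at probe {r!r}, array {c!r}")
    return df.astype(float)


def write_intensity_tsv(df: pd.DataFrame, path, config: RunConfig | None = None,
                        seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index_label="probe_id")


def write_bed(features, path, config: RunConfig | None = None) -> None:
    """BED6 export (0-based half-open) of probes or probesets.

    ``features`` yields objects with source_contig/start/end/strand and an
    id, or (chrom, start, end, name, score, strand) tuples.
    """
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        for f in features:
            if isinstance(f, tuple):
                chrom, start, end, name, score, strand = f
            else:
                probe = getattr(f, "probe", f)
                chrom = probe.source_contig
                start, end, strand = probe.start, probe.end, probe.strand
                name = probe.probe_id
                score = 0
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"array_id", "sample", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    if df["array_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate array ids")
    return df


def write_sample_sheet(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config))
        df.to_csv(fh, sep="\t", index=False)
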