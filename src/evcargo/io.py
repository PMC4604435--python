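"""File-format plumbing: FASTA/BED/TSV readers and writers, run config.

Coordinate policy: a single internal convention (1-based closed intervals,
transcript-oriented where applicable); BED is 0-based half-open on disk and
converted exactly once here.  TSVs are UTF-8, tab-delimited, single header
row, deterministic column order; count tables carry their library id and
unique-mapper total in a leading ``#`` comment so they round-trip.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .counting import GeneCounts
from .synthetic_data import ConfigError, GeneAnnotation, ReferenceBundle


class BedFormatError(ValueError):
    """Malformed BED line."""


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED6(+1 family column) -> annotations in 1-based closed coordinates."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedFormatError(
                    f"{path}: line {lineno}: expected >=6 fields, got {len(fields)}: {line!r}"
                )
            chrom, start0, end0, name, _score, strand = fields[:6]
            family = fields[6] if len(fields) > 6 else ""
            try:
                start0_i, end0_i = int(start0), int(end0)
            except ValueError:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates: {line!r}"
                ) from None
            if end0_i <= start0_i:
                raise BedFormatError(f"{path}: line {lineno}: empty interval: {line!r}")
            out.append(
                GeneAnnotation(name, family, chrom, start0_i + 1, end0_i, strand)
            )
    return out


def write_bed(annotations: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.chrom}\t{a.start - 1}\t{a.end}\t{a.gene_id}\t0\t{a.strand}\t{a.family}\n"
            )


def load_reference(fasta_path: str | Path, bed_path: str | Path) -> ReferenceBundle:
    """Rebuild a ReferenceBundle from its on-disk FASTA + BED form.

    Pseudogene membership is recovered from annotations whose family is
    ``pseudogene`` and whose id is ``<parent>P<number>``."""
    chroms = read_fasta(fasta_path)
    annotations = read_bed(bed_path)
    gene_ids = {a.gene_id for a in annotations}
    pseudo: dict[str, list[str]] = {}
    for a in annotations:
        if a.family != "pseudogene":
            continue
        m = re.fullmatch(r"(.+?)P\d+", a.gene_id)
        if m and m.group(1) in gene_ids:
            pseudo.setdefault(m.group(1), []).append(a.gene_id)
    return ReferenceBundle(chroms, annotations, pseudo)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def write_counts_tsv(
    counts: GeneCounts,
    path: str | Path,
    annotations: list[GeneAnnotation] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_id={counts.library_id}\ttotal_unique={counts.total_unique}\n")
        counts.to_frame(annotations).to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> GeneCounts:
    with open(path) as fh:
        header = fh.readline()
        m = re.match(r"# library_id=(\S+)\ttotal_unique=(\d+)", header)
        if not m:
            raise ValueError(f"{path}: missing counts metadata header")
        df = pd.read_csv(fh, sep="\t")
    return GeneCounts(
        m.group(1),
        dict(zip(df["gene_id"], df["count"].astype(int))),
        int(m.group(2)),
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end run; the seed is mandatory."""

    seed: int
    out_dir: str = "evcargo_run"
    n_reads: int = 100_000
    error_rate: float = 0.001
    profiles: list[str] = field(
        default_factory=lambda: ["bj_cell", "bj_ev", "k562_cell", "k562_ev"]
    )
    max_mismatches: int = 5
    max_loci: int = 10
    fragment_threshold: float = 1000.0
    fragment_policy: str = "include_pseudogene_set"
    hoechst_threshold: float = 1000.0
    yopro_threshold: float = 500.0
    cytometry_events: int = 10_000
    cytometry_conditions: list[str] = field(
        default_factory=lambda: [
            "bj_untreated",
            "bj_mock",
            "bj_plus_bj_ev_rna",
            "bj_plus_k562_ev_rna",
            "bj_coculture_k562",
        ]
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("run config requires an explicit seed")
        self.seed = int(self.seed)
        if not self.profiles:
            raise ConfigError("run config requires at least one library profile")

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ConfigError(f"{path}: config missing required 'seed'")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)
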