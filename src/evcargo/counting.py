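"""Union-mode gene counting on unique mappers, rpm, families, enrichment.

A SAM record is counted toward a gene when (a) its NH tag equals 1 and
(b) its alignment interval overlaps exactly one gene annotation.  Records
overlapping no gene are ``no_feature``; records overlapping more than one
are ``ambiguous`` and discarded.  Multimappers (NH > 1) are excluded from
counting *and* from the rpm denominator: reads-per-million for a gene is

    rpm(g) = count(g) / total_unique_mappers * 1e6

where the denominator includes unique no_feature records.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps

from .synthetic_data import GeneAnnotation

#: Families shown by name in the composition tables; everything else folds
#: into "Others" (pseudogenes, mitochondrial tRNA, antisense, ...).
NAMED_FAMILIES = (
    "lincRNA",
    "miRNA",
    "miscRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "protein_coding",
)


class SamFormatError(ValueError):
    """SAM input missing required information (e.g. NH tags)."""


class GeneInterval:
    """Per-chromosome sorted interval lookup for non-overlapping genes."""

    def __init__(self, annotations: list[GeneAnnotation]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[GeneAnnotation]]] = {}
        for chrom in {a.chrom for a in annotations}:
            anns = sorted(
                (a for a in annotations if a.chrom == chrom), key=lambda a: a.start
            )
            self._by_chrom[chrom] = (
                [a.start for a in anns],
                [a.end for a in anns],
                anns,
            )

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneAnnotation]:
        """Genes overlapping the 1-based closed interval [start, end]."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, anns = entry
        out = []
        i = bisect_right(starts, end) - 1
        while i >= 0 and ends[i] >= start:
            out.append(anns[i])
            i -= 1
        out.reverse()
        return out


@dataclass
class GeneCounts:
    """Per-gene unique-mapper counts for one library."""

    library_id: str
    counts: dict[str, int]
    total_unique: int
    stats: dict[str, int] = field(default_factory=dict)

    def rpm(self, gene: str) -> float:
        if self.total_unique == 0:
            return 0.0
        return self.counts.get(gene, 0) / self.total_unique * 1e6

    def rpm_table(self) -> dict[str, float]:
        return {g: self.rpm(g) for g in self.counts}

    def to_frame(self, annotations: list[GeneAnnotation] | None = None) -> pd.DataFrame:
        fam = {a.gene_id: a.family for a in annotations} if annotations else {}
        rows = [
            {
                "gene_id": g,
                "family": fam.get(g, ""),
                "count": c,
                "rpm": self.rpm(g),
            }
            for g, c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "family", "count", "rpm"])


def count_genes(
    sam_path: str | Path,
    annotations: list[GeneAnnotation],
    library_id: str | None = None,
) -> GeneCounts:
    """Union-mode counting of a SAM file.

    Secondary records of a multimapper are classified once per record; the
    conservation invariant ``counted + no_feature + ambiguous + multimapper
    == total records`` holds over SAM records.
    """
    lookup = GeneInterval(annotations)
    counts: dict[str, int] = {a.gene_id: 0 for a in annotations}
    stats = {
        "total_records": 0,
        "counted": 0,
        "no_feature": 0,
        "ambiguous": 0,
        "multimapper": 0,
    }
    total_unique = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            stats["total_records"] += 1
            try:
                nh = rec.get_tag("NH")
            except KeyError:
                raise SamFormatError(
                    f"{sam_path}: record {rec.query_name} lacks NH tag"
                ) from None
            if nh > 1:
                stats["multimapper"] += 1
                continue
            total_unique += 1
            start = rec.reference_start + 1
            end = rec.reference_end  # pysam half-open end == closed 1-based end
            hits = lookup.overlapping(rec.reference_name, start, end)
            if len(hits) == 1:
                counts[hits[0].gene_id] += 1
                stats["counted"] += 1
            elif len(hits) == 0:
                stats["no_feature"] += 1
            else:
                stats["ambiguous"] += 1
    return GeneCounts(
        library_id or Path(sam_path).stem, counts, total_unique, stats
    )


@dataclass
class FamilyAbundance:
    """RNA-family composition of one library ("pie chart" table)."""

    library_id: str
    table: pd.DataFrame  # columns: family, rpm, fraction
    others_members: list[str]

    def fraction(self, family: str) -> float:
        row = self.table.loc[self.table["family"] == family, "fraction"]
        return float(row.iloc[0]) if len(row) else 0.0

    def rpm(self, family: str) -> float:
        row = self.table.loc[self.table["family"] == family, "rpm"]
        return float(row.iloc[0]) if len(row) else 0.0


def family_table(
    counts: GeneCounts,
    annotations: list[GeneAnnotation],
    named_families: tuple[str, ...] = NAMED_FAMILIES,
) -> FamilyAbundance:
    """Aggregate gene rpm into family rpm; families outside the named set
    fold into "Others"."""
    fam_of = {a.gene_id: a.family for a in annotations}
    fam_rpm: dict[str, float] = {}
    others: list[str] = []
    for gene, n in counts.counts.items():
        family = fam_of.get(gene)
        if family is None:
            raise ValueError(f"gene {gene!r} has no family label")
        if family not in named_families:
            if family not in others:
                others.append(family)
            family = "Others"
        fam_rpm[family] = fam_rpm.get(family, 0.0) + counts.rpm(gene)
    total = sum(fam_rpm.values())
    rows = [
        {"family": f, "rpm": r, "fraction": (r / total if total else 0.0)}
        for f, r in sorted(fam_rpm.items(), key=lambda kv: -kv[1])
    ]
    return FamilyAbundance(
        counts.library_id,
        pd.DataFrame(rows, columns=["family", "rpm", "fraction"]),
        sorted(others),
    )


def enrichment(ev_counts: GeneCounts, cell_counts: GeneCounts, gene: str) -> float:
    """EV-versus-cell rpm fold-enrichment, rpm_ev / rpm_cell.

    A gene absent from the cell library yields ``inf`` with a warning.
    """
    rpm_ev = ev_counts.rpm(gene)
    rpm_cell = cell_counts.rpm(gene)
    if rpm_cell == 0.0:
        warnings.warn(
            f"{gene}: zero rpm in cell library; enrichment reported as inf",
            stacklevel=2,
        )
        return math.inf
    return rpm_ev / rpm_cell


def ev_cell_ratio(ev_counts: GeneCounts, cell_counts: GeneCounts) -> dict[str, float]:
    """Per-gene rpm_ev / (rpm_ev + rpm_cell) over genes expressed in either
    library; values in [0, 1]."""
    out: dict[str, float] = {}
    genes = set(ev_counts.counts) | set(cell_counts.counts)
    for g in sorted(genes):
        a, b = ev_counts.rpm(g), cell_counts.rpm(g)
        if a + b > 0:
            out[g] = a / (a + b)
    return out


def replicate_correlation(counts_a: GeneCounts, counts_b: GeneCounts) -> float:
    """Pearson r on log10(rpm + 1) over genes expressed in either library."""
    genes = sorted(
        g
        for g in set(counts_a.counts) | set(counts_b.counts)
        if counts_a.counts.get(g, 0) > 0 or counts_b.counts.get(g, 0) > 0
    )
    if len(genes) < 2:
        raise ValueError("need at least two expressed genes")
    x = np.log10(np.array([counts_a.rpm(g) for g in genes]) + 1.0)
    y = np.log10(np.array([counts_b.rpm(g) for g in genes]) + 1.0)
    r, _p = sps.pearsonr(x, y)
    return float(r)
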