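"""Synthetic inputs for the pipeline, with declared ground truth.

Four generators live here:

``build_reference``
    A toy two-chromosome genome carrying an RNY5 locus (the printed 83-nt
    transcript), a panel of background small-RNA genes with family labels,
    and RNY5 pseudogene decoys: two loci identical to the first 29 nt of
    RNY5 and three near-identical (~97%) loci.  Reads of 29 nt or shorter
    that start at the RNY5 5' end therefore multimap, as in the real genome.

``simulate_library``
    Paired whole-cell / EV small-RNA libraries.  Per-read gene identity is
    multinomial over the profile's source fractions; RNY5 reads are drawn
    from a fragment model concentrated on the processed forms
    (1,23), (1,29), (1,31), full-length (1,83) and the 3'-side (52,83).

``simulate_processing``
    A rule table reproducing the qualitative in-vitro processing outcomes:
    EV extract converts motif-bearing substrates into the 23/29/31-nt
    products, whole-cell extract leaves everything intact, and a substrate
    whose motif was replaced shows only residual 23-nt product.

``simulate_cytometry``
    Two-channel (Hoechst, YO-PRO-1) event tables with a configured true
    dead fraction and a small Hoechst-negative debris population.

Library profiles are *anchored at measured values*: the packaged profiles
solve for generation probabilities such that the pipeline's unique-mapper
measurements reproduce the anchor numbers (RNY5 share of assigned reads,
EV/cell rpm enrichment) in expectation.  See docs/methods.md for the
derivation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .sequences import (
    PROCESSING_MOTIF,
    RNY5_31MER,
    RNY5_83MER,
    RnaSeq,
    find_motif,
)

NO_FEATURE = "__no_feature__"
MIN_READ_LEN = 15

_DNA = "ACGT"


class ConfigError(ValueError):
    """Invalid generator configuration."""


class RuleCoverageError(LookupError):
    """No processing rule covers the given substrate."""


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    family: str
    chrom: str
    start: int  # 1-based closed
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Background gene panel: (gene_id, family, length, weight within family).
#: Lengths are typical for each class (mature miRNAs 22 nt, 5S rRNA 121 nt,
#: tRNAs ~72 nt, Y RNAs 84-112 nt).
BACKGROUND_GENES: list[tuple[str, str, int, float]] = [
    ("RNY1", "miscRNA", 112, 0.30),
    ("RNY3", "miscRNA", 101, 0.25),
    ("RNY4", "miscRNA", 95, 0.25),
    ("VTRNA1-1", "miscRNA", 98, 0.20),
    ("RNA5S1", "rRNA", 121, 0.60),
    ("RNA5-8S1", "rRNA", 156, 0.40),
    ("TRG-GCC1", "tRNA", 71, 0.34),
    ("TRE-CTC1", "tRNA", 72, 0.33),
    ("TRK-TTT1", "tRNA", 73, 0.33),
    ("MIR21", "miRNA", 22, 0.40),
    ("MIR16-1", "miRNA", 22, 0.30),
    ("MIRLET7A1", "miRNA", 22, 0.30),
    ("SNORD3A", "snoRNA", 104, 0.60),
    ("SNORA1", "snoRNA", 130, 0.40),
    ("RNU1-1", "snRNA", 164, 0.55),
    ("RNU2-1", "snRNA", 141, 0.45),
    ("LINC-TOY1", "lincRNA", 300, 1.00),
    ("GAPDH-3P", "protein_coding", 300, 0.55),
    ("ACTB-3P", "protein_coding", 300, 0.45),
    ("MT-TF", "Mt_tRNA", 71, 1.00),
]


@dataclass
class ReferenceConfig:
    """Layout of the toy reference.

    ``n_perfect_decoys`` loci share exactly the first 29 nt of RNY5 (the
    multimapping window for short 5' fragments); ``n_near_decoys`` differ
    from that 29-mer at ~3% of positions (one substitution)."""

    genes: Sequence[tuple[str, str, int, float]] = field(
        default_factory=lambda: list(BACKGROUND_GENES)
    )
    n_perfect_decoys: int = 2
    n_near_decoys: int = 3
    decoy_length: int = 29
    gap_range: tuple[int, int] = (80, 150)
    gene_prefix: str = ""
    include_rny5: bool = True


@dataclass
class ReferenceBundle:
    chromosomes: dict[str, str]
    annotations: list[GeneAnnotation]
    pseudogene_set: dict[str, list[str]]
    seed: int = 0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GeneAnnotation]] = {}
        for ann in self.annotations:
            if ann.chrom not in self.chromosomes:
                raise ConfigError(f"{ann.gene_id}: unknown chromosome {ann.chrom}")
            if not (1 <= ann.start <= ann.end <= len(self.chromosomes[ann.chrom])):
                raise ConfigError(f"{ann.gene_id}: interval outside chromosome")
            by_chrom.setdefault(ann.chrom, []).append(ann)
        for anns in by_chrom.values():
            anns = sorted(anns, key=lambda a: a.start)
            for prev, cur in zip(anns, anns[1:]):
                if cur.start <= prev.end:
                    raise ConfigError(
                        f"overlapping annotations: {prev.gene_id} / {cur.gene_id}"
                    )
        self._by_id = {a.gene_id: a for a in self.annotations}

    def gene(self, gene_id: str) -> GeneAnnotation:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def gene_sequence(self, gene_id: str) -> str:
        ann = self.gene(gene_id)
        return self.chromosomes[ann.chrom][ann.start - 1 : ann.end]

    def intergenic_intervals(self, chrom: str, margin: int = 2) -> list[tuple[int, int]]:
        """1-based closed intervals not touching any annotation (for
        sampling unannotated background reads)."""
        anns = sorted(
            (a for a in self.annotations if a.chrom == chrom), key=lambda a: a.start
        )
        length = len(self.chromosomes[chrom])
        out = []
        cursor = 1
        for a in anns:
            lo, hi = cursor + margin, a.start - 1 - margin
            if hi - lo + 1 >= 40:
                out.append((lo, hi))
            cursor = a.end + 1
        lo, hi = cursor + margin, length - margin
        if hi - lo + 1 >= 40:
            out.append((lo, hi))
        return out

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def to_bed(self, path: str | Path) -> None:
        """BED6+1 (family in column 7); 0-based half-open on disk."""
        with open(path, "w") as fh:
            for a in self.annotations:
                fh.write(
                    f"{a.chrom}\t{a.start - 1}\t{a.end}\t{a.gene_id}\t0\t"
                    f"{a.strand}\t{a.family}\n"
                )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_DNA[i] for i in rng.integers(0, 4, size=n))


RNY5_DNA = RNY5_83MER.residues.replace("U", "T")


def build_reference(config: ReferenceConfig | None = None, seed: int = 0) -> ReferenceBundle:
    """Assemble the toy genome; deterministic for a given seed."""
    cfg = config or ReferenceConfig()
    rng = np.random.default_rng(seed)
    p = cfg.gene_prefix

    # chr1: RNY5 plus background genes separated by random intergenic gaps
    parts: list[str] = [_random_dna(rng, 200)]
    annotations: list[GeneAnnotation] = []
    cursor = 201
    gene_entries: list[tuple[str, str, str]] = []
    if cfg.include_rny5:
        gene_entries.append(("RNY5", "miscRNA", RNY5_DNA))
    for gid, family, length, _w in cfg.genes:
        gene_entries.append((p + gid, family, _random_dna(rng, length)))
    for gid, family, seq in gene_entries:
        annotations.append(
            GeneAnnotation(gid, family, "chr1", cursor, cursor + len(seq) - 1)
        )
        parts.append(seq)
        cursor += len(seq)
        gap = int(rng.integers(*cfg.gap_range))
        parts.append(_random_dna(rng, gap))
        cursor += gap
    chr1 = "".join(parts)

    # chr2: pseudogene decoy loci
    decoy_ids: list[str] = []
    parts = [_random_dna(rng, 150)]
    cursor = 151
    core = RNY5_DNA[: cfg.decoy_length]
    n_total = cfg.n_perfect_decoys + cfg.n_near_decoys
    for i in range(n_total):
        gid = f"RNY5P{i + 1}"
        if i < cfg.n_perfect_decoys:
            seq = core
        else:
            # ~3% divergence: one substitution at a seeded position
            pos = int(rng.integers(0, cfg.decoy_length))
            base = _DNA[(_DNA.index(core[pos]) + 1 + int(rng.integers(0, 3))) % 4]
            seq = core[:pos] + base + core[pos + 1 :]
        annotations.append(
            GeneAnnotation(gid, "pseudogene", "chr2", cursor, cursor + len(seq) - 1)
        )
        decoy_ids.append(gid)
        parts.append(seq)
        cursor += len(seq)
        # the base following the decoy must differ from RNY5 position 30 so a
        # perfect 31-nt 5' read stays unique to the parent locus
        gap = _random_dna(rng, int(rng.integers(*cfg.gap_range)))
        if gap[0] == RNY5_DNA[cfg.decoy_length]:
            gap = ("A" if gap[0] != "A" else "C") + gap[1:]
        parts.append(gap)
        cursor += len(gap)
    chr2 = "".join(parts)

    chromosomes = {"chr1": chr1}
    if n_total:
        chromosomes["chr2"] = chr2
    pseudogenes = {"RNY5": decoy_ids} if (cfg.include_rny5 and decoy_ids) else {}
    return ReferenceBundle(chromosomes, annotations, pseudogenes, seed=seed)


def mixed_species_reference(seed: int = 0) -> ReferenceBundle:
    """Human RNY5 spiked into a mouse-like background: same gene panel with
    mouse-prefixed ids and no RNY5 pseudogenes (the mouse genome lacks the
    gene, so every RNY5-derived read maps uniquely)."""
    cfg = ReferenceConfig(n_perfect_decoys=0, n_near_decoys=0, gene_prefix="mm-")
    return build_reference(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Library profiles
# ---------------------------------------------------------------------------


#: EV fragment model for RNY5: mass concentrated on the processed 5' forms
#: (stops 23/29/31), the full-length transcript and the 3'-side fragment.
#: Stops 23 and 29 (multimapping forms) carry enough mass to clear the
#: 1000-rpm frequent-position cut while keeping the unique-mapper loss small.
EV_RNY5_FRAGMENTS: dict[tuple[int, int], float] = {
    (1, 23): 0.008,
    (1, 29): 0.012,
    (1, 31): 0.510,
    (1, 83): 0.260,
    (52, 83): 0.210,
}

#: Whole-cell fragment model: dominated by the full-length 83-nt form.
CELL_RNY5_FRAGMENTS: dict[tuple[int, int], float] = {
    (1, 23): 0.015,
    (1, 29): 0.025,
    (1, 31): 0.040,
    (1, 83): 0.920,
}

#: Printed measurement anchors per cell line: RNY5's share of gene-assigned
#: small-RNA reads in EV and whole-cell libraries, and the EV/cell rpm
#: fold-enrichment.
ABUNDANCE_ANCHORS: dict[str, dict[str, float]] = {
    "bj": {"ev_share": 0.35, "cell_share": 0.001, "enrichment": 196.0},
    "k562": {"ev_share": 0.48, "cell_share": 0.002, "enrichment": 68.0},
}

#: RNY5's target share of miscRNA-family reads (EV: >89% printed; whole
#: cell: 40% printed).
MISC_SHARE = {"ev": 0.945, "cell": 0.40}

#: Fraction of whole-cell library reads assigned to annotated genes; the
#: remainder is unannotated background.  The EV assigned fraction is solved
#: from the enrichment anchor.
CELL_ASSIGNED_FRACTION = 0.95

#: Family composition of the non-RNY5, non-miscRNA assigned mass.
EV_FAMILY_WEIGHTS = {
    "rRNA": 0.42,
    "tRNA": 0.32,
    "miRNA": 0.08,
    "snoRNA": 0.05,
    "snRNA": 0.04,
    "lincRNA": 0.02,
    "protein_coding": 0.04,
    "Mt_tRNA": 0.03,
}
CELL_FAMILY_WEIGHTS = {
    "rRNA": 0.44,
    "tRNA": 0.06,
    "miRNA": 0.21,
    "snoRNA": 0.21,
    "snRNA": 0.04,
    "lincRNA": 0.01,
    "protein_coding": 0.02,
    "Mt_tRNA": 0.01,
}


@dataclass
class LibraryProfile:
    """A simulated sequencing library: per-source abundance fractions and
    per-gene fragment models.

    ``source_fractions`` includes the pseudo-source ``__no_feature__`` for
    reads drawn from unannotated intergenic sequence; fractions sum to 1.
    """

    name: str
    source_fractions: dict[str, float]
    fragment_models: dict[str, dict[tuple[int, int], float]]
    read_count: int = 1_000_000
    error_rate: float = 0.001
    seed: int = 0

    def validate(self, ref: ReferenceBundle) -> None:
        total = sum(self.source_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"{self.name}: fractions sum to {total}, not 1")
        for gene, frac in self.source_fractions.items():
            if frac < 0:
                raise ConfigError(f"{self.name}: negative fraction for {gene}")
            if gene == NO_FEATURE:
                continue
            ann = ref.gene(gene)
            model = self.fragment_models.get(gene)
            if model is None:
                raise ConfigError(f"{self.name}: no fragment model for {gene}")
            if abs(sum(model.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{self.name}: fragment model for {gene} not normalized")
            for (s, t) in model:
                if not (1 <= s <= t <= ann.length):
                    raise ConfigError(
                        f"{self.name}: fragment {s}-{t} outside {gene} (len {ann.length})"
                    )
                if t - s + 1 < MIN_READ_LEN:
                    raise ConfigError(f"{self.name}: fragment {s}-{t} shorter than {MIN_READ_LEN}")


def default_fragment_model(length: int) -> dict[tuple[int, int], float]:
    """Fragmentation of a background gene: short genes are sequenced
    full-length; longer ones yield 5'-, middle- and 3'-anchored windows."""
    if length <= 32:
        return {(1, length): 1.0}
    mid = max(1, length // 2 - 13)
    model = {
        (1, 25): 0.20,
        (1, 31): 0.20,
        (mid, min(length, mid + 27)): 0.20,
        (max(1, length - 30), length): 0.20,
        (max(1, length - 24), length): 0.20,
    }
    # merge duplicate windows (possible for lengths just over 32)
    merged: dict[tuple[int, int], float] = {}
    for k, v in model.items():
        merged[k] = merged.get(k, 0.0) + v
    return merged


def _rny5_rpm(f: float, p_mm: float, s: float) -> float:
    """Expected RNY5 rpm given its generated fraction ``f`` of assigned
    mass, multimapper fraction ``p_mm`` of its reads, and assigned library
    fraction ``s``; the rpm denominator is all unique mappers."""
    return f * (1 - p_mm) * s * 1e6 / (1 - f * p_mm * s)


def _make_profile(
    cell_line: str,
    compartment: str,
    ref: ReferenceBundle,
    read_count: int,
    error_rate: float,
    seed: int,
) -> LibraryProfile:
    anchors = ABUNDANCE_ANCHORS[cell_line]
    is_ev = compartment == "ev"
    rny5_model = EV_RNY5_FRAGMENTS if is_ev else CELL_RNY5_FRAGMENTS
    p_mm = sum(v for (s, t), v in rny5_model.items() if s == 1 and t <= 29)
    m = anchors["ev_share"] if is_ev else anchors["cell_share"]
    # invert the multimapper loss so the unique-mapper measurement hits m
    f = m / (1 - (1 - m) * p_mm)

    if is_ev:
        # solve the assigned fraction s from the enrichment anchor
        cell_p_mm = sum(
            v for (cs, ct), v in CELL_RNY5_FRAGMENTS.items() if cs == 1 and ct <= 29
        )
        mc = anchors["cell_share"]
        fc = mc / (1 - (1 - mc) * cell_p_mm)
        rpm_cell = _rny5_rpm(fc, cell_p_mm, CELL_ASSIGNED_FRACTION)
        target_rpm = anchors["enrichment"] * rpm_cell
        a = f * (1 - p_mm) * 1e6
        b = f * p_mm
        s = target_rpm / (a + target_rpm * b)
    else:
        s = CELL_ASSIGNED_FRACTION

    # miscRNA companions sized so RNY5's counted share of the family hits
    # the printed target
    tau = MISC_SHARE["ev" if is_ev else "cell"]
    misc_other = f * (1 - p_mm) * (1 - tau) / tau
    rest = 1.0 - f - misc_other
    if rest <= 0:
        raise ConfigError("anchors leave no mass for background families")

    weights = EV_FAMILY_WEIGHTS if is_ev else CELL_FAMILY_WEIGHTS
    fractions: dict[str, float] = {NO_FEATURE: 1.0 - s, "RNY5": f * s}
    models: dict[str, dict[tuple[int, int], float]] = {"RNY5": dict(rny5_model)}
    genes = [g for g in BACKGROUND_GENES]
    misc_total_w = sum(w for _g, fam, _l, w in genes if fam == "miscRNA")
    for gid, family, length, w in genes:
        if family == "miscRNA":
            frac = misc_other * (w / misc_total_w)
        else:
            fam_w = weights.get(family, 0.0)
            fam_total = sum(ww for _g, fm, _l, ww in genes if fm == family)
            frac = rest * fam_w * (w / fam_total)
        if frac <= 0:
            continue
        fractions[gid] = frac * s
        models[gid] = default_fragment_model(length)
    return LibraryProfile(
        name=f"{cell_line}_{compartment}",
        source_fractions=fractions,
        fragment_models=models,
        read_count=read_count,
        error_rate=error_rate,
        seed=seed,
    )


def default_profile(
    name: str,
    ref: ReferenceBundle,
    read_count: int = 1_000_000,
    error_rate: float = 0.001,
    seed: int = 0,
) -> LibraryProfile:
    """Packaged profiles: ``bj_cell``, ``bj_ev``, ``k562_cell``, ``k562_ev``."""
    try:
        cell_line, compartment = name.split("_")
        if compartment not in ("cell", "ev"):
            raise ValueError
        profile = _make_profile(cell_line, compartment, ref, read_count, error_rate, seed)
    except (ValueError, KeyError):
        raise ConfigError(f"unknown profile {name!r}") from None
    profile.validate(ref)
    return profile


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Ground truth of one simulated library."""

    profile_name: str
    n_reads: int
    seed: int
    gene_counts: Counter
    fragment_counts: dict[str, Counter]
    fastq_path: str | None = None
    truth_sam_path: str | None = None

    @property
    def n_no_feature(self) -> int:
        return self.gene_counts.get(NO_FEATURE, 0)


def _truth_header(ref: ReferenceBundle) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.chromosomes.items()],
    }


def simulate_library(
    profile: LibraryProfile,
    ref: ReferenceBundle,
    fastq_path: str | Path,
    truth_sam_path: str | Path | None = None,
    seed: int | None = None,
) -> SimulationTruth:
    """Draw a library and write FASTQ (plus an optional truth SAM carrying
    the true origin of every read in ``XG``/``XF`` tags).

    Deterministic: the same profile, reference and seed produce
    byte-identical files.
    """
    profile.validate(ref)
    seed = profile.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    sources = sorted(profile.source_fractions)
    probs = np.array([profile.source_fractions[s] for s in sources])
    n_per_source = rng.multinomial(profile.read_count, probs / probs.sum())

    # expand to per-read records: (chrom, genomic start, gene, tstart, tstop)
    chroms: list[str] = []
    starts: list[int] = []
    genes: list[str] = []
    tstarts: list[int] = []
    tstops: list[int] = []
    rlens: list[int] = []
    intergenic = {
        c: ref.intergenic_intervals(c) for c in ref.chromosomes
    }
    chr1_gaps = intergenic.get("chr1", [])
    gap_lens = np.array([hi - lo + 1 for lo, hi in chr1_gaps], dtype=float)
    for src, n in zip(sources, n_per_source):
        if n == 0:
            continue
        if src == NO_FEATURE:
            if not chr1_gaps:
                raise ConfigError("no intergenic sequence available for background reads")
            gaps = rng.choice(len(chr1_gaps), size=n, p=gap_lens / gap_lens.sum())
            lens = rng.integers(20, 33, size=n)
            for gi, L in zip(gaps, lens):
                lo, hi = chr1_gaps[gi]
                L = int(min(L, hi - lo + 1))
                pos = int(rng.integers(lo, hi - L + 2))
                chroms.append("chr1")
                starts.append(pos)
                genes.append(NO_FEATURE)
                tstarts.append(0)
                tstops.append(0)
                rlens.append(L)
        else:
            ann = ref.gene(src)
            model = profile.fragment_models[src]
            frags = sorted(model)
            fp = np.array([model[k] for k in frags])
            counts = rng.multinomial(n, fp / fp.sum())
            for (s, t), c in zip(frags, counts):
                if c == 0:
                    continue
                if ann.strand == "+":
                    gpos = ann.start + s - 1
                else:
                    gpos = ann.end - t + 1
                chroms.extend([ann.chrom] * c)
                starts.extend([gpos] * c)
                genes.extend([src] * c)
                tstarts.extend([s] * c)
                tstops.extend([t] * c)
                rlens.extend([t - s + 1] * c)

    n_reads = len(chroms)
    order = rng.permutation(n_reads)

    gene_counts: Counter = Counter()
    fragment_counts: dict[str, Counter] = {}
    truth = SimulationTruth(
        profile.name, n_reads, seed, gene_counts, fragment_counts,
        str(fastq_path), str(truth_sam_path) if truth_sam_path else None,
    )

    sam = None
    if truth_sam_path is not None:
        sam = pysam.AlignmentFile(
            str(truth_sam_path), "w", header=pysam.AlignmentHeader.from_dict(_truth_header(ref))
        )
    tid_of = {c: i for i, c in enumerate(ref.chromosomes)}

    with open(fastq_path, "w") as fq:
        for out_i, i in enumerate(order):
            chrom, pos, gene = chroms[i], starts[i], genes[i]
            s, t = tstarts[i], tstops[i]
            L = rlens[i]
            seq = ref.chromosomes[chrom][pos - 1 : pos - 1 + L]
            n_err = rng.binomial(L, profile.error_rate)
            if n_err:
                positions = rng.choice(L, size=n_err, replace=False)
                sl = list(seq)
                for p in positions:
                    sl[p] = _DNA[(_DNA.index(sl[p]) + 1 + int(rng.integers(0, 3))) % 4]
                seq = "".join(sl)
            rid = f"r{out_i:07d}"
            fq.write(f"@{rid}\n{seq}\n+\n{'I' * L}\n")
            gene_counts[gene] += 1
            if gene != NO_FEATURE:
                fragment_counts.setdefault(gene, Counter())[(s, t)] += 1
            if sam is not None:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = rid
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = tid_of[chrom]
                a.reference_start = pos - 1
                a.mapping_quality = 255
                a.cigarstring = f"{L}M"
                a.set_tags(
                    [
                        ("NH", 1),
                        ("NM", int(n_err)),
                        ("XG", gene),
                        ("XF", f"{s}-{t}"),
                    ]
                )
                sam.write(a)
    if sam is not None:
        sam.close()
    return truth


# ---------------------------------------------------------------------------
# In-vitro processing rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProcessingRule:
    """One row of the rule table mapping a substrate class to its product
    spectrum.  ``products`` maps product length -> qualitative abundance
    ("full" or "residual"); ``substrate_remains`` records whether unreacted
    substrate is still detectable."""

    name: str
    extract: str  # "whole_cell" | "ev"
    predicate: "object"  # Callable[[RnaSeq, bool], bool]
    products: dict[int, str]
    substrate_remains: bool = True


_FLANK5 = RNY5_31MER.residues[: PROCESSING_MOTIF.start_1based - 1]  # 1-13
_FLANK3 = RNY5_31MER.residues[PROCESSING_MOTIF.end_1based :]  # 22-31


def _has_motif(seq: RnaSeq, ds: bool) -> bool:
    return bool(find_motif(seq, PROCESSING_MOTIF.sequence))


def _motif_scar(seq: RnaSeq, ds: bool) -> bool:
    """5' and 3' flanks of the motif are intact but the motif itself was
    replaced by something else (not merely deleted)."""
    r = seq.residues
    if _has_motif(seq, ds):
        return False
    if not (r.startswith(_FLANK5) and r.endswith(_FLANK3)):
        return False
    return len(r) > len(_FLANK5) + len(_FLANK3)


DEFAULT_PROCESSING_RULES: list[ProcessingRule] = [
    # whole-cell extract shows no detectable processing of any substrate
    ProcessingRule("cell_inert", "whole_cell", lambda s, ds: True, {}, True),
    # a duplex sequesters the motif: no processing
    ProcessingRule("ev_duplex_protected", "ev", lambda s, ds: ds, {}, True),
    # motif-bearing substrate long enough to carry the 3' arm: all
    # processed forms appear, full-length substrate remains detectable
    ProcessingRule(
        "ev_full_length",
        "ev",
        lambda s, ds: _has_motif(s, ds) and len(s) > 52,
        {23: "full", 29: "full", 31: "full"},
        True,
    ),
    # shorter motif-bearing 5' fragments are trimmed to the 23-nt product
    ProcessingRule(
        "ev_5p_fragment",
        "ev",
        lambda s, ds: _has_motif(s, ds) and len(s) > 23,
        {23: "full"},
        True,
    ),
    ProcessingRule(
        "ev_terminal_product",
        "ev",
        lambda s, ds: _has_motif(s, ds),
        {},
        True,
    ),
    # motif replaced in place: only residual 23-nt product
    ProcessingRule("ev_motif_scar", "ev", _motif_scar, {23: "residual"}, True),
    # anything without the motif (scrambled, motif-deleted, 3'-side) is inert
    ProcessingRule("ev_inert", "ev", lambda s, ds: not _has_motif(s, ds), {}, True),
]


@dataclass(frozen=True)
class ProcessingResult:
    substrate_id: str
    extract: str
    rule: str
    products: dict[int, str]
    substrate_remains: bool


def simulate_processing(
    substrate: RnaSeq,
    extract: str,
    rules: Sequence[ProcessingRule] | None = None,
    double_stranded: bool = False,
) -> ProcessingResult:
    """Deterministic product spectrum for a substrate in the given extract.

    The first matching rule (in table order) applies; a substrate matched
    by no rule raises :class:`RuleCoverageError`.
    """
    if extract not in ("whole_cell", "ev"):
        raise ConfigError(f"unknown extract {extract!r}")
    table = DEFAULT_PROCESSING_RULES if rules is None else list(rules)
    for rule in table:
        if rule.extract == extract and rule.predicate(substrate, double_stranded):
            return ProcessingResult(
                substrate.id, extract, rule.name, dict(rule.products), rule.substrate_remains
            )
    raise RuleCoverageError(
        f"no {extract} rule covers substrate {substrate.id}"
    )


# ---------------------------------------------------------------------------
# Cytometry event simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity model for one population/channel."""

    meanlog: float
    sdlog: float


@dataclass
class CytoCondition:
    """A flow-cytometry condition with known truth.

    Events are a mixture of Hoechst-negative debris and Hoechst-positive
    cells; among cells, a ``dead_fraction`` takes up YO-PRO-1 (membrane-
    permeable only in apoptotic/dead cells) and shows brighter, condensed
    chromatin in the Hoechst channel.
    """

    name: str
    dead_fraction: float
    event_count: int = 10_000
    debris_fraction: float = 0.05
    seed: int = 0
    hoechst_debris: ChannelModel = ChannelModel(5.0, 0.5)
    hoechst_live: ChannelModel = ChannelModel(8.5, 0.4)
    hoechst_dead: ChannelModel = ChannelModel(8.7, 0.4)
    yopro_debris: ChannelModel = ChannelModel(4.6, 0.5)
    yopro_live: ChannelModel = ChannelModel(4.6, 0.5)
    yopro_dead: ChannelModel = ChannelModel(8.0, 0.5)

    def validate(self) -> None:
        if not (0.0 <= self.dead_fraction <= 1.0):
            raise ConfigError(f"{self.name}: dead fraction outside [0, 1]")
        if not (0.0 <= self.debris_fraction < 1.0):
            raise ConfigError(f"{self.name}: debris fraction outside [0, 1)")
        if self.yopro_dead.meanlog <= self.yopro_live.meanlog:
            raise ConfigError(f"{self.name}: dead population not shifted up in YO-PRO-1")


def _preset(name: str, dead: float) -> CytoCondition:
    return CytoCondition(name=name, dead_fraction=dead)


#: Packaged conditions.  Only the BJ-EV-RNA (10.6%) versus K562-EV-RNA
#: (20.5%) pair and the ~2x / ~4x ratios are anchored at printed values;
#: untreated/mock baselines use a typical primary-culture background.
CYTO_PRESETS: dict[str, CytoCondition] = {
    "bj_untreated": _preset("bj_untreated", 0.05),
    "bj_mock": _preset("bj_mock", 0.06),
    "bj_plus_bj_ev_rna": _preset("bj_plus_bj_ev_rna", 0.106),
    "bj_plus_k562_ev_rna": _preset("bj_plus_k562_ev_rna", 0.205),
    "bj_plus_bj_ev": _preset("bj_plus_bj_ev", 0.055),
    "bj_plus_k562_ev": _preset("bj_plus_k562_ev", 0.21),
    "bj_coculture_k562": _preset("bj_coculture_k562", 0.20),
    "k562_untreated": _preset("k562_untreated", 0.05),
    "k562_plus_k562_ev_rna": _preset("k562_plus_k562_ev_rna", 0.055),
}

#: Dose-response truth for the 5' 31-mer in BJ cells: (dose pmol, dead
#: fraction), monotone over the printed dose ladder.
DOSE_RESPONSE_PRESET: list[tuple[float, float]] = [
    (10.0, 0.06),
    (50.0, 0.09),
    (100.0, 0.12),
    (200.0, 0.16),
    (300.0, 0.19),
    (400.0, 0.21),
]


def simulate_cytometry(
    condition: CytoCondition,
    seed: int | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Event table (event_id, hoechst, yopro); optionally written as TSV.

    The realized dead fraction is Binomial(n_cells, dead_fraction), i.e.
    within ordinary sampling error of the configured truth.
    """
    condition.validate()
    rng = np.random.default_rng(condition.seed if seed is None else seed)
    n = condition.event_count
    is_debris = rng.random(n) < condition.debris_fraction
    is_dead = (~is_debris) & (rng.random(n) < condition.dead_fraction)

    hoechst = np.empty(n)
    yopro = np.empty(n)
    for mask, hmod, ymod in (
        (is_debris, condition.hoechst_debris, condition.yopro_debris),
        (~is_debris & ~is_dead, condition.hoechst_live, condition.yopro_live),
        (is_dead, condition.hoechst_dead, condition.yopro_dead),
    ):
        k = int(mask.sum())
        hoechst[mask] = rng.lognormal(hmod.meanlog, hmod.sdlog, size=k)
        yopro[mask] = rng.lognormal(ymod.meanlog, ymod.sdlog, size=k)

    df = pd.DataFrame(
        {
            "event_id": [f"e{i:06d}" for i in range(n)],
            "hoechst": np.round(hoechst, 3),
            "yopro": np.round(yopro, 3),
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
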