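"""Brute-force ungapped short-read alignment to the toy reference.

The mapping contract mirrors the one the sequencing study states: end-to-end
alignment with at most five mismatches, reporting only reads that map to ten
or fewer loci.  Two refinements make the behaviour well-defined:

- only the minimal-mismatch stratum is reported (a placement with more
  mismatches than the read's best placement is never emitted);
- reads whose minimal stratum exceeds ``max_loci`` are suppressed entirely.

Alignment is exhaustive over every offset of every chromosome on both
strands, vectorised with numpy sliding windows; identical read sequences are
aligned once and the placements reused.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic_data import MIN_READ_LEN, ReferenceBundle

_DNA = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")
_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_DNA):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("N")] = 255  # never matches


class FastqFormatError(ValueError):
    """Malformed FASTQ input."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One reported placement of a read."""

    read_id: str
    chrom: str
    start: int  # 1-based
    strand: str
    mismatch_count: int
    hit_count: int

    @property
    def is_unique(self) -> bool:
        return self.hit_count == 1


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ReferenceIndex:
    """Encoded chromosomes with cached sliding-window views per read length."""

    def __init__(self, ref: ReferenceBundle):
        self.ref = ref
        self.chrom_names = list(ref.chromosomes)
        self._enc = {c: _encode(s) for c, s in ref.chromosomes.items()}
        self._windows: dict[tuple[str, int], np.ndarray] = {}

    def windows(self, chrom: str, length: int) -> np.ndarray | None:
        arr = self._enc[chrom]
        if length > arr.size:
            return None
        key = (chrom, length)
        if key not in self._windows:
            self._windows[key] = sliding_window_view(arr, length)
        return self._windows[key]


def _exact_placements(
    index: ReferenceIndex, seq: str
) -> list[tuple[str, int, str, int]]:
    """All zero-mismatch placements, via plain substring search.

    When any exact placement exists it *is* the minimal stratum, so the
    exhaustive mismatch scan can be skipped (the common case for
    error-free reads)."""
    out: list[tuple[str, int, str, int]] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for chrom in index.chrom_names:
            ref_seq = index.ref.chromosomes[chrom]
            pos = ref_seq.find(s)
            while pos != -1:
                out.append((chrom, pos + 1, strand, 0))
                pos = ref_seq.find(s, pos + 1)
    return out


def _placements(
    index: ReferenceIndex, seq: str, max_mismatches: int
) -> list[tuple[str, int, str, int]]:
    """All placements (chrom, 1-based start, strand, mismatches) with at
    most ``max_mismatches``, before stratum filtering."""
    out: list[tuple[str, int, str, int]] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        enc = _encode(s)
        for chrom in index.chrom_names:
            win = index.windows(chrom, enc.size)
            if win is None:
                continue
            mm = (win != enc).sum(axis=1)
            hits = np.nonzero(mm <= max_mismatches)[0]
            for pos in hits:
                out.append((chrom, int(pos) + 1, strand, int(mm[pos])))
    return out


def align_read(
    seq: str,
    index: ReferenceIndex | ReferenceBundle,
    read_id: str = "read",
    max_mismatches: int = 5,
    max_loci: int = 10,
) -> list[AlignmentRecord]:
    """Align one read; returns the minimal-mismatch stratum sorted by
    (chrom, start, strand), or an empty list when the read is unmappable
    or maps to more than ``max_loci`` loci."""
    if not seq:
        raise ValueError("empty read")
    if len(seq) < MIN_READ_LEN:
        return []
    if isinstance(index, ReferenceBundle):
        index = ReferenceIndex(index)
    cands = _exact_placements(index, seq)
    if not cands:
        cands = _placements(index, seq, max_mismatches)
    if not cands:
        return []
    best = min(c[3] for c in cands)
    stratum = sorted(
        (c for c in cands if c[3] == best), key=lambda c: (c[0], c[1], c[2])
    )
    if len(stratum) > max_loci:
        return []
    nh = len(stratum)
    return [
        AlignmentRecord(read_id, chrom, start, strand, mm, nh)
        for chrom, start, strand, mm in stratum
    ]


def _read_fastq(path: str | Path):
    """Minimal strict FASTQ reader yielding (id, seq); errors carry the
    offending line number."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: line {lineno}: expected '@', got {header.strip()!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(
                    f"{path}: line {lineno}: truncated record {header.strip()!r}"
                )
            lineno += 3
            if not plus.startswith("+"):
                raise FastqFormatError(f"{path}: line {lineno - 1}: missing '+' separator")
            seq = seq.strip()
            if len(seq) != len(qual.strip()):
                raise FastqFormatError(
                    f"{path}: line {lineno}: sequence/quality length mismatch"
                )
            yield header[1:].split()[0], seq


def _sam_header(ref: ReferenceBundle) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.chromosomes.items()],
            "PG": [{"ID": "evcargo", "PN": "evcargo-toy-aligner"}],
        }
    )


def align_library(
    fastq_path: str | Path,
    ref: ReferenceBundle,
    out_sam: str | Path,
    max_mismatches: int = 5,
    max_loci: int = 10,
) -> dict[str, int]:
    """Align a FASTQ file and write SAM (NH tag = number of reported loci).

    Returns summary counters: reads seen / aligned / suppressed (over
    ``max_loci``) / unmapped / too short.  Output order follows input order;
    placements of a read are sorted, so output is deterministic.
    """
    index = ReferenceIndex(ref)
    tid_of = {c: i for i, c in enumerate(index.chrom_names)}
    cache: dict[str, tuple[list[AlignmentRecord], str]] = {}
    stats = {"reads": 0, "aligned": 0, "suppressed": 0, "unmapped": 0, "too_short": 0}

    with pysam.AlignmentFile(str(out_sam), "w", header=_sam_header(ref)) as sam:
        for rid, seq in _read_fastq(fastq_path):
            stats["reads"] += 1
            if len(seq) < MIN_READ_LEN:
                stats["too_short"] += 1
                continue
            cached = cache.get(seq)
            if cached is None:
                placements = align_read(
                    seq, index, read_id="", max_mismatches=max_mismatches, max_loci=max_loci
                )
                if placements:
                    status = "aligned"
                elif _placements(index, seq, max_mismatches):
                    status = "suppressed"
                else:
                    status = "unmapped"
                cached = (placements, status)
                cache[seq] = cached
            placements, status = cached
            if not placements:
                stats[status] += 1
                continue
            stats["aligned"] += 1
            nh = placements[0].hit_count
            for k, rec in enumerate(placements):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = rid
                a.flag = (16 if rec.strand == "-" else 0) | (256 if k > 0 else 0)
                a.reference_id = tid_of[rec.chrom]
                a.reference_start = rec.start - 1
                a.mapping_quality = 255 if nh == 1 else 1
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = seq if rec.strand == "+" else reverse_complement(seq)
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                a.set_tags([("NH", nh), ("NM", rec.mismatch_count)])
                sam.write(a)
    return stats
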