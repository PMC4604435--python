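"""Read start/stop profiling of a gene in transcript coordinates.

For every read attributed to the gene, the transcript-relative 1-based
coordinates of its 5' end (start) and 3' end (stop) are accumulated into
rpm-weighted histograms; positions whose marginal rpm strictly exceeds a
threshold (default 1000 rpm) are called "frequent".  This reproduces the
analysis that reveals processing sites: a transcript processed at stops
23/29/31 shows those stops above threshold while untouched positions stay
near zero.

Multimapper policy: short 5' fragments of a gene with pseudogene decoys
multimap and would otherwise vanish from the profile.  Under
``include_pseudogene_set`` (default), a multimapping read is attributed to
the gene when *every* reported locus lies within the gene or its annotated
pseudogene set; ``exclude_multimappers`` keeps unique mappers only and is
retained for sensitivity analysis.

rpm here is normalised by the library's total unique mappers — the same
denominator used for gene counting — so included multimappers add mass on
top of a fixed scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .counting import GeneInterval, SamFormatError
from .synthetic_data import GeneAnnotation

POLICIES = ("include_pseudogene_set", "exclude_multimappers")


@dataclass
class FragmentProfile:
    """Start/stop rpm histograms of one gene."""

    gene_id: str
    gene_length: int
    start_rpm: dict[int, float]
    stop_rpm: dict[int, float]
    fragments: dict[tuple[int, int], float]  # joint (start, stop) -> rpm
    threshold: float
    n_reads: int
    n_multimappers_included: int
    n_clipped: int
    total_unique: int

    @property
    def frequent_starts(self) -> set[int]:
        return {p for p, v in self.start_rpm.items() if v > self.threshold}

    @property
    def frequent_stops(self) -> set[int]:
        return {p for p, v in self.stop_rpm.items() if v > self.threshold}

    def stops_for_start(self, start: int) -> dict[int, float]:
        """Stop-position rpm among reads starting at ``start``."""
        out: dict[int, float] = {}
        for (s, t), v in self.fragments.items():
            if s == start:
                out[t] = out.get(t, 0.0) + v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(1, self.gene_length + 1):
            s = self.start_rpm.get(pos, 0.0)
            t = self.stop_rpm.get(pos, 0.0)
            rows.append(
                {
                    "position": pos,
                    "start_rpm": s,
                    "stop_rpm": t,
                    "start_is_frequent": s > self.threshold,
                    "stop_is_frequent": t > self.threshold,
                }
            )
        return pd.DataFrame(rows)


def _transcript_coords(
    ann: GeneAnnotation, g_start: int, g_end: int
) -> tuple[int, int]:
    """Genomic closed interval -> transcript 5'->3' (start, stop)."""
    if ann.strand == "+":
        return g_start - ann.start + 1, g_end - ann.start + 1
    return ann.end - g_end + 1, ann.end - g_start + 1


def profile_gene(
    sam_path: str | Path,
    annotations: list[GeneAnnotation],
    gene_id: str,
    pseudogene_set: dict[str, list[str]] | None = None,
    policy: str = "include_pseudogene_set",
    threshold: float = 1000.0,
    total_unique: int | None = None,
) -> FragmentProfile:
    """Profile one gene from a SAM file with NH tags.

    ``total_unique`` overrides the rpm denominator (otherwise counted from
    the same file).  Reads extending past the gene span are clipped to it
    and counted in ``n_clipped``.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    by_id = {a.gene_id: a for a in annotations}
    if gene_id not in by_id:
        raise KeyError(f"unknown gene {gene_id!r}")
    gene = by_id[gene_id]
    decoy_ids = set((pseudogene_set or {}).get(gene_id, ()))
    allowed = [gene] + [by_id[d] for d in decoy_ids if d in by_id]
    allowed_lookup = GeneInterval(allowed)
    gene_lookup = GeneInterval([gene])

    joint: Counter = Counter()
    n_unique_total = 0
    n_gene_reads = 0
    n_multi_included = 0
    n_clipped = 0
    # pending multimappers: read_id -> [records_seen, nh, in_gene_interval,
    # all_loci_allowed]
    pending: dict[str, list] = {}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            try:
                nh = rec.get_tag("NH")
            except KeyError:
                raise SamFormatError(
                    f"{sam_path}: record {rec.query_name} lacks NH tag"
                ) from None
            start, end = rec.reference_start + 1, rec.reference_end
            if nh == 1:
                n_unique_total += 1
                if gene_lookup.overlapping(rec.reference_name, start, end):
                    joint[(start, end)] += 1
                    n_gene_reads += 1
                continue
            if policy == "exclude_multimappers":
                continue
            state = pending.setdefault(rec.query_name, [0, nh, None, True])
            state[0] += 1
            hit_allowed = allowed_lookup.overlapping(rec.reference_name, start, end)
            if not hit_allowed:
                state[3] = False
            elif gene_lookup.overlapping(rec.reference_name, start, end):
                state[2] = (start, end)
            if state[0] == nh:
                del pending[rec.query_name]
                if state[3] and state[2] is not None:
                    joint[state[2]] += 1
                    n_gene_reads += 1
                    n_multi_included += 1

    denom = total_unique if total_unique is not None else n_unique_total
    glen = gene.length
    fragments: dict[tuple[int, int], float] = {}
    start_rpm: dict[int, float] = {}
    stop_rpm: dict[int, float] = {}
    for (g_start, g_end), n in sorted(joint.items()):
        ts, tt = _transcript_coords(gene, g_start, g_end)
        clipped = ts < 1 or tt > glen
        if clipped:
            n_clipped += n
            ts, tt = max(ts, 1), min(tt, glen)
        rpm = n / denom * 1e6 if denom else 0.0
        fragments[(ts, tt)] = fragments.get((ts, tt), 0.0) + rpm
        start_rpm[ts] = start_rpm.get(ts, 0.0) + rpm
        stop_rpm[tt] = stop_rpm.get(tt, 0.0) + rpm

    return FragmentProfile(
        gene_id=gene_id,
        gene_length=glen,
        start_rpm=start_rpm,
        stop_rpm=stop_rpm,
        fragments=fragments,
        threshold=threshold,
        n_reads=n_gene_reads,
        n_multimappers_included=n_multi_included,
        n_clipped=n_clipped,
        total_unique=denom,
    )


def fragment_length_spectrum(profile: FragmentProfile) -> dict[int, float]:
    """Length -> rpm from the joint (start, stop) fragments; length is
    stop - start + 1."""
    out: dict[int, float] = {}
    for (s, t), rpm in profile.fragments.items():
        L = t - s + 1
        out[L] = out.get(L, 0.0) + rpm
    return dict(sorted(out.items()))
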