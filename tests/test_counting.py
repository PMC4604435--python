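"""Union-mode counting, rpm normalisation, family aggregation, enrichment."""

import math

import pysam
import pytest

from evcargo.counting import (
    GeneCounts,
    SamFormatError,
    count_genes,
    enrichment,
    ev_cell_ratio,
    family_table,
    replicate_correlation,
)
from evcargo.synthetic_data import GeneAnnotation

ANNS = [
    GeneAnnotation("geneA", "miscRNA", "c1", 101, 200),
    GeneAnnotation("geneB", "rRNA", "c1", 301, 400),
]


def write_sam(path, records, chrom_len=1000):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": chrom_len}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rid, start1, length, nh in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rid
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start1 - 1
            a.mapping_quality = 255
            a.cigarstring = f"{length}M"
            a.query_sequence = "A" * length
            a.set_tags([("NH", nh)])
            sam.write(a)


@pytest.fixture()
def hand_sam(tmp_path):
    """Ten records with a known union-mode tally:

    geneA: 3 unique; geneB: 3 unique; 1 unique in no gene (no_feature);
    1 unique spanning both genes (ambiguous); 2 multimapper records.
    """
    path = tmp_path / "hand.sam"
    write_sam(
        path,
        [
            ("r1", 110, 20, 1),   # A
            ("r2", 150, 20, 1),   # A
            ("r3", 190, 20, 1),   # A (overlaps A only: 190-209)
            ("r4", 310, 20, 1),   # B
            ("r5", 350, 20, 1),   # B
            ("r6", 390, 11, 1),   # B (390-400)
            ("r7", 500, 20, 1),   # no_feature
            ("r8", 195, 111, 1),  # spans A (to 200) and B (301..) -> ambiguous
            ("r9", 110, 20, 2),   # multimapper
            ("r9", 320, 20, 2),   # multimapper (second locus)
        ],
    )
    return path


def test_hand_tally(hand_sam):
    counts = count_genes(hand_sam, ANNS, "hand")
    assert counts.counts == {"geneA": 3, "geneB": 3}
    assert counts.stats == {
        "total_records": 10,
        "counted": 6,
        "no_feature": 1,
        "ambiguous": 1,
        "multimapper": 2,
    }
    assert counts.total_unique == 8
    assert counts.rpm("geneA") == pytest.approx(3 / 8 * 1e6)


def test_conservation_invariant(hand_sam, bj_ev_small):
    for counts in (count_genes(hand_sam, ANNS), bj_ev_small["counts"]):
        s = counts.stats
        assert (
            s["counted"] + s["no_feature"] + s["ambiguous"] + s["multimapper"]
            == s["total_records"]
        )


def test_rpm_sums_to_at_most_a_million(hand_sam, bj_ev_small):
    for counts in (count_genes(hand_sam, ANNS), bj_ev_small["counts"]):
        total_rpm = sum(counts.rpm_table().values())
        assert total_rpm <= 1e6 + 1e-6
    # equality holds iff every unique mapper was counted
    only_counted = count_genes(hand_sam, ANNS)
    frac = only_counted.stats["counted"] / only_counted.total_unique
    assert sum(only_counted.rpm_table().values()) == pytest.approx(frac * 1e6)


def test_multimappers_only_gives_zero_counts(tmp_path):
    path = tmp_path / "mm.sam"
    write_sam(path, [("r1", 110, 20, 2), ("r1", 310, 20, 2)])
    counts = count_genes(path, ANNS)
    assert all(v == 0 for v in counts.counts.values())
    assert counts.total_unique == 0


def test_missing_nh_tag_is_an_error(tmp_path):
    path = tmp_path / "nonh.sam"
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 1000}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        a = pysam.AlignedSegment(sam.header)
        a.query_name = "r1"
        a.reference_id = 0
        a.reference_start = 110
        a.cigarstring = "20M"
        a.query_sequence = "A" * 20
        sam.write(a)
    with pytest.raises(SamFormatError, match="NH"):
        count_genes(path, ANNS)


def test_error_free_decoyfree_counts_equal_truth(ref_nodecoy, tmp_path):
    from conftest import run_library

    bag = run_library(ref_nodecoy, "bj_ev", 10_000, seed=31, workdir=tmp_path,
                      error_rate=0.0)
    truth, counts = bag["truth"], bag["counts"]
    for gene, n in truth.gene_counts.items():
        if gene == "__no_feature__":
            assert counts.stats["no_feature"] == n
        else:
            assert counts.counts[gene] == n


def test_family_table_folds_unnamed_into_others(bj_ev_small, ref):
    fam = family_table(bj_ev_small["counts"], ref.annotations)
    assert fam.fraction("miscRNA") > 0.3
    assert "Mt_tRNA" in fam.others_members
    assert fam.table["fraction"].sum() == pytest.approx(1.0)


def test_single_gene_library_family_fraction_is_one():
    counts = GeneCounts("solo", {"geneA": 10}, 10)
    fam = family_table(counts, ANNS)
    assert fam.fraction("miscRNA") == pytest.approx(1.0)


def test_unlabeled_gene_is_an_error():
    counts = GeneCounts("x", {"mystery": 1}, 1)
    with pytest.raises(ValueError, match="family"):
        family_table(counts, ANNS)


def test_enrichment_identities(bj_ev_small, bj_cell_small):
    ev, cell = bj_ev_small["counts"], bj_cell_small["counts"]
    assert enrichment(ev, ev, "RNY5") == pytest.approx(1.0)
    fold = enrichment(ev, cell, "RNY5")
    assert fold > 1
    assert fold * enrichment(cell, ev, "RNY5") == pytest.approx(1.0)


def test_enrichment_zero_cell_rpm_warns_infinite():
    ev = GeneCounts("ev", {"g": 5}, 10)
    cell = GeneCounts("cell", {"g": 0}, 10)
    with pytest.warns(UserWarning, match="inf"):
        assert enrichment(ev, cell, "g") == math.inf


def test_ev_cell_ratio_identities(bj_ev_small, bj_cell_small):
    ev_only = GeneCounts("ev", {"g": 5}, 10)
    empty = GeneCounts("cell", {"g": 0}, 10)
    assert ev_cell_ratio(ev_only, empty)["g"] == pytest.approx(1.0)
    assert ev_cell_ratio(ev_only, ev_only)["g"] == pytest.approx(0.5)
    ratios = ev_cell_ratio(bj_ev_small["counts"], bj_cell_small["counts"])
    assert ratios["RNY5"] > 0.99  # the 196-fold anchor implies 196/197


def test_replicate_correlation(ref, tmp_path):
    from conftest import run_library

    a = run_library(ref, "bj_ev", 50_000, seed=41, workdir=tmp_path / "a")
    b = run_library(ref, "bj_ev", 50_000, seed=42, workdir=tmp_path / "b")
    same = replicate_correlation(a["counts"], b["counts"])
    assert replicate_correlation(a["counts"], a["counts"]) == pytest.approx(1.0)
    assert same > 0.95


def test_cross_profile_correlation_is_lower(bj_ev_small, bj_cell_small):
    cross = replicate_correlation(bj_ev_small["counts"], bj_cell_small["counts"])
    assert cross < 0.95
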