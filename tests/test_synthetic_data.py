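"""Generator contracts: reference layout, library truth, processing rules,
cytometry events."""

import numpy as np
import pytest
from scipy import stats as sps

from evcargo.sequences import (
    RNY5_23MER,
    RNY5_31MER,
    RNY5_31MER_SCRAMBLED,
    RNY5_83MER,
    RNY5_3P_32MER,
    RNY5_MOTIF_DELETED,
    RNY5_MOTIF_SCRAMBLED,
)
from evcargo.synthetic_data import (
    CYTO_PRESETS,
    ConfigError,
    CytoCondition,
    GeneAnnotation,
    ReferenceBundle,
    ReferenceConfig,
    RuleCoverageError,
    build_reference,
    default_profile,
    simulate_cytometry,
    simulate_library,
    simulate_processing,
)


def _count_occurrences(ref, s):
    return sum(chrom.count(s) for chrom in ref.chromosomes.values())


class TestReference:
    def test_rny5_locus_is_the_printed_transcript(self, ref):
        ann = ref.gene("RNY5")
        assert ann.length == 83
        assert ref.gene_sequence("RNY5") == RNY5_83MER.residues.replace("U", "T")

    def test_decoy_panel(self, ref):
        decoys = ref.pseudogene_set["RNY5"]
        assert len(decoys) == 5
        core = ref.gene_sequence("RNY5")[:29]
        perfect = [d for d in decoys if ref.gene_sequence(d) == core]
        near = [d for d in decoys if ref.gene_sequence(d) != core]
        assert len(perfect) == 2
        assert len(near) == 3
        for d in near:
            seq = ref.gene_sequence(d)
            assert sum(a != b for a, b in zip(seq, core)) == 1

    def test_short_5p_read_matches_at_least_three_loci(self, ref):
        """A 23-nt 5' fragment hits the parent locus plus both perfect
        decoys exactly."""
        read = ref.gene_sequence("RNY5")[:23]
        assert _count_occurrences(ref, read) >= 3

    def test_31nt_5p_read_is_unique(self, ref):
        read = ref.gene_sequence("RNY5")[:31]
        assert _count_occurrences(ref, read) == 1

    def test_decoy_free_reference_makes_rny5_unique(self, ref_nodecoy):
        read = ref_nodecoy.gene_sequence("RNY5")[:23]
        assert _count_occurrences(ref_nodecoy, read) == 1
        assert ref_nodecoy.pseudogene_set == {}

    def test_mixed_species_preset_has_no_decoys(self):
        from evcargo.synthetic_data import mixed_species_reference

        mm = mixed_species_reference(seed=5)
        assert mm.pseudogene_set == {}
        assert _count_occurrences(mm, mm.gene_sequence("RNY5")[:23]) == 1
        assert all(
            a.gene_id.startswith("mm-") or a.gene_id == "RNY5"
            for a in mm.annotations
        )

    def test_deterministic_for_seed(self):
        a = build_reference(seed=7)
        b = build_reference(seed=7)
        assert a.chromosomes == b.chromosomes
        assert a.annotations == b.annotations

    def test_overlapping_annotations_rejected(self):
        chroms = {"c": "ACGT" * 50}
        anns = [
            GeneAnnotation("g1", "miscRNA", "c", 10, 50),
            GeneAnnotation("g2", "miscRNA", "c", 40, 90),
        ]
        with pytest.raises(ConfigError, match="overlapping"):
            ReferenceBundle(chroms, anns, {})

    def test_annotation_outside_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            ReferenceBundle(
                {"c": "ACGT"}, [GeneAnnotation("g", "miscRNA", "c", 1, 10)], {}
            )


class TestLibrarySimulation:
    def test_same_seed_is_byte_identical(self, ref, tmp_path):
        profile = default_profile("bj_ev", ref, read_count=5_000)
        paths = []
        for tag in ("a", "b"):
            fq = tmp_path / f"{tag}.fq"
            sam = tmp_path / f"{tag}.sam"
            simulate_library(profile, ref, fq, sam, seed=9)
            paths.append((fq.read_bytes(), sam.read_bytes()))
        assert paths[0] == paths[1]

    def test_error_free_reads_are_exact_substrings(self, ref, tmp_path):
        profile = default_profile("bj_ev", ref, read_count=3_000, error_rate=0.0)
        fq = tmp_path / "e0.fq"
        simulate_library(profile, ref, fq, None, seed=4)
        genome = "".join(ref.chromosomes.values())
        with open(fq) as fh:
            lines = fh.read().splitlines()
        seqs = lines[1::4]
        assert seqs and all(s in genome for s in seqs)

    def test_truth_fractions_match_profile(self, ref, tmp_path):
        """Truth gene counts are multinomial around the profile's own
        source fractions (chi-square GOF not rejected at alpha=0.01)."""
        n = 100_000
        profile = default_profile("bj_ev", ref, read_count=n)
        truth = simulate_library(profile, ref, tmp_path / "x.fq", None, seed=5)
        genes = sorted(profile.source_fractions)
        obs = np.array([truth.gene_counts.get(g, 0) for g in genes])
        exp = np.array([profile.source_fractions[g] * n for g in genes])
        keep = exp >= 5
        _chi, p = sps.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert p > 0.01

    def test_fragment_model_marginals_converge(self, ref, tmp_path):
        n = 100_000
        profile = default_profile("bj_ev", ref, read_count=n)
        truth = simulate_library(profile, ref, tmp_path / "y.fq", None, seed=6)
        model = profile.fragment_models["RNY5"]
        frags = sorted(model)
        obs = np.array([truth.fragment_counts["RNY5"].get(f, 0) for f in frags])
        exp = np.array([model[f] for f in frags]) * obs.sum()
        _chi, p = sps.chisquare(obs, exp)
        assert p > 0.01

    def test_ev_profile_anchors(self, ref):
        """The EV profile concentrates RNY5 mass on the processed forms and
        keeps the whole-cell profile dominated by the full-length form."""
        ev = default_profile("bj_ev", ref)
        cell = default_profile("bj_cell", ref)
        assert set(ev.fragment_models["RNY5"]) == {
            (1, 23), (1, 29), (1, 31), (1, 83), (52, 83),
        }
        assert cell.fragment_models["RNY5"][(1, 83)] > 0.9
        assert ev.source_fractions["RNY5"] > cell.source_fractions["RNY5"]

    def test_unknown_profile_rejected(self, ref):
        with pytest.raises(ConfigError):
            default_profile("hela_ev", ref)

    def test_bad_fractions_rejected(self, ref):
        profile = default_profile("bj_ev", ref, read_count=100)
        profile.source_fractions["RNY5"] += 0.5
        with pytest.raises(ConfigError, match="sum"):
            profile.validate(ref)


class TestProcessingRules:
    def test_full_length_in_ev_extract_yields_all_forms(self):
        res = simulate_processing(RNY5_83MER, "ev")
        assert set(res.products) == {23, 29, 31}
        assert res.substrate_remains

    def test_whole_cell_extract_is_inert(self):
        for substrate in (RNY5_83MER, RNY5_31MER, RNY5_MOTIF_SCRAMBLED):
            res = simulate_processing(substrate, "whole_cell")
            assert res.products == {}

    def test_31mer_trims_to_23(self):
        res = simulate_processing(RNY5_31MER, "ev")
        assert res.products == {23: "full"}

    def test_scrambled_31mer_not_processed(self):
        res = simulate_processing(RNY5_31MER_SCRAMBLED, "ev")
        assert res.products == {}

    def test_motif_scrambled_gives_residual_23(self):
        res = simulate_processing(RNY5_MOTIF_SCRAMBLED, "ev")
        assert res.products == {23: "residual"}

    def test_motif_deleted_and_3p_fragment_inert(self):
        for substrate in (RNY5_MOTIF_DELETED, RNY5_3P_32MER):
            assert simulate_processing(substrate, "ev").products == {}

    def test_duplex_is_protected(self):
        res = simulate_processing(RNY5_31MER, "ev", double_stranded=True)
        assert res.products == {}

    def test_terminal_23mer_product(self):
        assert simulate_processing(RNY5_23MER, "ev").products == {}

    def test_rule_coverage_error(self):
        with pytest.raises(RuleCoverageError):
            simulate_processing(RNY5_83MER, "ev", rules=[])


class TestCytometrySimulation:
    def test_event_table_shape_and_determinism(self, tmp_path):
        cond = CYTO_PRESETS["bj_untreated"]
        a = simulate_cytometry(cond, seed=3)
        b = simulate_cytometry(cond, seed=3)
        assert list(a.columns) == ["event_id", "hoechst", "yopro"]
        assert len(a) == cond.event_count
        assert a.equals(b)

    def test_realized_dead_fraction_tracks_truth(self):
        from evcargo.cytometry import gate

        for frac in (0.0, 0.205, 1.0):
            cond = CytoCondition("c", dead_fraction=frac, event_count=10_000)
            res = gate(simulate_cytometry(cond, seed=8), condition="c")
            sigma = 100 * np.sqrt(max(frac * (1 - frac), 1e-4) / res.n_hoechst_pos)
            assert abs(res.percent_dead - 100 * frac) <= max(3 * sigma, 0.5)

    def test_invalid_condition_rejected(self):
        with pytest.raises(ConfigError):
            CytoCondition("bad", dead_fraction=1.5).validate()
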