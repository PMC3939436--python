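"""Synthetic community generator: catalog structure, clone sampling,
planted loci, and the read-quality rules."""

import numpy as np
import pandas as pd
import pytest

from rdhprofiler import synthetic as syn
from rdhprofiler import coverage as cov
from rdhprofiler.errors import (CapacityError, InputError, ParameterError)


class TestReferenceCatalog:
    def test_zero_rate_family_absent(self):
        cat = syn.generate_reference_catalog(20, 100, 0.35, 0.0, seed=1)
        assert cat.mean_copy("rdhA", complete_only=False) == 0.0

    def test_rare_family_mean_copy_recomputed_from_matrix(self):
        cat = syn.generate_reference_catalog(20, 100, 0.35, 0.04, seed=1)
        j = cat.group_index("rdhA")
        mean = cat.copy_matrix[:, j].mean()
        assert 0.0 <= mean <= 0.15  # one copy among 20 genomes

    def test_universal_markers_meet_paper_like_criteria(self, small_catalog):
        for group in small_catalog.universal_groups:
            for domain in ("archaea", "bacteria"):
                assert small_catalog.presence_fraction(group, domain) >= 0.95
                assert small_catalog.mean_copy(group, domain=domain) < 1.2

    def test_deterministic_under_seed(self):
        a = syn.generate_reference_catalog(12, 50, 0.3, 0.1, seed=9)
        b = syn.generate_reference_catalog(12, 50, 0.3, 0.1, seed=9)
        assert np.array_equal(a.copy_matrix, b.copy_matrix)
        assert a.gene_lengths_aa == b.gene_lengths_aa

    @pytest.mark.parametrize("kwargs", [
        dict(n_genomes=3, n_groups=10, universal_fraction=0.5,
             target_family_rate=0.0),
        dict(n_genomes=10, n_groups=10, universal_fraction=1.5,
             target_family_rate=0.0),
        dict(n_genomes=10, n_groups=10, universal_fraction=0.5,
             target_family_rate=-0.1),
    ])
    def test_impossible_constraints_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            syn.generate_reference_catalog(seed=1, **kwargs)

    def test_table_round_trip_lengths_positive(self, small_catalog):
        table = small_catalog.to_table()
        assert (table["aa_length"] > 0).all()
        assert table["gene_id"].is_unique


class TestGenerateMetagenome:
    def test_zero_clones_empty_outputs(self, small_catalog):
        contigs, reads, calls, plac, truth = syn.generate_metagenome(
            small_catalog, None, n_clones=0, seed=1)
        assert len(reads) == 0 and plac.empty
        assert truth.total_read_nt == 0

    def test_single_genome_coverage_matches_closed_form(self):
        """With one genome at abundance 1 every gene's coverage should equal
        total read nucleotides / genome length, up to read-boundary effects
        at gene edges."""
        cat = syn.generate_reference_catalog(
            4, 30, 0.5, 0.0, seed=3, archaea_fraction=0.25)
        solo = dict.fromkeys((g.id for g in cat.genomes), 0.0)
        solo[cat.genomes[0].id] = 1.0
        for seed in (11, 12, 13):
            contigs, reads, calls, plac, truth = syn.generate_metagenome(
                cat, solo, n_clones=1000, read_len_range=(700, 700),
                seed=seed, emit_sequences=False)
            expected = truth.expected_single_copy_coverage
            own = calls[calls["contig"].str.startswith(cat.genomes[0].id)]
            nt = np.zeros(len(own))
            for i, g in enumerate(own.itertuples()):
                sel = plac[plac["contig_id"] == g.contig]
                ov = (np.minimum(sel["end"], g.end)
                      - np.maximum(sel["start"], g.start)).clip(lower=0)
                nt[i] = ov.sum()
            observed = (nt / (own["end"] - own["start"])).mean()
            assert observed == pytest.approx(expected, rel=0.05)

    def test_clones_are_paired_and_within_length_bounds(self, small_catalog):
        contigs, reads, calls, plac, truth = syn.generate_metagenome(
            small_catalog, None, n_clones=50, seed=4)
        assert len(reads) == 50
        for clone_id, fwd, rev in reads.clones:
            assert 650 <= len(fwd.sequence) <= 800
            assert 650 <= len(rev.sequence) <= 800
        assert plac.groupby("clone_id").size().eq(2).all()

    def test_conservation_reads_equal_placements(self, small_catalog):
        """Total nucleotides in truth placements equal total emitted read
        length (after trimming, which keeps whole reads at uniform Q40)."""
        contigs, reads, calls, plac, truth = syn.generate_metagenome(
            small_catalog, None, n_clones=80, seed=5)
        trimmed = 0
        for _, fwd, rev in reads.clones:
            for rec in (fwd, rev):
                lo, hi = syn.quality_trim(rec.qualities)
                trimmed += hi - lo
        assert trimmed == (plac["end"] - plac["start"]).sum()
        assert trimmed == truth.total_read_nt

    def test_determinism_byte_identical(self, small_catalog):
        out = [syn.generate_metagenome(small_catalog, None, 30, seed=8)
               for _ in range(2)]
        assert out[0][0] == out[1][0]  # contig dicts
        pd.testing.assert_frame_equal(out[0][3], out[1][3])
        assert out[0][1].clones == out[1][1].clones

    def test_empty_catalog_rejected(self):
        empty = syn.ReferenceCatalog(genomes=[], groups=[],
                                     copy_matrix=np.zeros((0, 0), dtype=int),
                                     gene_lengths_aa={})
        with pytest.raises(InputError):
            syn.generate_metagenome(empty, None, 10, seed=1)

    def test_single_copy_ratio_recovers_one(self, small_catalog,
                                            small_markers, small_metagenome):
        """Average coverage ratio of a single-copy group is ~1 over seeds."""
        ratios = []
        for seed in range(5):
            _, _, calls, plac, _ = syn.generate_metagenome(
                small_catalog, None, 1000, seed=seed, emit_sequences=False)
            prof = cov.compute_coverage_profile(calls, plac, small_catalog,
                                                small_markers)
            per_group = prof.groupby("group_id")["avg_coverage_ratio"].sum()
            ratios.append(per_group[sorted(small_markers)[0]])
        ratios = np.array(ratios)
        assert abs(ratios.mean() - 1.0) <= 3 * ratios.std(ddof=1) / np.sqrt(5)


class TestPlantRdhLoci:
    def test_capacity_error(self, small_catalog):
        contigs = {"c1": "ACGT" * 100}
        calls = pd.DataFrame(columns=syn.GENE_CALL_COLUMNS)
        with pytest.raises(CapacityError):
            syn.plant_rdh_loci(contigs, calls, n_rdhA=2, seed=1)

    def test_no_companions_when_fraction_zero(self):
        contigs = {f"c{i}": "ACGT" * 500 for i in range(5)}
        calls = pd.DataFrame(columns=syn.GENE_CALL_COLUMNS)
        _, _, planted = syn.plant_rdh_loci(contigs, calls, 5,
                                           with_rdhB=0.0, seed=2)
        assert planted.planted_rdhB == []

    def test_planted_features_recoverable_by_coordinates(self):
        contigs = {f"c{i}": "ACGT" * 500 for i in range(3)}
        calls = pd.DataFrame(columns=syn.GENE_CALL_COLUMNS)
        new_contigs, new_calls, planted = syn.plant_rdh_loci(
            contigs, calls, 3, syn.MotifConfig(tat_prob=1.0),
            with_rdhB=1.0, seed=3)
        from Bio.Seq import Seq
        for rec in planted.planted_motifs:
            nt = new_contigs[rec["contig"]][rec["start"]:rec["end"]]
            prot = str(Seq(nt).translate())
            assert prot.startswith("M")
            for pos in rec["fes_positions"]:
                assert prot[pos] == "C"


class TestQualityRules:
    def test_trim_all_good(self):
        assert syn.quality_trim([30] * 100) == (0, 100)

    def test_trim_all_bad(self):
        assert syn.quality_trim([10] * 100) == (0, 0)

    def test_trim_mixed_windows_hand_case(self):
        """First 20 bp at Q30 pass; the next window has only 5/20 bases at
        Q20+, failing the 80% rule, so only the first window is kept."""
        q = [30] * 20 + [25] * 5 + [10] * 15
        assert syn.quality_trim(q) == (0, 20)

    def test_trim_keeps_leftmost_of_tied_runs(self):
        q = [30] * 20 + [5] * 20 + [30] * 20
        assert syn.quality_trim(q) == (0, 20)

    def test_trim_trailing_partial_window_own_length(self):
        # 25 bases: full window passes, 5-base tail at Q30 passes on its own
        q = [30] * 25
        assert syn.quality_trim(q) == (0, 25)

    def test_mask_identity_when_all_high(self):
        assert syn.mask_low_quality("ACGT", [20, 20, 15, 30]) == "ACGT"

    def test_mask_everything_when_all_low(self):
        assert syn.mask_low_quality("ACGT", [5, 0, 14, 2]) == "XXXX"

    def test_mask_positionwise(self):
        assert syn.mask_low_quality("ACGTA", [20, 3, 15, 14, 40]) == "AXGXA"

    def test_mask_length_mismatch(self):
        with pytest.raises(InputError):
            syn.mask_low_quality("ACGT", [20, 20])
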