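"""Motif detectors, rdhB neighborhood screen, tree pruning and
support-thresholded cluster extraction."""

import numpy as np
import pandas as pd
import pytest

from rdhprofiler import rdh
from rdhprofiler import synthetic as syn
from rdhprofiler.errors import InputError
from rdhprofiler.orthologs import HomologyHit, MergedOrthologTable


def translate_gene(contigs: dict, row) -> str:
    from Bio.Seq import Seq
    return str(Seq(contigs[row.contig][row.start:row.end]).translate())


class TestSelectRdhGroups:
    def _table(self, n_members):
        table = MergedOrthologTable()
        for i in range(n_members):
            table._add_reference("grp", "g0", f"gene{i}", 350)
        return table

    def _annos(self, positives):
        return [rdh.DomainAnnotation(f"gene{i}", "RdhA", 100.0, True)
                for i in positives]

    def test_half_positive_is_selected(self):
        table = self._table(6)
        assert rdh.select_rdh_groups(table, self._annos(range(3))) == {"grp"}

    def test_below_half_rejected(self):
        table = self._table(6)
        assert rdh.select_rdh_groups(table, self._annos(range(2))) == set()

    def test_failing_annotations_ignored(self):
        table = self._table(2)
        annos = [rdh.DomainAnnotation("gene0", "RdhA", 10.0, False)]
        assert rdh.select_rdh_groups(table, annos) == set()


class TestTatMotif:
    def test_canonical_twin_arginine(self):
        assert rdh.detect_tat_motif("MSRRGFLKAAA", True) == rdh.PRESENT

    def test_truncated_gene_not_assessable(self):
        assert rdh.detect_tat_motif("SRRGFLK", False) == rdh.NOT_ASSESSABLE

    def test_no_rr_pair_absent(self):
        assert rdh.detect_tat_motif("MSKAGFLK" * 10, True) == rdh.ABSENT

    def test_motif_outside_n_region_absent(self):
        seq = "M" + "A" * 60 + "SRRGFLK"
        assert rdh.detect_tat_motif(seq, True, n_region=50) == rdh.ABSENT

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            rdh.detect_tat_motif("", True)

    def test_masked_runs_never_present(self):
        assert rdh.detect_tat_motif("X" * 80, True) == rdh.ABSENT


class TestFesMotifs:
    def test_poly_alanine_zero(self):
        assert rdh.detect_fes_motifs("A" * 100) == 0

    def test_two_planted_blocks(self):
        block = "CAACAACAAAC"  # C-x2-C-x2-C-x3-C
        seq = "M" + "A" * 20 + block + "G" * 20 + block + "A" * 10
        assert rdh.detect_fes_motifs(seq) == 2
        assert rdh.has_twin_fes(seq)

    def test_single_block_is_not_twin(self):
        assert not rdh.has_twin_fes("M" + "CAACAACAAAC" + "A" * 30)

    def test_masked_runs_never_match(self):
        assert rdh.detect_fes_motifs("X" * 60) == 0


class TestTmHelices:
    def test_poly_glutamate_zero(self):
        assert rdh.count_tm_helices("E" * 100) == 0

    def test_three_separated_poly_leucine_stretches(self):
        linker = "E" * 25
        seq = linker + ("L" * 21 + linker) * 3
        assert rdh.count_tm_helices(seq) == 3

    def test_below_window_length_zero(self):
        assert rdh.count_tm_helices("L" * 10) == 0

    def test_adjacent_passing_windows_merge(self):
        assert rdh.count_tm_helices("E" * 20 + "L" * 40 + "E" * 20) == 1


class TestRdhBScreen:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=syn.GENE_CALL_COLUMNS)

    def _loci(self):
        return self._calls([("tig", 10000, 11050, "+", "rdhA1", "rdhA")])

    def test_qualifying_candidate(self):
        calls = self._calls([("tig", 12550, 12910, "+", "b1", "x")])
        prots = {"b1": "M" + "E" * 5 + ("L" * 21 + "E" * 19) * 3}
        cands, trunc = rdh.screen_rdhB_neighbors(calls, self._loci(), prots)
        assert list(cands["gene_id"]) == ["b1"]
        assert trunc.empty

    def test_length_rule_rejects_160aa(self):
        calls = self._calls([("tig", 12550, 13030, "+", "b1", "x")])
        prots = {"b1": ("M" + "E" * 5 + ("L" * 21 + "E" * 19) * 3
                        + "E" * 34)}  # 160 aa
        cands, _ = rdh.screen_rdhB_neighbors(calls, self._loci(), prots)
        assert cands.empty

    def test_distance_rule_rejects_beyond_2kb(self):
        calls = self._calls([("tig", 13100, 13460, "+", "b1", "x")])
        prots = {"b1": "M" + "E" * 5 + ("L" * 21 + "E" * 19) * 3}
        cands, _ = rdh.screen_rdhB_neighbors(calls, self._loci(), prots)
        assert cands.empty

    def test_truncated_gene_reported_separately(self):
        calls = self._calls([("tig", 12550, 12910, "+", "b1", "x")])
        prots = {"b1": "M" + "E" * 5 + ("L" * 21 + "E" * 19) * 3}
        cands, trunc = rdh.screen_rdhB_neighbors(
            calls, self._loci(), prots, contig_lengths={"tig": 12910})
        assert cands.empty
        assert list(trunc["gene_id"]) == ["b1"]

    def test_coordinate_translation_invariance(self):
        calls = self._calls([("tig", 12550, 12910, "+", "b1", "x")])
        prots = {"b1": "M" + "E" * 5 + ("L" * 21 + "E" * 19) * 3}
        base, _ = rdh.screen_rdhB_neighbors(calls, self._loci(), prots)
        shift = 5000
        calls2 = calls.assign(start=calls["start"] + shift,
                              end=calls["end"] + shift)
        loci2 = self._loci().assign(
            start=self._loci()["start"] + shift,
            end=self._loci()["end"] + shift)
        shifted, _ = rdh.screen_rdhB_neighbors(calls2, loci2, prots)
        assert list(shifted["gene_id"]) == list(base["gene_id"])
        assert list(shifted["distance_bp"]) == list(base["distance_bp"])

    def test_planted_companions_all_recovered_no_decoy_hits(
            self, planted_community):
        contigs, calls, planted = planted_community
        loci = pd.DataFrame(planted.planted_motifs)
        prots = {row.gene_id: translate_gene(contigs, row)
                 for row in calls.itertuples()
                 if row.gene_id.startswith("smkt1")}
        contig_lengths = {c: len(s) for c, s in contigs.items()}
        cands, trunc = rdh.screen_rdhB_neighbors(
            calls, loci, prots, contig_lengths)
        expected = {b["gene_id"] for b in planted.planted_rdhB}
        assert set(cands["gene_id"]) == expected
        decoys = {d["gene_id"] for d in planted.planted_decoys}
        assert not (set(cands["gene_id"]) & decoys)


NEWICK_6 = "(((a:1,b:1)0.95:1,(c:1,d:1)0.60:1)0.85:1,(e:1,f:1)0.97:1);"


class TestPruneTree:
    def test_all_positive_unchanged(self):
        tree = rdh.load_support_tree(NEWICK_6)
        out = rdh.prune_tree_by_domain(tree, {"a", "b", "c", "d", "e", "f"})
        assert {l.taxon.label for l in out.leaf_node_iter()} == set("abcdef")

    def test_negative_cherry_removed_rest_intact(self):
        tree = rdh.load_support_tree(NEWICK_6)
        out = rdh.prune_tree_by_domain(tree, {"a", "b", "c", "d"})
        assert {l.taxon.label for l in out.leaf_node_iter()} == set("abcd")

    def test_negative_leaf_inside_positive_clade_retained(self):
        tree = rdh.load_support_tree(NEWICK_6)
        out = rdh.prune_tree_by_domain(tree, {"a", "c", "d", "e", "f"})
        # b is negative but sits in the positive cherry (a,b): retained
        assert "b" in {l.taxon.label for l in out.leaf_node_iter()}

    def test_idempotent(self):
        tree = rdh.load_support_tree(NEWICK_6)
        once = rdh.prune_tree_by_domain(tree, {"a", "b"})
        twice = rdh.prune_tree_by_domain(once, {"a", "b"})
        assert ({l.taxon.label for l in once.leaf_node_iter()}
                == {l.taxon.label for l in twice.leaf_node_iter()})

    def test_zero_positive_leaves_empty_with_warning(self):
        tree = rdh.load_support_tree(NEWICK_6)
        with pytest.warns(UserWarning):
            out = rdh.prune_tree_by_domain(tree, set())
        assert sum(1 for l in out.leaf_node_iter()
                   if l.taxon is not None) == 0


class TestExtractSupportedClusters:
    def test_high_support_cluster(self):
        tree = rdh.load_support_tree(NEWICK_6)
        out = rdh.extract_supported_clusters(tree, {"C1": ["a", "b"]})
        assert set(out["gene_id"]) == {"a", "b"}
        assert (out["status"] == "supported").all()
        assert out["support"].iloc[0] == pytest.approx(0.95)

    def test_low_support_cluster_tentative(self):
        # mirrors a 0.71-support cluster kept with a tentative name
        nwk = "((a:1,b:1)0.71:1,(c:1,d:1)0.95:1);"
        tree = rdh.load_support_tree(nwk)
        out = rdh.extract_supported_clusters(tree, {"Ds3": ["a", "b"]})
        assert (out["status"] == "tentative").all()
        assert out["support"].iloc[0] == pytest.approx(0.71)

    def test_exact_boundary_inclusive(self):
        nwk = "((a:1,b:1)0.90:1,(c:1,d:1)0.95:1);"
        tree = rdh.load_support_tree(nwk)
        out = rdh.extract_supported_clusters(tree, {"C": ["a", "b"]})
        assert (out["status"] == "supported").all()

    def test_support_min_zero_assigns_regardless(self):
        nwk = "((a:1,b:1)0.05:1,(c:1,d:1)0.95:1);"
        tree = rdh.load_support_tree(nwk)
        out = rdh.extract_supported_clusters(tree, {"C": ["a", "b"]},
                                             support_min=0.0)
        assert set(out["gene_id"]) == {"a", "b"}
        assert (out["status"] == "supported").all()

    def test_missing_seed_rejected(self):
        tree = rdh.load_support_tree(NEWICK_6)
        with pytest.raises(InputError):
            rdh.extract_supported_clusters(tree, {"C": ["zz"]})

    def test_clade_membership_includes_non_seed_leaves(self):
        tree = rdh.load_support_tree(NEWICK_6)
        out = rdh.extract_supported_clusters(tree, {"C": ["a", "d"]})
        # smallest clade containing a and d spans a, b, c, d
        assert set(out["gene_id"]) == {"a", "b", "c", "d"}


class TestClassifyByTopHit:
    def _hit(self, q, s, bits, ident=0.8):
        return HomologyHit(q, s, ident, 200, 1e-20, bits)

    def test_unhit_read_unclassified(self):
        out = rdh.classify_by_top_hit([], {"g1": "Smkt1"}, reads=["r1"])
        assert out == {"r1": rdh.UNCLASSIFIED}

    def test_best_hit_cluster_inherited(self):
        hits = [self._hit("r1", "g1", 120), self._hit("r1", "g2", 90)]
        out = rdh.classify_by_top_hit(hits, {"g1": "Smkt1", "g2": "Dh"})
        assert out == {"r1": "Smkt1"}

    def test_tie_breaks_on_identity_then_subject(self):
        hits = [self._hit("r1", "g2", 100, ident=0.9),
                self._hit("r1", "g1", 100, ident=0.8)]
        out = rdh.classify_by_top_hit(hits, {"g1": "A", "g2": "B"})
        assert out == {"r1": "B"}

    def test_reads_from_labeled_genes_mostly_correct(self):
        """Reads shed from cluster-labeled genes at moderate divergence get
        >= 95% correct labels via their top hit."""
        rng = np.random.default_rng(4)
        assignments = {f"g{i}": ("Smkt1" if i % 2 else "Dh")
                       for i in range(10)}
        hits, want = [], {}
        for r in range(100):
            read = f"r{r}"
            true_subject = f"g{rng.integers(10)}"
            want[read] = assignments[true_subject]
            hits.append(self._hit(read, true_subject,
                                  bits=float(rng.uniform(150, 250))))
            decoy = f"g{rng.integers(10)}"
            hits.append(self._hit(read, decoy,
                                  bits=float(rng.uniform(60, 140)),
                                  ident=0.5))
        out = rdh.classify_by_top_hit(hits, assignments)
        correct = sum(out[r] == want[r] for r in want)
        assert correct >= 95
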