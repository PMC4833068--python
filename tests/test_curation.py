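"""Hit filtering, column trimming, branch cutting, tip masking, pipeline."""

import numpy as np
import pytest

from conftest import random_tree
from phyloforge.curation import (CurationParams, HitRecord, HomologGroup,
                                 curate_pipeline, cut_long_branches,
                                 filter_cluster, filter_hits,
                                 mask_isoform_tips, parse_hit_table,
                                 remove_spurious_tips, trim_columns)
from phyloforge.seqs import Alignment, SeqRecord, TaxonMap
from phyloforge.simulate import SimulationConfig, simulate_family
from phyloforge.trees import random_reroot, read_newick, reroot


def hit(pident=60.0, qcov=0.8, evalue=1e-10, query="a@1", subject="b@1"):
    return HitRecord(query, subject, pident, int(pident), 100, 100, qcov,
                     evalue)


class TestHitFiltering:
    @pytest.mark.parametrize("record,kept", [
        (hit(pident=60, qcov=0.8, evalue=1e-10), True),
        (hit(pident=40, qcov=0.9, evalue=1e-10), False),   # identity <= 50
        (hit(pident=60, qcov=0.5), False),                 # coverage <= 0.7
        (hit(pident=50.0), False),                         # boundary strict
        (hit(qcov=0.7), False),                            # boundary strict
        (hit(evalue=1e-3), False),
        (hit(subject="a@1"), False),                       # self hit
    ])
    def test_rule_application(self, record, kept):
        assert (filter_hits([record]) == [record]) is kept

    def test_malformed_row_reports_line_number(self):
        text = "a\tb\t90.0\t100\t5\t0\t1\t100\t1\t100\t1e-50\t200\t100\t100\n" \
               "broken\trow\n"
        with pytest.raises(ValueError, match="line 2"):
            parse_hit_table(text)

    def test_parse_computes_coverage_and_identity(self):
        text = "a\tb\t90.0\t100\t10\t0\t11\t100\t1\t100\t1e-50\t200\t120\t100\n"
        (rec,) = parse_hit_table(text)
        assert rec.nident == 90
        assert rec.qcov == pytest.approx(90 / 120)


class TestClusterFilter:
    def make_group(self, lengths_by_id):
        return HomologGroup("g1", [SeqRecord(i, "A" * n)
                                   for i, n in lengths_by_id.items()])

    def test_short_member_removed(self, simple_taxa):
        g = self.make_group({f"{t}@1": 100 for t in "ABCDEFGH"} | {"A@2": 39})
        out = filter_cluster(g, CurationParams(), simple_taxa)
        assert "A@2" not in out.member_ids()
        assert len(out.members) == 8

    def test_too_few_ingroup_taxa_rejected(self, simple_taxa):
        g = self.make_group({f"{t}@1": 100 for t in "ABCDEFG"})  # 7 taxa
        assert filter_cluster(g, CurationParams(), simple_taxa) is None

    def test_clean_group_unchanged(self, simple_taxa):
        g = self.make_group({f"{t}@1": 40 for t in "ABCDEFGH"})
        out = filter_cluster(g, CurationParams(), simple_taxa)
        assert out.member_ids() == g.member_ids()


class TestTrimColumns:
    def build(self, n_rows, filled_per_col):
        cols = []
        for filled in filled_per_col:
            cols.append(["A" if i < filled else "-" for i in range(n_rows)])
        rows = ["".join(col[i] for col in cols) for i in range(n_rows)]
        return Alignment([SeqRecord(f"T{i}@1", r) for i, r in enumerate(rows)])

    def test_boundary_at_occupancy_threshold(self):
        aln = self.build(100, [4, 6, 100])
        out, _ = trim_columns(aln, 0.05)
        assert out.n_cols == 2        # 4/100 removed, 6/100 and full kept

    def test_zero_threshold_keeps_everything(self):
        aln = self.build(10, [0, 1, 10])
        out, _ = trim_columns(aln, 0.0)
        assert out.n_cols == 3

    def test_all_gap_rows_flagged_not_dropped(self):
        aln = Alignment([SeqRecord("A@1", "AA-"), SeqRecord("B@1", "AA-"),
                         SeqRecord("C@1", "--A")])
        out, empty = trim_columns(aln, 0.6)
        assert out.n_rows == 3 and empty == ["C@1"]

    def test_only_drops_columns_never_edits_residues(self):
        rng = np.random.default_rng(0)
        chars = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(20):
            rows = ["".join(rng.choice(chars, size=30)) for _ in range(8)]
            aln = Alignment([SeqRecord(f"T{i}@1", r)
                             for i, r in enumerate(rows)])
            out, _ = trim_columns(aln, float(rng.uniform(0, 1)))
            for before, after in zip(aln.rows, out.rows):
                assert after.n_unambiguous <= before.n_unambiguous
                # surviving columns are a subsequence of the original row
                it = iter(before.residues)
                assert all(c in it for c in after.residues)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            trim_columns(Alignment([]), 0.5)


class TestCutLongBranches:
    def test_no_long_branches_returns_identical_tree(self, quartet):
        (only,) = cut_long_branches(quartet, 2.0)
        assert sorted(only.tip_labels()) == ["A", "B", "C", "D"]

    def test_single_long_internal_branch_splits_in_two(self):
        t = read_newick("((A:0.1,B:0.1):2.5,(C:0.1,D:0.1):0.1);")
        parts = cut_long_branches(t, 2.0)
        assert sorted(sorted(p.tip_labels()) for p in parts) == \
            [["A", "B"], ["C", "D"]]

    def test_two_long_branches_give_three_components(self):
        t = read_newick(
            "(((A:0.1,B:0.1):3.0,(C:0.1,D:0.1):0.1):0.1,(E:0.1,F:3.5):0.1);")
        parts = cut_long_branches(t, 2.0)
        assert sorted(sorted(p.tip_labels()) for p in parts) == \
            [["A", "B"], ["C", "D", "E"], ["F"]]

    def test_no_output_branch_exceeds_cutoff(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            t = random_tree(rng, [f"t{i}" for i in range(12)], max_len=1.2)
            for part in cut_long_branches(t, 0.9):
                for n in part.nodes():
                    if n is not part.root and n.length is not None:
                        assert n.length <= 0.9

    def test_invariant_to_rerooting(self):
        import random as pyrandom
        rng = np.random.default_rng(9)
        t = random_tree(rng, [f"t{i}" for i in range(14)], max_len=1.2)
        want = sorted(tuple(sorted(p.tip_labels()))
                      for p in cut_long_branches(t, 0.9))
        pyr = pyrandom.Random(1)
        for _ in range(50):
            r = random_reroot(t, pyr)
            got = sorted(tuple(sorted(p.tip_labels()))
                         for p in cut_long_branches(r, 0.9))
            assert got == want


class TestSpuriousTips:
    def test_long_tip_with_tiny_sister_removed(self):
        t = read_newick("((X:0.25,S:0.01):0.1,(C:0.1,D:0.1):0.1);")
        out = remove_spurious_tips(t)
        assert "X" not in out.tip_labels()

    def test_ratio_below_threshold_kept(self):
        t = read_newick("((X:0.25,S:0.05):0.1,(C:0.1,D:0.1):0.1);")
        assert "X" in remove_spurious_tips(t).tip_labels()  # ratio 5 < 10

    def test_below_absolute_cutoff_kept(self):
        t = read_newick("((X:0.15,S:0.001):0.1,(C:0.1,D:0.1):0.1);")
        assert "X" in remove_spurious_tips(t).tip_labels()

    def test_internal_sister_uses_stepwise_depth(self):
        # sister subtree (A:0.004,B:0.004):0.004 -> depth 0.004+0.004=0.008
        t = read_newick("((X:0.25,(A:0.004,B:0.004):0.004):0.1,C:0.1);")
        out = remove_spurious_tips(t)
        assert "X" not in out.tip_labels()
        # same topology, deeper sister: 0.02+0.01 = 0.03, ratio < 10
        t2 = read_newick("((X:0.25,(A:0.01,B:0.01):0.02):0.1,C:0.1);")
        assert "X" in remove_spurious_tips(t2).tip_labels()


class TestIsoformMasking:
    def taxa(self):
        return TaxonMap(ingroup={"X", "Y", "Z"}, outgroup={"Aq"},
                        root_taxon="Aq")

    def test_cherry_keeps_higher_character_count(self):
        t = read_newick("((x@1:0.01,x@2:0.01):0.1,Y@1:0.1);")
        # taxon is the id prefix before '@': both tips are taxon 'x'
        out = mask_isoform_tips(t, self.taxa(), {"x@1": 300, "x@2": 200,
                                                 "Y@1": 100})
        assert sorted(out.tip_labels()) == ["Y@1", "x@1"]

    def test_paraphyletic_grade_keeps_single_best(self):
        t = read_newick("((x@1:0.1,(x@2:0.1,(x@3:0.1,Y@1:0.1):0.1):0.1):0.1,Z@1:0.2);")
        out = mask_isoform_tips(t, self.taxa(),
                                {"x@1": 100, "x@2": 350, "x@3": 200,
                                 "Y@1": 50, "Z@1": 50})
        assert sorted(out.tip_labels()) == ["Y@1", "Z@1", "x@2"]

    def test_one_tip_per_taxon_is_identity(self, quartet):
        out = mask_isoform_tips(quartet, self.taxa(),
                                {t: 1 for t in "ABCD"})
        assert sorted(out.tip_labels()) == ["A", "B", "C", "D"]

    def test_tie_breaks_to_smallest_id(self):
        t = read_newick("((x@b:0.01,x@a:0.01):0.1,Y@1:0.1);")
        out = mask_isoform_tips(t, self.taxa(), {"x@a": 100, "x@b": 100,
                                                 "Y@1": 1})
        assert "x@a" in out.tip_labels()

    def test_missing_char_count_names_tip(self):
        t = read_newick("((x@1:0.01,x@2:0.01):0.1,Y@1:0.1);")
        with pytest.raises(KeyError, match="x@2"):
            mask_isoform_tips(t, self.taxa(), {"x@1": 1, "Y@1": 1})

    def test_simulated_isoforms_reduced_to_one_per_taxon(self):
        config = SimulationConfig(seed=5, isoform_rate=0.3, dup_rate=0.0,
                                  loss_rate=0.0, wgd_events=[])
        rng = np.random.default_rng(5)
        found = 0
        for i in range(20):
            fam = simulate_family(config, i, rng)
            if not fam.truth.isoforms:
                continue
            found += 1
            counts = {t: 1000 for t in fam.tree.tip_labels()}
            out = mask_isoform_tips(fam.tree, config.taxa, counts)
            taxa_seen = [config.taxa.taxon_of(l) for l in out.tip_labels()]
            assert len(taxa_seen) == len(set(taxa_seen))
        assert found > 5


class TestPipeline:
    def make_group(self, tree, taxa):
        members = [SeqRecord(l, "A" * 100) for l in tree.tip_labels()]
        aln = Alignment(list(members))
        return HomologGroup("fam", members, aln, tree)

    def test_clean_group_is_identity(self):
        config = SimulationConfig(seed=2, dup_rate=0.0, loss_rate=0.0,
                                  wgd_events=[])
        rng = np.random.default_rng(2)
        fam = simulate_family(config, 0, rng)
        group = self.make_group(fam.tree, config.taxa)
        out, log = curate_pipeline(group, CurationParams(), config.taxa)
        assert len(out) == 1 and log == []
        assert sorted(out[0].tree.tip_labels()) == \
            sorted(fam.tree.tip_labels())

    def test_contaminant_branch_separated_at_first_cutoff(self):
        config = SimulationConfig(seed=3, dup_rate=0.0, loss_rate=0.0,
                                  wgd_events=[], contaminant_rate=1.0)
        rng = np.random.default_rng(3)
        fam = simulate_family(config, 0, rng)
        (contaminant,) = fam.truth.contaminants
        group = self.make_group(fam.tree, config.taxa)
        out, log = curate_pipeline(group, CurationParams(), config.taxa)
        assert len(out) == 1
        assert contaminant not in out[0].tree.tip_labels()
        assert any(e.stage.startswith("cut@2") for e in log)

    def test_simulated_isoform_pair_leaves_one_tip(self):
        config = SimulationConfig(seed=8, dup_rate=0.0, loss_rate=0.0,
                                  wgd_events=[], isoform_rate=0.5)
        rng = np.random.default_rng(8)
        fam = simulate_family(config, 0, rng)
        assert fam.truth.isoforms
        group = self.make_group(fam.tree, config.taxa)
        out, log = curate_pipeline(group, CurationParams(), config.taxa)
        assert len(out) == 1
        labels = out[0].tree.tip_labels()
        taxa_seen = [config.taxa.taxon_of(l) for l in labels]
        assert len(taxa_seen) == len(set(taxa_seen))
        assert any(e.stage == "isoform_mask" for e in log)
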