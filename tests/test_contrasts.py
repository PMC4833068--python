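"""Codon alignment prep, stepwise averaging, contrasts, sign tests."""

import numpy as np
import pytest
from scipy import stats

from conftest import random_tree
from phyloforge.contrasts import (ContrastDefinition, RateTrees,
                                  back_translate, compute_contrast,
                                  find_sister_pairs, label_branch_model,
                                  run_contrast_study, sign_test,
                                  stepwise_average, trim_codon_columns)
from phyloforge.seqs import Alignment, SeqRecord, TaxonMap
from phyloforge.simulate import (SimulationConfig, assign_branch_lengths,
                                 default_contrast_definitions,
                                 default_species_tree, simulate_family)
from phyloforge.orthology import extract_rooted_clades
from phyloforge.trees import read_newick


class TestBackTranslate:
    def test_gap_becomes_triple_gap(self):
        aln = Alignment([SeqRecord("x@1", "M-K")])
        out = back_translate(aln, {"x@1": "ATGAAA"})
        assert out.rows[0].residues == "ATG---AAA"

    def test_terminal_stop_tolerated_and_dropped(self):
        aln = Alignment([SeqRecord("x@1", "MK")])
        out = back_translate(aln, {"x@1": "ATGAAATAA"})
        assert out.rows[0].residues == "ATGAAA"

    def test_codon_disagreement_names_sequence_and_position(self):
        aln = Alignment([SeqRecord("x@1", "MK")])
        with pytest.raises(ValueError, match="x@1 position 2"):
            back_translate(aln, {"x@1": "ATGGGG"})   # GGG is G, not K

    def test_length_mismatch_is_error(self):
        aln = Alignment([SeqRecord("x@1", "MK")])
        with pytest.raises(ValueError, match="x@1"):
            back_translate(aln, {"x@1": "ATGAA"})


class TestTrimCodonColumns:
    def build(self, columns):
        """columns: list of per-row codon lists."""
        n_rows = len(columns[0])
        rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
        return Alignment([SeqRecord(f"t{i}@1", r)
                          for i, r in enumerate(rows)], "codon")

    def test_boundary_inclusive_at_threshold(self):
        good, bad = "ATG", "A-G"
        col1 = self.build([[good] + [bad] * 9])      # 1/10 unambiguous
        assert trim_codon_columns(col1, 0.2).n_cols == 0
        col2 = self.build([[good] * 2 + [bad] * 8])  # 2/10: boundary kept
        assert trim_codon_columns(col2, 0.2).n_cols == 3

    def test_all_unambiguous_unchanged(self):
        aln = Alignment([SeqRecord("a@1", "ATGAAA"),
                         SeqRecord("b@1", "ATGAAG")], "codon")
        out = trim_codon_columns(aln, 0.2)
        assert out.rows[0].residues == "ATGAAA"

    def test_drops_whole_codons_only(self):
        aln = Alignment([SeqRecord("a@1", "ATG" + "A-A" + "TTT"),
                         SeqRecord("b@1", "ATG" + "ANA" + "TTT")], "codon")
        out = trim_codon_columns(aln, 0.2)
        assert out.n_cols == 6
        assert out.rows[0].residues == "ATGTTT"


class TestLabelBranchModel:
    def setup_method(self):
        self.taxa = TaxonMap(
            ingroup={"W1", "W2", "H1", "H2", "X1"}, outgroup={"Aq"},
            habit={"W1": "W", "W2": "W", "H1": "H", "H2": "H", "X1": "H"},
            root_taxon="Aq")
        self.defn = ContrastDefinition("A", {"W1", "W2"}, {"H1", "H2"})

    def test_marks_both_sister_subtrees(self):
        t = read_newick("(((W1@1:1,W2@1:1):1,(H1@1:1,H2@1:1):1):1,X1@1:1);")
        (job,) = label_branch_model(t, self.defn, self.taxa, "c1")
        assert "#1" in job.newick and "#2" in job.newick
        assert "(W1@1:1,W2@1:1)#1" in job.newick
        assert "(H1@1:1,H2@1:1)#2" in job.newick
        assert job.config["model"] == 2

    def test_clade_without_herbaceous_side_skipped(self):
        t = read_newick("((W1@1:1,W2@1:1):1,X1@1:1);")
        assert label_branch_model(t, self.defn, self.taxa, "c1") == []

    def test_multiple_candidate_pairs_all_emitted(self):
        t = read_newick("(((W1@1:1,H1@1:1):1,(W2@1:1,H2@1:1):1):1,X1@1:1);")
        jobs = label_branch_model(t, self.defn, self.taxa, "c1")
        assert len(jobs) == 2


class TestStepwiseAverage:
    def test_cherry_is_plain_mean(self):
        t = read_newick("(A:0.1,B:0.3);")
        assert stepwise_average(t.root) == pytest.approx(0.2)

    def test_distinguishes_from_arithmetic_tip_mean(self):
        t = read_newick("((A:0.1,B:0.1):0.1,C:0.3);")
        assert stepwise_average(t.root) == pytest.approx(0.25)

    def test_single_tip_is_zero(self):
        t = read_newick("(A:0.5);")
        assert stepwise_average(t.root.children[0]) == 0.0

    def test_ladder_equals_path_length(self):
        t = read_newick("(((A:0.1):0.2):0.3);")
        assert stepwise_average(t.root) == pytest.approx(0.6)

    def test_against_recursive_oracle_on_random_trees(self):
        def oracle(node):
            if not node.children:
                return 0.0
            return float(np.mean([(c.length or 0) + oracle(c)
                                  for c in node.children]))
        rng = np.random.default_rng(17)
        for _ in range(200):
            t = random_tree(rng, [f"t{i}" for i in range(10)])
            assert stepwise_average(t.root) == pytest.approx(oracle(t.root))


class TestComputeContrast:
    def setup_method(self):
        self.taxa = TaxonMap(
            ingroup={"W1", "W2", "H1", "H2"}, outgroup={"Aq"},
            habit={"W1": "W", "W2": "W", "H1": "H", "H2": "H"},
            root_taxon="Aq")
        self.defn = ContrastDefinition("A", {"W1", "W2"}, {"H1", "H2"})

    def rate_trees(self, w_stem, w_tip, h_stem, h_tip):
        text = (f"((W1@1:{w_tip},W2@1:{w_tip}):{w_stem},"
                f"(H1@1:{h_tip},H2@1:{h_tip}):{h_stem});")
        return RateTrees(read_newick(text), read_newick(text))

    def pair_tips(self):
        return {"W1@1", "W2@1", "H1@1", "H2@1"}

    def test_herbaceous_longer_is_positive(self):
        rt = self.rate_trees(0.05, 0.05, 0.15, 0.15)   # LW=0.1, LH=0.3
        c = compute_contrast(rt, self.pair_tips(), self.defn, self.taxa)
        assert c.ds_contrast == pytest.approx(2.0)
        assert c.included

    def test_antisymmetry_under_swapping(self):
        rt = self.rate_trees(0.15, 0.15, 0.05, 0.05)   # LW=0.3, LH=0.1
        c = compute_contrast(rt, self.pair_tips(), self.defn, self.taxa)
        assert c.ds_contrast == pytest.approx(-2.0)

    def test_extreme_value_excluded(self):
        rt = self.rate_trees(0.005, 0.005, 0.125, 0.125)  # 0.01 vs 0.25
        c = compute_contrast(rt, self.pair_tips(), self.defn, self.taxa)
        assert c.ds_contrast == pytest.approx(24.0)
        assert not c.included

    def test_zero_denominator_excluded(self):
        rt = self.rate_trees(0.0, 0.0, 0.1, 0.1)
        c = compute_contrast(rt, self.pair_tips(), self.defn, self.taxa)
        assert c.ds_contrast is None and not c.included

    def test_no_stem_flag(self):
        rt = self.rate_trees(0.1, 0.1, 0.1, 0.3)
        c = compute_contrast(rt, self.pair_tips(), self.defn, self.taxa,
                             include_stem=False)
        assert c.ds_contrast == pytest.approx(2.0)   # 0.3 vs 0.1, stems ignored


class TestSignTest:
    def test_symmetric_counts_give_one(self):
        assert sign_test(3, 3) == 1.0

    def test_agrees_with_exhaustive_binomial_enumeration(self):
        for n in range(1, 26):
            pmf = [stats.binom.pmf(k, n, 0.5) for k in range(n + 1)]
            for k in range(n + 1):
                # two-sided: sum of outcomes at most as likely as observed
                want = sum(p for p in pmf if p <= pmf[k] + 1e-12)
                assert sign_test(k, n - k) == pytest.approx(min(1, want),
                                                            rel=1e-9)

    def test_zero_pairs_flagged(self):
        with pytest.raises(ValueError):
            sign_test(0, 0)


class TestStudy:
    def clades(self, config, n, rng):
        """Extracted ingroup clades with rate trees."""
        out = []
        for i in range(n):
            fam = simulate_family(config, i, rng)
            if fam.tree is None:
                continue
            for clade in extract_rooted_clades(fam.tree, config.taxa):
                ingroup_taxa = {config.taxa.taxon_of(l)
                                for l in clade.tip_labels()} & \
                    config.taxa.ingroup
                if len(ingroup_taxa) >= 8:
                    out.append((f"fam{i}", assign_branch_lengths(
                        clade, config, rng)))
                    break
        return out

    def test_three_fold_multiplier_gives_positive_signal(self):
        config = SimulationConfig(seed=31, dup_rate=0.0, loss_rate=0.0,
                                  wgd_events=[])
        rng = np.random.default_rng(31)
        clades = self.clades(config, 60, rng)
        report = run_contrast_study(clades, default_contrast_definitions(),
                                    config.taxa, seed=0)
        for row in report.all_pairs:
            if row.label == "A":
                assert row.n_lt > row.n_gt        # herbaceous faster
                assert row.p_value < 1e-6
                assert row.median_contrast > 0.5

    def test_equal_rates_give_no_systematic_sign(self):
        config = SimulationConfig(seed=32, dup_rate=0.0, loss_rate=0.0,
                                  wgd_events=[], ds_herb_multiplier=1.0,
                                  dn_herb_multiplier=1.0)
        rng = np.random.default_rng(32)
        clades = self.clades(config, 60, rng)
        report = run_contrast_study(clades, default_contrast_definitions(),
                                    config.taxa, seed=0)
        for row in report.all_pairs:
            assert row.p_value > 0.001

    def test_small_sets_skip_subsampling(self):
        config = SimulationConfig(seed=33, dup_rate=0.0, loss_rate=0.0,
                                  wgd_events=[])
        rng = np.random.default_rng(33)
        clades = self.clades(config, 10, rng)
        report = run_contrast_study(clades, default_contrast_definitions(),
                                    config.taxa, n_sub=3000, seed=0)
        row = next(r for r in report.all_pairs
                   if r.label == "A" and r.metric == "dS")
        assert row.n_analyzed == len(clades)

    def test_equal_tip_table_subset(self):
        config = SimulationConfig(seed=34, dup_rate=0.1, loss_rate=0.1,
                                  wgd_events=[])
        rng = np.random.default_rng(34)
        clades = self.clades(config, 80, rng)
        report = run_contrast_study(clades, default_contrast_definitions(),
                                    config.taxa, seed=0)
        for eq, al in zip(report.equal_tips, report.all_pairs):
            assert eq.n_analyzed <= al.n_analyzed
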