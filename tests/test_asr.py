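import numpy as np
import pytest
from oracles import brute_force_marginal_posterior

from ancres import (Alignment, SitePosterior, SubstitutionModel, alt_ancestor,
                    ambiguous_sites, marginal_posteriors, pairwise_identity,
                    random_tree, read_newick, reconstruct_ancestor,
                    simulate_alignment)
from ancres.asr import posterior_table
from ancres.substitution import AMINO_ACIDS
from ancres.trees import node_label


def make_posterior(probs, node="N1", site=1):
    p = np.asarray(probs, dtype=float)
    best = int(np.argmax(p))
    return SitePosterior(node=node, site=site, p=p,
                         best_state=AMINO_ACIDS[best], best_pp=float(p[best]))


def spread(best_pp, second_pp, best=0, second=1):
    p = np.full(20, (1.0 - best_pp - second_pp) / 18.0)
    p[best], p[second] = best_pp, second_pp
    return p


class TestMarginalPosteriors:
    def test_matches_brute_force_bayes(self, lg_model_k2):
        tree = read_newick("((A:0.12,B:0.23)N2:0.07,(C:0.31,D:0.05)N3:0.18)N1;",
                           is_path=False)
        aln = Alignment.from_sequences(
            [("A", "MKV"), ("B", "M-V"), ("C", "LKX"), ("D", "AKV")])
        for label in ("N1", "N2", "N3"):
            post = marginal_posteriors(aln, tree, lg_model_k2, node=label)
            for s in range(aln.n_sites):
                expected = brute_force_marginal_posterior(
                    tree, aln, lg_model_k2, label, s)
                assert np.abs(post[s].p - expected).max() < 1e-10

    def test_posteriors_sum_to_one(self, lg_model, four_tip_tree,
                                   small_alignment):
        for label in ("N1", "N2", "N3"):
            post = marginal_posteriors(small_alignment, four_tip_tree,
                                       lg_model, node=label)
            for sp in post:
                assert sp.p.sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_branch_ancestor_equals_tips(self, lg_model):
        tree = read_newick("(A:1e-9,B:1e-9)N1;", is_path=False)
        aln = Alignment.from_sequences([("A", "A"), ("B", "A")])
        post = marginal_posteriors(aln, tree, lg_model, node="N1")
        assert post[0].p[0] > 0.999999

    def test_long_branch_limit_is_pi(self, lg_model):
        tree = read_newick("(A:500.0,B:500.0)N1;", is_path=False)
        aln = Alignment.from_sequences([("A", "W"), ("B", "C")])
        post = marginal_posteriors(aln, tree, lg_model, node="N1")
        assert np.abs(post[0].p - lg_model.pi).max() < 1e-6

    def test_mrca_addressing(self, lg_model, four_tip_tree, small_alignment):
        by_label = marginal_posteriors(small_alignment, four_tip_tree,
                                       lg_model, node="N2")
        by_mrca = marginal_posteriors(small_alignment, four_tip_tree,
                                      lg_model, taxa=["A", "B"])
        assert np.allclose(by_label[0].p, by_mrca[0].p)

    def test_leaf_target_rejected(self, lg_model, four_tip_tree,
                                  small_alignment):
        with pytest.raises(ValueError, match="leaf"):
            marginal_posteriors(small_alignment, four_tip_tree, lg_model,
                                node="A")
        with pytest.raises(ValueError, match="not in tree"):
            marginal_posteriors(small_alignment, four_tip_tree, lg_model,
                                taxa=["A", "ZZZ"])

    def test_branch_scaling_does_not_sharpen(self, lg_model):
        """Multiplying all branch lengths x10 cannot increase mean best PP."""
        model = SubstitutionModel.lg(alpha=0.7)
        short = random_tree(12, seed=5, height=0.4)
        aln, _ = simulate_alignment(short, model, n_sites=300, seed=6)
        long = random_tree(12, seed=5, height=0.4)
        for e in long.preorder_edge_iter():
            if e.length is not None:
                e.length *= 10.0
        root = node_label(short.seed_node)
        pp_short = np.mean([sp.best_pp for sp in
                            marginal_posteriors(aln, short, model, node=root)])
        pp_long = np.mean([sp.best_pp for sp in
                           marginal_posteriors(aln, long, model, node=root)])
        assert pp_long <= pp_short


class TestAmbiguityAndAltAncestor:
    def test_threshold_rule(self):
        ambiguous = ambiguous_sites([make_posterior(spread(0.70, 0.25))])
        assert len(ambiguous) == 1
        assert ambiguous[0].alt_state == AMINO_ACIDS[1]
        assert ambiguous[0].alt_pp == pytest.approx(0.25)
        clear = ambiguous_sites([make_posterior(spread(0.85, 0.15))])
        assert clear == []

    def test_exactly_at_threshold_not_ambiguous(self):
        assert ambiguous_sites([make_posterior(spread(0.80, 0.20))]) == []

    def test_three_states_over_threshold_substitutes_second_best(self):
        p = np.zeros(20)
        p[0], p[1], p[2] = 0.40, 0.35, 0.25
        amb = ambiguous_sites([make_posterior(p)])
        assert len(amb) == 1
        assert amb[0].alt_state == AMINO_ACIDS[1]
        assert [s for s, _ in amb[0].over_threshold] == [AMINO_ACIDS[1],
                                                         AMINO_ACIDS[2]]

    def test_alt_ancestor_substitution(self):
        posts = [make_posterior(spread(0.9, 0.05), site=1),
                 make_posterior(spread(0.6, 0.4, best=10, second=1), site=2),
                 make_posterior(spread(0.95, 0.02, best=17), site=3)]
        rec = reconstruct_ancestor(posts)
        assert rec.ml_sequence == "ALW"
        assert rec.alt_sequence == "ARW"
        changed = sum(a != b for a, b in zip(rec.ml_sequence,
                                             rec.alt_sequence))
        assert changed == len(rec.ambiguous_sites) == 1

    def test_no_ambiguity_alt_equals_ml(self):
        posts = [make_posterior(spread(0.99, 0.005), site=s) for s in (1, 2)]
        rec = reconstruct_ancestor(posts)
        assert rec.alt_sequence == rec.ml_sequence

    def test_alt_ancestor_direct(self):
        from ancres.asr import AmbiguousSite
        amb = [AmbiguousSite(site=2, best_state="K", best_pp=0.6,
                             alt_state="R", alt_pp=0.4)]
        assert alt_ancestor("MKV", amb) == "MRV"


class TestReconstruction:
    def test_overall_pp_is_mean_of_best(self):
        posts = [make_posterior(spread(pp, 0.01), site=i + 1)
                 for i, pp in enumerate([1.0, 0.9, 0.95])]
        rec = reconstruct_ancestor(posts)
        assert rec.overall_pp == pytest.approx(0.95)

    def test_tie_broken_by_alphabet_order(self):
        p = np.zeros(20)
        p[0] = p[19] = 0.5    # A vs V
        post = marginal = make_posterior(p)
        assert marginal.best_state == "A"
        rec = reconstruct_ancestor([post])
        assert rec.ml_sequence == "A"

    def test_present_mask_excludes_sites(self):
        posts = [make_posterior(spread(0.9, 0.05), site=s + 1)
                 for s in range(4)]
        rec = reconstruct_ancestor(posts, present_mask=[True, False, True,
                                                        False])
        assert len(rec.ml_sequence) == 2
        assert rec.present_sites == [1, 3]
        with pytest.raises(ValueError, match="present"):
            reconstruct_ancestor(posts, present_mask=[False] * 4)

    def test_posterior_calibration_on_truth(self):
        """Mean best-state PP tracks the actual recovery frequency."""
        model = SubstitutionModel.lg(alpha=0.7)
        tree = random_tree(16, seed=3, height=0.5)
        aln, truth = simulate_alignment(tree, model, n_sites=500, seed=4)
        root = node_label(tree.seed_node)
        post = marginal_posteriors(aln, tree, model, node=root)
        true_seq = truth.node_sequences[root]
        recovery = np.mean([sp.best_state == true_seq[i]
                            for i, sp in enumerate(post)])
        mean_pp = np.mean([sp.best_pp for sp in post])
        assert abs(mean_pp - recovery) < 0.05


class TestPairwiseIdentity:
    @pytest.mark.parametrize("n_cols, n_diff, expected", [
        (531, 54, 89.8),     # typical reconstructed-vs-extant bookkeeping
        (559, 57, 89.8),
        (100, 0, 100.0),
    ])
    def test_bookkeeping(self, n_cols, n_diff, expected):
        a = "A" * n_cols
        b = "R" * n_diff + "A" * (n_cols - n_diff)
        pct, changes, cols = pairwise_identity(a, b)
        assert (pct, changes, cols) == (expected, n_diff, n_cols)

    def test_gap_handling(self):
        # both-gap column skipped; gap vs residue counts as a change
        pct, changes, cols = pairwise_identity("MK-V-", "ML-VA")
        assert cols == 4
        assert changes == 2
        assert pct == 50.0

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_identity("MK", "MKV")


def test_posterior_table_schema(lg_model, four_tip_tree, small_alignment):
    post = marginal_posteriors(small_alignment, four_tip_tree, lg_model,
                               node="N2")
    table = posterior_table(post)
    assert list(table.columns[:2]) == ["node", "site"]
    assert set(AMINO_ACIDS) <= set(table.columns)
    assert len(table) == small_alignment.n_sites
    assert table[list(AMINO_ACIDS)].sum(axis=1).round(6).eq(1.0).all()
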