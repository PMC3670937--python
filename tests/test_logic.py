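"""Logic trees, moves, scoring and the annealing/exhaustive searches."""

import numpy as np
import pytest

from epilogic.logic import (AND, OR, AnnealSchedule, Leaf, LogicTree, Node,
                            anneal_fit, binarize_genotypes, covariate_matrix,
                            evaluate_tree, exhaustive_fit, model_score,
                            null_deviance, parse_tree, propose_move)

from conftest import hwe_genotypes, make_cohort


def all_binary_inputs(p):
    codes = np.arange(2**p)
    return ((codes[:, None] >> np.arange(p)) & 1).astype(np.uint8)


class TestBinarize:
    def test_coding_rules(self):
        g = np.array([[0], [1], [2]], dtype=np.int8)
        data = make_cohort(g, [1, 0, 0])
        dom, rec = binarize_genotypes(data)
        assert dom.values.tolist() == [0, 1, 1]
        assert rec.values.tolist() == [0, 0, 1]
        assert dom.name.endswith("_dom") and rec.name.endswith("_rec")

    def test_two_covariates_per_snp(self, rng):
        g = hwe_genotypes(rng, 30, [0.3] * 17)
        y = np.r_[np.ones(15, dtype=np.int8), np.zeros(15, dtype=np.int8)]
        covs = binarize_genotypes(make_cohort(g, y))
        assert len(covs) == 34

    def test_recessive_implies_dominant(self, rng):
        g = hwe_genotypes(rng, 500, [0.2, 0.4])
        y = np.r_[np.ones(250, dtype=np.int8), np.zeros(250, dtype=np.int8)]
        X, _ = covariate_matrix(binarize_genotypes(make_cohort(g, y)))
        for j in range(0, X.shape[1], 2):
            assert not np.any((X[:, j] == 0) & (X[:, j + 1] == 1))

    def test_missing_genotype_directs_to_filter(self):
        from epilogic.datasets import MISSING

        g = np.array([[0], [MISSING]], dtype=np.int8)
        with pytest.raises(ValueError, match="complete_case_filter"):
            binarize_genotypes(make_cohort(g, [1, 0]))


class TestTreeEvaluation:
    def test_published_tree_on_single_subject(self):
        # (rec1 OR rec2) AND rec3 on dosages (1, 2, 2) -> (0 or 1) and 1 -> 1
        g = np.array([[1, 2, 2]], dtype=np.int8)
        data = make_cohort(np.vstack([g, [[0, 0, 0]]]), [1, 0])
        X, names = covariate_matrix(binarize_genotypes(data))
        tree = parse_tree(f"AND(OR({names[1]}, {names[3]}), {names[5]})", names)
        assert tree.evaluate(X)[0] == 1
        assert tree.evaluate(X)[1] == 0

    def test_single_leaf_identity(self):
        X = all_binary_inputs(3)
        t = LogicTree(Leaf(1))
        np.testing.assert_array_equal(t.evaluate(X), X[:, 1].astype(bool))

    def test_de_morgan_exhaustive(self):
        X = all_binary_inputs(2)
        not_and = LogicTree(Node(OR, Leaf(0, True), Leaf(1, True)))
        and_tree = LogicTree(Node(AND, Leaf(0), Leaf(1)))
        np.testing.assert_array_equal(not_and.evaluate(X), ~and_tree.evaluate(X))

    def test_parse_round_trip(self):
        names = ["a_dom", "a_rec", "b_dom", "b_rec"]
        s = "AND(OR(a_dom, NOT(b_rec)), a_rec)"
        tree = parse_tree(s, names)
        assert tree.to_string(names) == s
        assert tree.n_leaves == 3


class TestModelScore:
    def test_null_deviance_closed_form(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        assert null_deviance(y) == pytest.approx(100 * 2 * np.log(2), rel=1e-12)
        assert null_deviance(y) == pytest.approx(138.629, abs=1e-3)

    def test_perfect_separation_deviance_near_zero(self):
        X = np.r_[np.ones((40, 1)), np.zeros((60, 1))].astype(np.uint8)
        y = np.r_[np.ones(40), np.zeros(60)]
        score = model_score([LogicTree(Leaf(0))], X, y)
        assert score < 1e-6

    def test_matches_subject_level_irls(self, rng):
        from epilogic.epistasis import fit_logistic_irls

        X = (rng.random((300, 4)) < 0.4).astype(np.uint8)
        y = (rng.random(300) < 0.45).astype(float)
        trees = [LogicTree(Node(OR, Leaf(0), Leaf(2))), LogicTree(Leaf(3))]
        outs = np.column_stack([t.evaluate(X) for t in trees]).astype(float)
        ref = fit_logistic_irls(np.column_stack([np.ones(300), outs]), y)
        assert model_score(trees, X, y) == pytest.approx(ref.deviance, abs=1e-9)

    def test_invariant_under_de_morgan_rewrite(self, rng):
        X = (rng.random((200, 5)) < 0.5).astype(np.uint8)
        y = (rng.random(200) < 0.4).astype(float)
        t1 = LogicTree(Node(AND, Leaf(0), Leaf(3)))
        t2 = LogicTree(Node(OR, Leaf(0, True), Leaf(3, True)))  # NOT of t1
        # complementing the tree output flips the coefficient sign but not fit
        assert model_score([t1], X, y) == pytest.approx(model_score([t2], X, y), abs=1e-9)

    def test_operand_swap_invariance(self, rng):
        X = (rng.random((150, 4)) < 0.5).astype(np.uint8)
        y = (rng.random(150) < 0.5).astype(float)
        a = LogicTree(Node(OR, Leaf(1), Leaf(2)))
        b = LogicTree(Node(OR, Leaf(2), Leaf(1)))
        assert model_score([a], X, y) == model_score([b], X, y)


class TestMoves:
    def test_single_leaf_inadmissible_moves(self, rng):
        # one tree, one leaf: delete-leaf and prune-branch are inadmissible;
        # all proposals keep >= 1 leaf
        trees = [LogicTree(Leaf(0))]
        g = np.random.default_rng(0)
        for _ in range(200):
            new, ok = propose_move(trees, g, max_total_leaves=2, n_covariates=4)
            assert ok
            assert sum(t.n_leaves for t in new) >= 1

    def test_every_neighbor_is_one_edit(self):
        g = np.random.default_rng(1)
        trees = [LogicTree(Node(AND, Node(OR, Leaf(0), Leaf(1)), Leaf(2))),
                 LogicTree(Leaf(3))]
        base_leaves = sum(t.n_leaves for t in trees)
        for _ in range(2000):
            new, ok = propose_move(trees, g, max_total_leaves=6, n_covariates=6)
            assert ok
            d = sum(t.n_leaves for t in new) - base_leaves
            assert d in (-2, -1, 0, 1)  # prune can drop a 2-leaf branch

    def test_leaf_budget_respected(self):
        g = np.random.default_rng(2)
        trees = [LogicTree(Leaf(0)), LogicTree(Leaf(1))]
        max_leaves = 4
        for _ in range(5000):
            trees, ok = propose_move(trees, g, max_total_leaves=max_leaves, n_covariates=6)
            assert sum(t.n_leaves for t in trees) <= max_leaves
            assert len(trees) == 2

    def test_no_move_mutates_parent(self):
        g = np.random.default_rng(3)
        trees = [LogicTree(Node(OR, Leaf(0), Leaf(1)))]
        s = trees[0].to_string()
        for _ in range(300):
            propose_move(trees, g, max_total_leaves=3, n_covariates=4)
            assert trees[0].to_string() == s


class TestExhaustive:
    def test_single_covariate_single_leaf(self):
        X = np.r_[np.ones((30, 1)), np.zeros((70, 1))].astype(np.uint8)
        y = np.r_[np.ones(25), np.zeros(5), np.ones(10), np.zeros(60)]
        model = exhaustive_fit(X, y, 1, 1)
        assert model.trees[0].n_leaves == 1
        out = model.trees[0].evaluate(X)
        # best single split is the covariate itself (or its complement)
        assert (out == X[:, 0].astype(bool)).all() or (out == ~X[:, 0].astype(bool)).all()

    def test_perfect_predictor_recovered(self, rng):
        X = (rng.random((100, 5)) < 0.5).astype(np.uint8)
        y = X[:, 3].astype(float)
        model = exhaustive_fit(X, y, 1, 3)
        np.testing.assert_array_equal(model.trees[0].evaluate(X), X[:, 3].astype(bool))
        assert model.score < 1e-6

    def test_agrees_with_rescoring(self, rng):
        from epilogic.logic import _enumerate_trees

        X = (rng.random((60, 3)) < 0.5).astype(np.uint8)
        y = (rng.random(60) < 0.5).astype(float)
        best = exhaustive_fit(X, y, 1, 2)
        brute = min(model_score([t], X, y)
                    for t in _enumerate_trees(3, 2))
        assert best.score == pytest.approx(brute, abs=1e-9)


class TestAnneal:
    def test_zero_iterations_returns_initial_single_leaves(self, rng):
        X = (rng.random((80, 4)) < 0.5).astype(np.uint8)
        y = (rng.random(80) < 0.5).astype(float)
        model = anneal_fit(X, y, n_trees=2, max_total_leaves=5,
                           schedule=AnnealSchedule(n_iterations=0), seed=0)
        assert model.n_trees == 2
        assert model.total_leaves == 2

    def test_reproducible_given_seed(self, rng):
        X = (rng.random((150, 6)) < 0.4).astype(np.uint8)
        y = (rng.random(150) < 0.4).astype(float)
        sched = AnnealSchedule(n_iterations=500)
        m1 = anneal_fit(X, y, 1, 3, sched, seed=42)
        m2 = anneal_fit(X, y, 1, 3, sched, seed=42)
        assert m1.score == m2.score
        assert m1.to_string() == m2.to_string()

    def test_matches_exhaustive_on_small_instance(self):
        rng = np.random.default_rng(7)
        X = (rng.random((200, 6)) < 0.4).astype(np.uint8)
        eta = -0.5 + 1.3 * ((X[:, 0] | X[:, 2]) & (1 - X[:, 4]))
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        oracle = exhaustive_fit(X, y, 1, 3)
        best = min(anneal_fit(X, y, 1, 3, AnnealSchedule(n_iterations=3000), seed=s).score
                   for s in range(5))
        assert best == pytest.approx(oracle.score, abs=1e-9)

    def test_score_monotone_in_leaf_budget(self):
        # larger search space cannot do worse (verified via exhaustive oracle)
        rng = np.random.default_rng(11)
        X = (rng.random((150, 4)) < 0.5).astype(np.uint8)
        y = (rng.random(150) < 0.45).astype(float)
        scores = [exhaustive_fit(X, y, 1, L).score for L in (1, 2, 3)]
        assert scores[0] >= scores[1] >= scores[2]
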