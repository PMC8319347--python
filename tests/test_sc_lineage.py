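"""Mutation-matrix construction, tree likelihood and ML search."""

import math

import numpy as np
import pandas as pd
import pytest

from syntrophevo.sc_lineage import (
    MutationMatrix,
    MutationTree,
    build_mutation_matrix,
    infer_ml_tree,
    order_trunk_by_generations,
    tree_loglikelihood,
)
from syntrophevo.synthetic_data import random_mutation_tree, simulate_single_cells
from syntrophevo.trajectory_stats import EvolutionLine, TrajectorySample

FD, AD = 6.04e-5, 0.21545


from _oracles import oracle_best_trees, oracle_loglik

# ---------------------------------------------------------------------------


class TestBuildMatrix:
    def records(self):
        rows = []
        # 4 cells x 1 site: frequencies (0.85, 0.90, 0.10, coverage 3)
        for cell, cov, freq in (
            ("c1", 20, 0.85), ("c2", 15, 0.90), ("c3", 30, 0.10), ("c4", 3, 0.95),
        ):
            rows.append({"cell": cell, "mutation": "m1", "coverage": cov,
                         "frequency": freq})
        return pd.DataFrame(rows)

    def test_state_rules(self):
        matrix = build_mutation_matrix(self.records())
        assert matrix.mutations == ("m1",)
        assert matrix.states[:, 0].tolist() == [1, 1, 0, 3]

    def test_low_coverage_is_missing(self):
        matrix = build_mutation_matrix(self.records(), min_coverage=8)
        assert matrix.states[3, 0] == 3

    def test_singleton_column_dropped(self):
        df = pd.DataFrame(
            [
                {"cell": "c1", "mutation": "m1", "coverage": 20, "frequency": 0.9},
                {"cell": "c2", "mutation": "m1", "coverage": 20, "frequency": 0.1},
            ]
        )
        matrix = build_mutation_matrix(df)
        assert matrix.mutations == ()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_mutation_matrix(pd.DataFrame())


class TestLikelihood:
    def chain_tree(self, m, labels=None):
        return MutationTree(
            parents=tuple([m] + list(range(m - 1))),
            labels=tuple(labels or (f"M{i}" for i in range(m))),
        )

    def test_noiseless_exact_genotypes_have_loglik_zero(self):
        tree = self.chain_tree(3)
        A = tree.ancestor_matrix()
        matrix = MutationMatrix(
            cells=tuple(f"c{i}" for i in range(4)),
            mutations=tree.labels,
            states=A.astype(np.int8),
            fd=0.0,
            ad=0.0,
        )
        assert tree_loglikelihood(tree, matrix) == pytest.approx(0.0, abs=1e-9)

    def test_single_mutation_single_cell_closed_form(self):
        """Cell observes 1; best attachment gives max(fd, 1-ad) = 0.78455."""
        tree = self.chain_tree(1)
        matrix = MutationMatrix(("c0",), ("M0",), np.array([[1]]), fd=FD, ad=AD)
        expected = math.log(max(FD, 1 - AD))
        assert tree_loglikelihood(tree, matrix, "max") == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-0.242645, abs=1e-6)

    def test_all_missing_is_uninformative(self):
        for parents in [(2, 0), (2, 1), (1, 2)]:
            if parents == (2, 1):
                continue
            tree = MutationTree(parents=parents, labels=("a", "b"))
            matrix = MutationMatrix(
                ("c0", "c1"), ("a", "b"), np.full((2, 2), 3), fd=FD, ad=AD
            )
            assert tree_loglikelihood(tree, matrix) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("attachment", ["max", "sum"])
    def test_matches_bruteforce_oracle(self, attachment):
        rng = np.random.default_rng(0)
        for seed in range(5):
            tree = random_mutation_tree(4, seed=seed)
            matrix, _ = simulate_single_cells(tree, 12, fd=0.01, ad=0.2,
                                              missing_rate=0.1, seed=seed)
            mine = tree_loglikelihood(tree, matrix, attachment)
            ref = oracle_loglik(tree.parents, matrix.states, 0.01, 0.2, attachment)
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_invariance_under_cell_and_column_permutation(self):
        tree = random_mutation_tree(4, seed=3)
        matrix, _ = simulate_single_cells(tree, 20, fd=0.01, ad=0.2, seed=3)
        ll = tree_loglikelihood(tree, matrix)
        rng = np.random.default_rng(1)
        rows = rng.permutation(matrix.n_cells)
        cols = rng.permutation(matrix.n_mutations)
        shuffled = MutationMatrix(
            cells=tuple(matrix.cells[i] for i in rows),
            mutations=tuple(matrix.mutations[j] for j in cols),
            states=matrix.states[np.ix_(rows, cols)],
            fd=matrix.fd,
            ad=matrix.ad,
        )
        assert tree_loglikelihood(tree, shuffled) == pytest.approx(ll, rel=1e-12)

    def test_label_mismatch_errors(self):
        tree = self.chain_tree(2)
        matrix = MutationMatrix(("c",), ("x", "y"), np.array([[0, 1]]), fd=FD, ad=AD)
        with pytest.raises(ValueError):
            tree_loglikelihood(tree, matrix)


class TestInference:
    def test_noiseless_chain_recovered(self):
        tree = MutationTree(parents=(4, 0, 1, 2), labels=("a", "b", "c", "d"))
        matrix, _ = simulate_single_cells(tree, 40, fd=0.0, ad=0.0, seed=2)
        found, ll = infer_ml_tree(matrix, search="exhaustive")
        assert found.parents == tree.parents

    def test_exhaustive_matches_bruteforce_optimum(self):
        for seed in range(6):
            tree = random_mutation_tree(4, seed=100 + seed)
            matrix, _ = simulate_single_cells(tree, 25, fd=FD, ad=AD,
                                              missing_rate=0.05, seed=seed)
            found, ll = infer_ml_tree(matrix, search="exhaustive")
            ref_ll, ref_best = oracle_best_trees(matrix.states, FD, AD)
            assert ll == pytest.approx(ref_ll, rel=1e-9)
            assert found.parents == ref_best[0]  # lexicographic tie-break

    def test_mcmc_reaches_exhaustive_optimum(self):
        tree = random_mutation_tree(5, seed=9)
        matrix, _ = simulate_single_cells(tree, 60, fd=FD, ad=AD, seed=9)
        _, ll_ex = infer_ml_tree(matrix, search="exhaustive")
        _, ll_mc = infer_ml_tree(matrix, search="mcmc", seed=4, chain_length=3000)
        assert ll_mc == pytest.approx(ll_ex, rel=1e-9)

    def test_mcmc_never_exceeds_exhaustive(self):
        tree = random_mutation_tree(4, seed=21)
        matrix, _ = simulate_single_cells(tree, 30, fd=FD, ad=AD, seed=21)
        _, ll_ex = infer_ml_tree(matrix, search="exhaustive")
        _, ll_mc = infer_ml_tree(matrix, search="mcmc", seed=1, chain_length=500)
        assert ll_mc <= ll_ex + 1e-9

    def test_identical_columns_tie_flagged_lexicographic(self):
        """Two mutations with identical cell sets admit both chain orders."""
        states = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        matrix = MutationMatrix(
            ("c0", "c1", "c2", "c3"), ("a", "b"), states, fd=0.01, ad=0.1
        )
        found, ll = infer_ml_tree(matrix, search="exhaustive")
        assert "likelihood_tie" in found.flags
        assert found.ties == (("a", "b"),)
        ref_ll, ref_best = oracle_best_trees(states, 0.01, 0.1)
        assert found.parents == ref_best[0]

    def test_zero_mutations_errors(self):
        matrix = MutationMatrix(("c",), (), np.zeros((1, 0)), fd=FD, ad=AD)
        with pytest.raises(ValueError):
            infer_ml_tree(matrix)


class TestTrunkOrdering:
    def tied_tree(self):
        return MutationTree(
            parents=(2, 0), labels=("a", "b"), ties=(("a", "b"),),
            flags=("likelihood_tie",),
        )

    def bulk_line(self, first_gen):
        gens = (100, 300, 500, 780, 1000)
        samples = []
        for g in gens:
            freqs = {}
            if g >= first_gen["a"]:
                freqs["a"] = 0.5
            if g >= first_gen["b"]:
                freqs["b"] = 0.5
            samples.append(TrajectorySample("UE3", g, freqs))
        return EvolutionLine("UE3", "Dv", samples)

    def test_earlier_detection_goes_first(self):
        line = self.bulk_line({"a": 500, "b": 300})
        out = order_trunk_by_generations(self.tied_tree(), line)
        # b (gen 300) should now precede a (gen 500)
        assert out.parents == (1, 2)
        assert any(f.startswith("reordered") for f in out.flags)

    def test_already_ordered_unchanged(self):
        line = self.bulk_line({"a": 300, "b": 500})
        out = order_trunk_by_generations(self.tied_tree(), line)
        assert out.parents == (2, 0)

    def test_no_ties_identity(self):
        tree = MutationTree(parents=(2, 0), labels=("a", "b"))
        line = self.bulk_line({"a": 500, "b": 300})
        out = order_trunk_by_generations(tree, line)
        assert out.parents == tree.parents

    def test_absent_mutation_flagged_rare(self):
        line = self.bulk_line({"a": 300, "b": 10_000})  # b never detected
        out = order_trunk_by_generations(self.tied_tree(), line)
        assert out.parents == (2, 0)
        assert any("rare/below-detection" in f for f in out.flags)


def test_matrix_csv_roundtrip(tmp_path):
    tree = random_mutation_tree(3, seed=5)
    matrix, _ = simulate_single_cells(tree, 10, fd=FD, ad=AD,
                                      missing_rate=0.2, seed=5)
    path = tmp_path / "m.csv"
    matrix.to_csv(path)
    back = MutationMatrix.from_csv(path, fd=FD, ad=AD)
    assert back.cells == matrix.cells
    assert back.mutations == matrix.mutations
    np.testing.assert_array_equal(back.states, matrix.states)


def test_newick_export_contains_all_labels():
    tree = MutationTree(parents=(4, 0, 1, 2), labels=("a", "b", "c", "d"))
    nwk = tree.to_newick()
    for lbl in tree.labels:
        assert lbl in nwk
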