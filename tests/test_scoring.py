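"""Sufficient statistics, closed-form likelihoods and BIC decomposability."""

from __future__ import annotations

import itertools
from math import log

import numpy as np
import pytest

from dbngrn import (
    PREV,
    SAME,
    TwoSliceStructure,
    ValidationError,
    bic_initial,
    bic_total,
    bic_transition,
    count_initial,
    count_transition,
    family_bic,
    family_dim,
    family_loglik,
)
from dbngrn.scoring import initial_family_score, transition_family_score

from conftest import make_dataset, simulate_discrete_dbn


def single_gene_dataset():
    """One binary gene; slice-0 values {0,0,1,1} and next-values {0,0,1,1}."""
    return make_dataset(
        [[[0, ], [0]], [[0], [0]], [[1], [1]], [[1], [1]]], arities=[2], genes=["g"]
    )


class TestCounting:
    def test_initial_empty_parent_tally(self):
        ds = single_gene_dataset()
        c = count_initial(ds, "g")
        np.testing.assert_array_equal(c.table, [[2, 2]])
        assert c.total == 4

    def test_initial_one_parent_all_cells(self):
        seqs = [[[p, ch], [0, 0]] for p, ch in [(0, 0), (0, 1), (1, 0), (1, 1)]]
        ds = make_dataset(seqs, arities=[2, 2], genes=["p", "c"])
        c = count_initial(ds, "c", ["p"])
        np.testing.assert_array_equal(c.table, [[1, 1], [1, 1]])

    def test_initial_totals_always_n_seq(self, rng):
        seqs = [rng.integers(0, 3, size=(4, 4)) for _ in range(10)]
        ds = make_dataset(seqs, arities=[3] * 4)
        for k in range(3):
            for parents in itertools.combinations([g for g in ds.genes if g != "g0"], k):
                assert count_initial(ds, "g0", parents).total == 10

    def test_transition_copy_diagonal(self):
        # x[t+1] == x[t] throughout: all 4 transitions land on the diagonal
        seq = np.array([[1], [1], [1], [1], [1]])
        ds = make_dataset([seq], arities=[2], genes=["x"])
        c = count_transition(ds, "x", [("x", PREV)])
        assert c.table[0, 0] + c.table[1, 1] == 4
        assert c.total == 4

    def test_transition_empty_parent_marginal(self):
        seq = np.array([[0], [1], [1], [0], [1]])
        ds = make_dataset([seq], arities=[2], genes=["x"])
        c = count_transition(ds, "x")
        np.testing.assert_array_equal(c.table, [[1, 3]])

    def test_transition_pooling_across_sequences(self, rng):
        seqs = [rng.integers(0, 2, size=(3, 2)), rng.integers(0, 2, size=(5, 2))]
        ds = make_dataset(seqs, arities=[2, 2])
        c = count_transition(ds, "g0", [("g1", PREV)])
        assert c.total == 2 + 4 == ds.n_transitions

    def test_same_tagged_child_rejected(self, rng):
        ds = make_dataset([rng.integers(0, 2, size=(4, 2))], arities=[2, 2])
        with pytest.raises(ValidationError, match="SAME"):
            count_transition(ds, "g0", [("g0", SAME)])

    def test_unknown_gene_rejected(self, rng):
        ds = make_dataset([rng.integers(0, 2, size=(4, 2))], arities=[2, 2])
        with pytest.raises(ValidationError, match="unknown gene"):
            count_initial(ds, "nope")


class TestFamilyScores:
    def test_loglik_balanced_binary(self):
        c = count_initial(single_gene_dataset(), "g")
        assert family_loglik(c) == pytest.approx(4 * log(0.5), abs=1e-9)

    def test_loglik_three_one(self):
        ds = make_dataset([[[0], [0]], [[0], [0]], [[0], [0]], [[1], [1]]], arities=[2])
        c = count_initial(ds, "g0")
        assert family_loglik(c) == pytest.approx(-2.2493406, abs=1e-6)

    def test_deterministic_family_loglik_exactly_zero(self):
        # child equals its parent in every observation
        seqs = [[[v, v], [0, 0]] for v in (0, 1, 0, 1)]
        ds = make_dataset(seqs, arities=[2, 2], genes=["p", "c"])
        c = count_initial(ds, "c", ["p"])
        assert family_loglik(c) == 0.0

    def test_family_bic_closed_forms(self):
        c = count_initial(single_gene_dataset(), "g")
        s = family_bic(c, m=4)
        assert s.dim == 1
        assert s.penalized == pytest.approx(-3.4657359, abs=1e-6)

        # deterministic binary child with one binary parent, M=100
        seqs = [[[v, v], [0, 0]] for v in (0, 1, 0, 1)]
        ds = make_dataset(seqs, arities=[2, 2], genes=["p", "c"])
        det = count_initial(ds, "c", ["p"])
        s = family_bic(det, m=100)
        assert s.loglik == 0.0 and s.dim == 2
        assert s.penalized == pytest.approx(-4.6051702, abs=1e-6)

    def test_family_dim_formula(self):
        assert family_dim(3, [3, 3]) == 18
        assert family_dim(2, []) == 1

    def test_penalized_never_exceeds_loglik(self, rng):
        ds = make_dataset([rng.integers(0, 3, size=(6, 3)) for _ in range(4)], arities=[3] * 3)
        for parents in ([], [("g1", PREV)], [("g1", PREV), ("g2", SAME)]):
            s = transition_family_score(ds, "g0", parents)
            assert s.penalized <= s.loglik
            assert s.loglik <= 1e-12  # likelihood never positive


class TestBicStructureScores:
    def test_empty_structure_single_gene_closed_form(self):
        ds = single_gene_dataset()
        s = TwoSliceStructure.empty(["g"])
        assert bic_initial(s, ds) == pytest.approx(-3.4657359, abs=1e-6)
        assert bic_transition(s, ds) == pytest.approx(-3.4657359, abs=1e-6)
        assert bic_total(s, ds) == pytest.approx(-6.9314718, abs=1e-6)

    def _random_structure(self, genes, rng):
        s = TwoSliceStructure.empty(genes)
        order = list(genes)
        for i, g in enumerate(order):
            for p in order[:i]:
                if rng.random() < 0.3:
                    s.b0_parents[g].add(p)
            for p in order:
                if rng.random() < 0.2:
                    s.trans_parents[g].add((p, PREV))
            for p in order[:i]:
                if rng.random() < 0.15:
                    s.trans_parents[g].add((p, SAME))
        s.validate()
        return s

    def test_decomposability_on_random_structures(self, rng):
        """Total BIC equals BIC0 + BIC-> and the per-family sum, to 1e-12."""
        for trial in range(100):
            ds = make_dataset(
                [rng.integers(0, 3, size=(5, 5)) for _ in range(3)], arities=[3] * 5
            )
            s = self._random_structure(ds.genes, rng)
            b0, bt = bic_initial(s, ds), bic_transition(s, ds)
            per_family = sum(
                initial_family_score(ds, g, sorted(s.b0_parents[g])).penalized
                for g in ds.genes
            ) + sum(
                transition_family_score(ds, g, sorted(s.trans_parents[g])).penalized
                for g in ds.genes
            )
            assert abs(bic_total(s, ds) - (b0 + bt)) < 1e-12
            assert bic_total(s, ds) == pytest.approx(per_family, abs=1e-9)

    def test_score_invariant_under_reordering(self, rng):
        seqs = [rng.integers(0, 2, size=(6, 3)) for _ in range(4)]
        ds = make_dataset(seqs, arities=[2] * 3)
        s = self._random_structure(ds.genes, rng)
        total = bic_total(s, ds)
        # permute gene columns and sequence order consistently
        perm = [2, 0, 1]
        ds2 = make_dataset(
            [seq[:, perm] for seq in reversed(seqs)],
            arities=[2] * 3,
            genes=[ds.genes[i] for i in perm],
        )
        assert bic_total(s, ds2) == pytest.approx(total, abs=1e-9)


class TestLargeSampleBehavior:
    def test_independent_parent_decreases_transition_bic(self, rng):
        """On a large sample, a jointly independent extra parent only pays penalty."""
        genes = ["x", "y", "z"]
        cpts = {
            "x": np.array([[0.5, 0.5]]),
            "z": np.array([[0.5, 0.5]]),
            "y": np.array([[0.9, 0.1], [0.1, 0.9]]),
        }
        ds = simulate_discrete_dbn(
            genes, [2] * 3, {"x": [], "z": [], "y": ["x"]}, cpts, 1, 10000, rng
        )
        with_parent = transition_family_score(ds, "y", [("x", PREV)]).penalized
        with_extra = transition_family_score(ds, "y", [("x", PREV), ("z", PREV)]).penalized
        assert with_extra < with_parent

    def test_true_parent_set_wins_with_growing_sample(self):
        """The true single-parent family beats its sub/supersets increasingly often."""
        freqs = []
        for n in (50, 500, 5000):
            wins = 0
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                cpts = {
                    "x": np.array([[0.5, 0.5]]),
                    "z": np.array([[0.5, 0.5]]),
                    "y": np.array([[0.95, 0.05], [0.05, 0.95]]),
                }
                ds = simulate_discrete_dbn(
                    ["x", "y", "z"], [2] * 3,
                    {"x": [], "z": [], "y": ["x"]}, cpts, 1, n, rng,
                )
                true_s = transition_family_score(ds, "y", [("x", PREV)]).penalized
                sub = transition_family_score(ds, "y", []).penalized
                sup = transition_family_score(ds, "y", [("x", PREV), ("z", PREV)]).penalized
                wins += true_s > sub and true_s > sup
            freqs.append(wins / 20)
        assert all(b >= a for a, b in zip(freqs, freqs[1:]))
        assert freqs[-1] == 1.0
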