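"""Supermatrix handling, NJ, pruning likelihood, placement, bootstrap."""

import itertools
import math

import numpy as np
import pytest

from baculokit.phylogeny import (
    AMINO_ACIDS,
    Supermatrix,
    TreeNode,
    bootstrap_support,
    concatenate,
    constrained_topology_compare,
    graft_sister,
    jtt_model,
    nj_tree,
    optimize_branch_lengths,
    poisson_model,
    protein_distance,
    reroot_adjacent_to_leaf,
    simulate_alignment,
    tree_lnL,
)
from baculokit.phylogeny import _bipartitions


def _leaf(name, length):
    t = TreeNode(name=name)
    t.length = length
    return t


def _four_leaf_tree():
    ab = TreeNode()
    ab.length = 0.3
    ab.add(_leaf("A", 0.1))
    ab.add(_leaf("B", 0.2))
    root = TreeNode()
    root.add(ab)
    root.add(_leaf("C", 0.25))
    root.add(_leaf("D", 0.15))
    return root


class TestConcatenate:
    def test_additivity_and_partitions(self):
        genes = {
            "g1": {"A": "MK", "B": "MR", "C": "MK", "D": "MK"},
            "g2": {"A": "LLL", "B": "LLI", "C": "LII", "D": "LLL"},
        }
        sm = concatenate(genes)
        assert sm.n_sites == 5
        assert sm.partitions == [("g1", 0, 2), ("g2", 2, 5)]
        # partitions re-split reproduce the inputs
        assert sm.gene_alignment("g1") == genes["g1"]
        assert sm.gene_alignment("g2") == genes["g2"]

    def test_pad_policy_gap_fills_missing_taxon(self):
        genes = {"g1": {"A": "MK", "B": "MR"}, "g2": {"A": "LL"}}
        sm = concatenate(genes, missing_policy="pad")
        assert sm.rows["B"] == "MR--"

    def test_intersect_policy_drops_missing_taxon(self):
        genes = {"g1": {"A": "MK", "B": "MR"}, "g2": {"A": "LL"}}
        sm = concatenate(genes, missing_policy="intersect")
        assert sm.taxa == ["A"]

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            concatenate({"g1": [("A", "MK"), ("A", "MR")]})


class TestDistances:
    def test_identical_rows_zero(self):
        sm = Supermatrix(taxa=["A", "B"], rows={"A": "MKLV", "B": "MKLV"})
        _, D = protein_distance(sm)
        assert D[0, 1] == 0.0

    def test_half_different_gives_ln2(self):
        sm = Supermatrix(taxa=["A", "B"], rows={"A": "MKLV", "B": "MKII"})
        _, D = protein_distance(sm)
        assert D[0, 1] == pytest.approx(math.log(2))

    def test_gap_columns_excluded(self):
        sm = Supermatrix(taxa=["A", "B"], rows={"A": "MK-V", "B": "MKL-"})
        _, D = protein_distance(sm)
        assert D[0, 1] == 0.0  # only the first two columns compare

    def test_recovers_simulated_distance(self):
        model = poisson_model()
        two = TreeNode()
        two.add(_leaf("A", 0.15))
        two.add(_leaf("B", 0.15))
        ests = []
        for rep in range(100):
            aln = simulate_alignment(two, model, 500, seed=rep)
            sm = Supermatrix(taxa=["A", "B"], rows=aln)
            _, D = protein_distance(sm)
            ests.append(D[0, 1])
        # Poisson correction assumes 19/20 multiple-hit acceptance; on 20
        # states the expected p at t=0.3 is (19/20)(1-exp(-20t/19))
        t = 0.3
        expected_p = (19 / 20) * (1 - math.exp(-20 * t / 19))
        expected_d = -math.log(1 - expected_p)
        se = np.std(ests) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - expected_d) < 3 * max(se, 1e-3)


class TestNeighborJoining:
    def test_additive_matrix_exact_recovery(self):
        # tree ((A:2,B:3):1,C:4,D:5) gives additive distances
        names = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        t = nj_tree(D, names)
        assert _bipartitions(t, "A") == {frozenset({"C", "D"})}
        # branch lengths recovered from additivity
        lengths = {}
        for n in t.postorder():
            if n.is_leaf:
                lengths[n.name] = n.length
        assert lengths["C"] == pytest.approx(4)
        assert lengths["D"] == pytest.approx(5)

    def test_three_taxa_deterministic(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        t = nj_tree(D, ["A", "B", "C"])
        assert sorted(t.leaf_names()) == ["A", "B", "C"]
        for c in t.children:
            assert c.length == pytest.approx(1)

    def test_fewer_than_three_warns(self):
        with pytest.warns(UserWarning):
            t = nj_tree(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])
        assert sorted(t.leaf_names()) == ["A", "B"]

    def test_simulated_supermatrix_recovery(self):
        model = poisson_model()
        A = TreeNode(); A.length = 0.15; A.add(_leaf("t1", 0.1)); A.add(_leaf("t2", 0.12))
        B = TreeNode(); B.length = 0.1; B.add(_leaf("t3", 0.11)); B.add(_leaf("t4", 0.09))
        C = TreeNode(); C.length = 0.2; C.add(A); C.add(B)
        root = TreeNode(); root.add(C); root.add(_leaf("t5", 0.3)); root.add(_leaf("t6", 0.25))
        true_bp = _bipartitions(root, "t1")
        hits = 0
        for rep in range(50):
            aln = simulate_alignment(root, model, 2000, seed=rep)
            sm = Supermatrix(taxa=list(aln), rows=aln)
            names, D = protein_distance(sm)
            hits += _bipartitions(nj_tree(D, names), "t1") == true_bp
        assert hits >= 48  # >= 95%


class TestLikelihood:
    def test_two_taxon_closed_form(self):
        model = poisson_model()
        t = TreeNode()
        t.add(_leaf("A", 0.1))
        t.add(_leaf("B", 0.2))
        rows = {"A": "AR", "B": "AK"}
        sm = Supermatrix(taxa=["A", "B"], rows=rows)
        lnl = tree_lnL(t, sm, model)
        # closed form: sum over sites of log sum_a pi_a P_aA(t1) P_aB(t2)
        PA = model.transition_matrix(0.1)
        PB = model.transition_matrix(0.2)
        idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        expected = 0.0
        for site in range(2):
            i, j = idx[rows["A"][site]], idx[rows["B"][site]]
            expected += math.log(sum(model.freqs[a] * PA[a, i] * PB[a, j] for a in range(20)))
        assert lnl == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("model_fn", [poisson_model, jtt_model])
    def test_matches_exhaustive_enumeration(self, model_fn):
        model = model_fn()
        tree = _four_leaf_tree()
        rng = np.random.default_rng(0)
        rows = {t: "".join(rng.choice(list(AMINO_ACIDS), 5)) for t in "ABCD"}
        sm = Supermatrix(taxa=list("ABCD"), rows=rows)
        lnl = tree_lnL(tree, sm, model)
        idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        P_ab = model.transition_matrix(0.3)
        P = {t: model.transition_matrix(l) for t, l in
             (("A", 0.1), ("B", 0.2), ("C", 0.25), ("D", 0.15))}
        expected = 0.0
        for site in range(5):
            obs = {t: idx[rows[t][site]] for t in "ABCD"}
            s = 0.0
            for r, m in itertools.product(range(20), range(20)):
                s += (model.freqs[r] * P_ab[r, m]
                      * P["A"][m, obs["A"]] * P["B"][m, obs["B"]]
                      * P["C"][r, obs["C"]] * P["D"][r, obs["D"]])
            expected += math.log(s)
        assert lnl == pytest.approx(expected, abs=1e-9)

    def test_zero_branches_identical_sequences_degenerate_limit(self):
        model = poisson_model()
        t = TreeNode()
        t.add(_leaf("A", 0.0))
        t.add(_leaf("B", 0.0))
        sm = Supermatrix(taxa=["A", "B"], rows={"A": "ARN", "B": "ARN"})
        lnl = tree_lnL(t, sm, model)
        assert lnl == pytest.approx(3 * math.log(1 / 20), abs=1e-9)

    def test_gaps_are_missing_data(self):
        model = poisson_model()
        t = TreeNode()
        t.add(_leaf("A", 0.1))
        t.add(_leaf("B", 0.2))
        sm1 = Supermatrix(taxa=["A", "B"], rows={"A": "A-", "B": "AR"})
        sm2 = Supermatrix(taxa=["A", "B"], rows={"A": "A", "B": "A"})
        # gap column contributes log pi_R-marginalized term = log pi-weighted row sum = 0 extra info
        lnl1 = tree_lnL(t, sm1, model)
        lnl2 = tree_lnL(t, sm2, model)
        assert lnl1 == pytest.approx(lnl2 + math.log(1 / 20), abs=1e-9)

    def test_rerooting_invariance(self):
        model = jtt_model()
        tree = _four_leaf_tree()
        rng = np.random.default_rng(3)
        rows = {t: "".join(rng.choice(list(AMINO_ACIDS), 40)) for t in "ABCD"}
        sm = Supermatrix(taxa=list("ABCD"), rows=rows)
        base = tree_lnL(tree, sm, model)
        for leaf in "ABCD":
            rerooted = reroot_adjacent_to_leaf(tree, leaf)
            assert tree_lnL(rerooted, sm, model) == pytest.approx(base, abs=1e-8)


class TestOptimization:
    def test_lnl_non_decreasing_and_fixed_point(self):
        model = poisson_model()
        tree = _four_leaf_tree()
        aln = simulate_alignment(tree, model, 400, seed=2)
        sm = Supermatrix(taxa=list(aln), rows=aln)
        before = tree_lnL(tree, sm, model)
        _, after = optimize_branch_lengths(tree, sm, model, tol=1e-6)
        assert after >= before
        # a second pass from the optimum changes nothing appreciable
        _, again = optimize_branch_lengths(tree, sm, model, tol=1e-6)
        assert again == pytest.approx(after, abs=1e-3)

    def test_branch_length_recovery(self):
        model = poisson_model()
        tree = _four_leaf_tree()
        aln = simulate_alignment(tree, model, 10_000, seed=4)
        sm = Supermatrix(taxa=list(aln), rows=aln)
        # perturb all branch lengths, then re-optimize
        perturbed = tree.copy()
        for n in perturbed.postorder():
            if n.length is not None:
                n.length *= 2.0
        opt, _ = optimize_branch_lengths(perturbed, sm, model, tol=1e-6)
        true_lengths = {0.1, 0.2, 0.25, 0.15, 0.3}
        for n in opt.postorder():
            if n.length is None:
                continue
            closest = min(true_lengths, key=lambda x: abs(x - n.length))
            assert abs(n.length - closest) / closest < 0.25


class TestPlacement:
    def _setup(self, seed, n_sites=300):
        root = TreeNode()
        A = TreeNode(); A.length = 0.3
        for n, l in (("a1", 0.1), ("a2", 0.1), ("a3", 0.15)):
            A.add(_leaf(n, l))
        B = TreeNode(); B.length = 0.3
        for n, l in (("b1", 0.1), ("b2", 0.1), ("b3", 0.15)):
            B.add(_leaf(n, l))
        B.add(_leaf("focal", 0.2))  # truth: focal inside group B
        root.add(A); root.add(B); root.add(_leaf("out", 0.5))
        aln = simulate_alignment(root, poisson_model(), n_sites, seed=seed)
        return Supermatrix(taxa=list(aln), rows=aln)

    def test_correct_sign_for_true_placement(self):
        sm = self._setup(seed=10)
        la, lb, d = constrained_topology_compare(
            sm, "focal", ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        )
        assert d > 0

    def test_group_swap_negates_delta(self):
        sm = self._setup(seed=11, n_sites=150)
        _, _, d1 = constrained_topology_compare(sm, "focal", ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        _, _, d2 = constrained_topology_compare(sm, "focal", ["b1", "b2", "b3"], ["a1", "a2", "a3"])
        assert d1 == pytest.approx(-d2, abs=1e-4)

    def test_focal_identical_to_group_member_prefers_that_group(self):
        sm = self._setup(seed=12, n_sites=150)
        rows = dict(sm.rows)
        rows["focal"] = rows["a1"]  # focal now a copy of an A-group member
        sm2 = Supermatrix(taxa=sm.taxa, rows=rows)
        _, _, d = constrained_topology_compare(sm2, "focal", ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert d < 0

    def test_overlapping_groups_rejected(self):
        sm = self._setup(seed=13, n_sites=60)
        with pytest.raises(ValueError):
            constrained_topology_compare(sm, "focal", ["a1"], ["a1", "b1"])


class TestBootstrap:
    def _matrix(self, n_sites, seed):
        A = TreeNode(); A.length = 0.2; A.add(_leaf("t1", 0.1)); A.add(_leaf("t2", 0.1))
        root = TreeNode(); root.add(A); root.add(_leaf("t3", 0.3)); root.add(_leaf("t4", 0.3))
        aln = simulate_alignment(root, poisson_model(), n_sites, seed=seed)
        return Supermatrix(taxa=list(aln), rows=aln)

    def test_single_replicate_supports_are_zero_or_one(self):
        sm = self._matrix(300, seed=1)
        t = bootstrap_support(sm, n_reps=1, seed=2)
        sups = [n.support for n in t.postorder() if n.support is not None]
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_same_seed_reproducible(self):
        sm = self._matrix(300, seed=1)
        t1 = bootstrap_support(sm, n_reps=20, seed=9)
        t2 = bootstrap_support(sm, n_reps=20, seed=9)
        s1 = [n.support for n in t1.postorder() if n.support is not None]
        s2 = [n.support for n in t2.postorder() if n.support is not None]
        assert s1 == s2

    def test_clean_signal_high_support(self):
        sm = self._matrix(3000, seed=3)
        t = bootstrap_support(sm, n_reps=50, seed=4)
        sups = [n.support for n in t.postorder() if n.support is not None]
        assert sups and min(sups) >= 0.95
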