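"""Strict and smoothed ghost-lineage calibration."""

import math
import random

import pytest

from paleochron import (
    SmoothingParams,
    ValidationError,
    calibrate_basic,
    calibrate_equal,
    find_donor_chain,
    smoothing_correction,
    tree_from_string,
)
from paleochron.timescale import ROOT_STEM
from _oracles import exhaustive_max_ages, random_topology


class TestSmoothingCorrection:
    @pytest.mark.parametrize("x, y, z", [(10, 1, 5), (7, 0, 7), (12, 3, 3)])
    def test_equal_division_law(self, x, y, z):
        assert smoothing_correction(x, y) == z

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            smoothing_correction(-1, 1)
        with pytest.raises(ValidationError):
            smoothing_correction(1, -1)


class TestCalibrateBasic:
    def test_worked_example(self, three_tip_basic):
        assert three_tip_basic.node_ages() == {
            frozenset({"A", "B"}): 20.0,
            frozenset({"A", "B", "C"}): 30.0,
        }
        assert three_tip_basic.durations() == {
            frozenset({"A"}): 10.0,
            frozenset({"B"}): 0.0,
            frozenset({"C"}): 0.0,
            frozenset({"A", "B"}): 10.0,
        }

    def test_star_tree(self):
        chron = calibrate_basic(tree_from_string("(A,B,C);"),
                                {"A": 5, "B": 10, "C": 15})
        assert chron.root_age == 15.0

    def test_missing_occurrence_names_tips(self):
        with pytest.raises(ValidationError, match="B"):
            calibrate_basic(tree_from_string("(A,B);"), {"A": 5})

    def test_matches_exhaustive_oracle(self, rng):
        """Node ages equal a brute-force maximum over each node's descendant
        tip set, on random topologies with random ages."""
        for _ in range(200):
            n = rng.randint(3, 8)
            labels = [f"t{i}" for i in range(n)]
            tree = tree_from_string(random_topology(rng, labels))
            ages = {lab: rng.uniform(0, 300) for lab in labels}
            chron = calibrate_basic(tree, ages)
            assert chron.node_ages() == exhaustive_max_ages(chron.tree, ages)


class TestFindDonorChain:
    def _linear_chain(self, donor_len, n_zero):
        """Caterpillar whose internal path has one positive branch of
        ``donor_len`` followed by ``n_zero`` zero-length internodes."""
        # ages: deepest pair at age a; nesting old tip keeps ancestors equal
        newick = "((((X,W),V),U),O);"
        tree = tree_from_string(newick)
        ages = {"X": 8, "W": 0, "V": 8, "U": 8, "O": 8 + donor_len}
        return calibrate_basic(tree, ages)

    def test_single_zero_internode(self):
        chron = calibrate_basic(tree_from_string("(((X,W),V),U);"),
                                {"X": 8, "W": 0, "V": 8, "U": 18})
        # branch above {X,W} is zero; donor is the root->{X,W,V} branch (10)
        node = chron.tree.mrca(taxon_labels=["X", "W"])
        chain = find_donor_chain(chron, node)
        assert chain.chain_length == 1
        assert chain.donor_duration == 10.0
        assert chain.share == 5.0

    def test_two_zero_internodes(self):
        chron = self._linear_chain(donor_len=12, n_zero=2)
        # deepest zero branch: terminal X under two zero internodes
        tip_x = next(lf for lf in chron.tree.leaf_node_iter()
                     if lf.taxon.label == "X")
        chain = find_donor_chain(chron, tip_x)
        assert chain.chain_length == 3  # {X,W}, {X,W,V} internodes + terminal X
        assert chain.donor_duration == 12.0
        assert chain.share == 3.0

    def test_root_stem_is_ultimate_donor(self):
        chron = calibrate_basic(tree_from_string("((A,B),C);"),
                                {"A": 20, "B": 20, "C": 20})
        node = chron.tree.mrca(taxon_labels=["A", "B"])
        chain = find_donor_chain(chron, node, vartime=1.0)
        assert chain.donor_id == ROOT_STEM
        assert chain.share == 0.5

    def test_chain_under_root_with_two_zero_internodes(self):
        """Stem donor of 1 Myr shared over a two-internode chain: z = 1/3."""
        chron = calibrate_basic(tree_from_string("(((A,B),C),D);"),
                                {"A": 20, "B": 20, "C": 20, "D": 20})
        node = chron.tree.mrca(taxon_labels=["A", "B"])
        chain = find_donor_chain(chron, node, vartime=1.0)
        assert chain.donor_id == ROOT_STEM
        assert chain.chain_length == 2
        assert chain.share == pytest.approx(1.0 / 3.0)


class TestCalibrateEqual:
    def test_two_tip_stem_donation(self):
        chron = calibrate_equal(tree_from_string("(A,B);"),
                                {"A": 10, "B": 20}, SmoothingParams(5.0))
        assert chron.root_age == 22.5
        assert chron.durations() == {frozenset({"A"}): 12.5,
                                     frozenset({"B"}): 2.5}

    def test_worked_micro_example(self):
        """((A,B),C), ages 20/20/30, vartime 1: the A-chain takes half of the
        10 Myr supporting branch (node AB slides to 25), B's branch is
        stretched passively, C borrows from the stem."""
        chron = calibrate_equal(tree_from_string("((A,B),C);"),
                                {"A": 20, "B": 20, "C": 30}, SmoothingParams(1.0))
        ages = chron.node_ages()
        assert ages[frozenset({"A", "B"})] == 25.0
        assert ages[frozenset({"A", "B", "C"})] == 30.5
        durations = chron.durations()
        assert durations[frozenset({"A"})] == 5.0
        assert durations[frozenset({"B"})] == 5.0
        assert durations[frozenset({"C"})] == 0.5
        assert durations[frozenset({"A", "B"})] == 5.5

    def test_isolated_chain_equal_shares(self):
        """A 12-Myr donor over two zero internodes and a terminal: every
        member ends at exactly x/(y+1) = 4 Myr."""
        tree = tree_from_string("(((X,W),V),U);")
        ages = {"X": 8, "W": 0, "V": 8, "U": 20}
        chron = calibrate_equal(tree, ages, SmoothingParams(1.0))
        d = chron.durations()
        assert d[frozenset({"X", "W"})] == pytest.approx(4.0, abs=1e-9)
        assert d[frozenset({"X"})] == pytest.approx(4.0, abs=1e-9)
        # donor branch also keeps one share (before the stem stretches it)
        log = chron.smoothing_log
        assert log[0].chain_length == 2
        assert log[0].share == pytest.approx(4.0, abs=1e-9)

    def test_vartime_must_be_positive(self):
        with pytest.raises(ValidationError):
            calibrate_equal(tree_from_string("(A,B);"), {"A": 1, "B": 2},
                            SmoothingParams(-1))

    @pytest.mark.parametrize("vartime", [1.0, 5.0, 10.0])
    def test_invariants_on_random_trees(self, rng, vartime):
        """Tip ages unchanged; node ages never younger than strict; root
        moves by at most vartime; every branch positive afterwards."""
        for _ in range(40):
            n = rng.randint(3, 10)
            labels = [f"t{i}" for i in range(n)]
            tree = tree_from_string(random_topology(rng, labels))
            # clustered ages produce plenty of zero-length branches
            ages = {lab: rng.choice([10.0, 10.0, 25.0, 40.0]) for lab in labels}
            basic = calibrate_basic(tree, ages)
            equal = calibrate_equal(tree, ages, SmoothingParams(vartime))
            assert equal.tip_ages() == basic.tip_ages()
            basic_ages = basic.node_ages()
            for key, age in equal.node_ages().items():
                assert age >= basic_ages[key] - 1e-9
            assert equal.root_age <= basic.root_age + vartime + 1e-9
            assert all(d > 0 for d in equal.durations().values())

    def test_donor_conservation(self, rng):
        """Each resolution moves time without creating it: the donor's share
        times (y+1) reproduces its old duration exactly, and the temporal
        span of the tree (the root age) grows only by the consumed portion of
        the stem, never more than vartime."""
        vartime = 5.0
        for _ in range(30):
            n = rng.randint(4, 9)
            labels = [f"t{i}" for i in range(n)]
            tree = tree_from_string(random_topology(rng, labels))
            ages = {lab: rng.choice([5.0, 5.0, 5.0, 30.0]) for lab in labels}
            basic = calibrate_basic(tree, ages)
            equal = calibrate_equal(tree, ages, SmoothingParams(vartime))
            for entry in equal.smoothing_log:
                # within one resolution every share is exact
                assert entry.share == pytest.approx(
                    entry.donor_duration / (entry.chain_length + 1), abs=1e-12)
            stem_consumed = sum(
                entry.donor_duration - entry.share
                for entry in equal.smoothing_log
                if entry.donor_id == ROOT_STEM
            )
            assert 0 <= stem_consumed <= vartime + 1e-9
            # only stem donations move the root
            assert equal.root_age - basic.root_age == pytest.approx(
                stem_consumed, abs=1e-9)

    def test_ages_monotone_along_paths(self, rng):
        labels = [f"t{i}" for i in range(8)]
        tree = tree_from_string(random_topology(rng, labels))
        ages = {lab: rng.choice([10.0, 10.0, 30.0]) for lab in labels}
        equal = calibrate_equal(tree, ages, SmoothingParams(2.0))
        for node in equal.tree.preorder_node_iter():
            for child in node.child_nodes():
                assert child.age <= node.age

    def test_rank_order_insensitive_to_vartime(self):
        """The choice of vartime (1/5/10 Myr) has little to no effect on
        smoothed node ages: on simulated datasets the node-age rank order is
        essentially preserved (only stem-fed chains move differently, so
        adjacent near-ties may swap)."""
        from scipy.stats import spearmanr
        from paleochron import BDSSConfig, simulate_bdss
        for seed in range(5):
            ds = simulate_bdss(BDSSConfig(seed=seed, min_tips=10, max_tips=60))
            tip_ages = {r.taxon_label: r.point_age for r in ds.occurrences}
            vectors = []
            for vt in (1.0, 5.0, 10.0):
                node_ages = calibrate_equal(ds.observed_tree.tree, tip_ages,
                                            SmoothingParams(vt)).node_ages()
                keys = sorted(node_ages, key=lambda k: tuple(sorted(k)))
                vectors.append([node_ages[k] for k in keys])
            for other in vectors[1:]:
                rho = spearmanr(vectors[0], other).statistic
                assert rho > 0.95
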