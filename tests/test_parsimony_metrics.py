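"""Matrix I/O, tree-length scoring, CI/RI — verified against brute force."""

import random

import pytest

from paleochron import (
    ValidationError,
    ci,
    matrix_from_rows,
    max_steps,
    min_steps,
    read_matrix,
    ri,
    score_tree,
    tree_from_string,
    tree_length,
    write_matrix,
)
from paleochron.parsimony_metrics import (
    character_max_steps,
    character_min_steps,
    _character_length_on_tree,
)
from _oracles import brute_force_tree_length, random_column, random_topology


NEXUS_SMALL = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=2 NCHAR=1;
FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
MATRIX
TaxA 0
TaxB 1
;
END;
"""

TNT_SMALL = """xread
'small test matrix'
4 3
TaxA 0102
TaxB 01?2
TaxC {01}110
;
ccode + 0 2.3;
"""


class TestReadMatrix:
    def test_binary_nexus(self, tmp_path):
        path = tmp_path / "m.nex"
        path.write_text(NEXUS_SMALL)
        matrix = read_matrix(path)
        assert matrix.taxa == ["TaxA", "TaxB"]
        assert matrix.cells == [[frozenset({0})], [frozenset({1})]]
        assert matrix.ordered_flags == [False]

    def test_polymorphic_and_missing_nexus(self, tmp_path):
        path = tmp_path / "m.nex"
        path.write_text(NEXUS_SMALL.replace("TaxA 0", "TaxA {01}")
                        .replace("TaxB 1", "TaxB ?"))
        matrix = read_matrix(path)
        assert matrix.cells[0][0] == frozenset({0, 1})
        assert matrix.cells[1][0] is None

    def test_tnt_with_ccode(self, tmp_path):
        path = tmp_path / "m.tnt"
        path.write_text(TNT_SMALL)
        matrix = read_matrix(path)
        assert matrix.n_taxa == 3 and matrix.n_characters == 4
        assert matrix.cells[2][0] == frozenset({0, 1})
        assert matrix.cells[1][2] is None
        assert matrix.ordered_flags == [True, False, True, True]

    def test_round_trip(self, tmp_path, rng):
        labels = [f"tax{i}" for i in range(6)]
        rows = {lab: "".join(random_column(rng, [lab], 3)[lab] for _ in range(8))
                for lab in labels}
        matrix = matrix_from_rows(rows, ordered=[1, 4])
        path = tmp_path / "rt.nex"
        write_matrix(matrix, path)
        back = read_matrix(path)
        assert back.taxa == matrix.taxa
        assert back.cells == matrix.cells
        assert back.ordered_flags == matrix.ordered_flags

    def test_ragged_rejected(self):
        from paleochron.parsimony_metrics import CharacterMatrix
        with pytest.raises(ValidationError):
            CharacterMatrix(taxa=["a", "b"],
                            cells=[[frozenset({0})], [frozenset({0}), frozenset({1})]])


class TestTreeLength:
    def test_single_binary_character(self):
        tree = tree_from_string("((A,B),(C,D));")
        matrix = matrix_from_rows({"A": "0", "B": "0", "C": "1", "D": "1"})
        assert tree_length(matrix, tree) == 1

    def test_ordered_character_linear_cost(self):
        tree = tree_from_string("((A,B),(C,D));")
        matrix = matrix_from_rows({"A": "0", "B": "2", "C": "0", "D": "2"},
                                  ordered=[0])
        # two changes of size two: total 4 ordered steps
        assert tree_length(matrix, tree) == 4

    def test_tip_missing_from_matrix_error(self):
        tree = tree_from_string("((A,B),C);")
        matrix = matrix_from_rows({"A": "0", "B": "1"})
        with pytest.raises(ValidationError, match="C"):
            tree_length(matrix, tree)

    def test_matches_brute_force_oracle(self, rng):
        """Sankoff DP equals exhaustive enumeration over internal-node state
        assignments, with polytomies, missing data and polymorphism, under
        both ordered and unordered costs; the m <= S <= g sandwich holds."""
        for _ in range(120):
            n = rng.randint(3, 7)
            labels = [f"t{i}" for i in range(n)]
            tree = tree_from_string(random_topology(rng, labels))
            n_states = rng.randint(2, 5)
            rows = random_column(rng, labels, n_states)
            ordered = rng.random() < 0.5
            matrix = matrix_from_rows(rows, ordered=[0] if ordered else [])
            column = matrix.column(0)
            dp = _character_length_on_tree(column, ordered, tree)
            assert dp == brute_force_tree_length(column, ordered, tree)
            assert (character_min_steps(column, ordered)
                    <= dp
                    <= character_max_steps(column, ordered))

    def test_resolving_polytomy_never_increases_length(self, rng):
        """A polytomy's length is an upper bound for any of its resolutions
        (and collapsing an edge never decreases length)."""
        for _ in range(25):
            labels = [f"t{i}" for i in range(5)]
            star = tree_from_string("(" + ",".join(labels) + ");")
            resolved = tree_from_string(random_topology(rng, labels))
            rows = random_column(rng, labels, 3, p_missing=0.1)
            ordered = rng.random() < 0.5
            matrix = matrix_from_rows(rows, ordered=[0] if ordered else [])
            assert tree_length(matrix, resolved) <= tree_length(matrix, star)


class TestStepBounds:
    def test_unordered_min(self):
        col = {f"t{i}": frozenset({s}) for i, s in enumerate([0, 1, 2, 1])}
        assert character_min_steps(col, ordered=False) == 2

    def test_ordered_min_is_range(self):
        col = {f"t{i}": frozenset({s}) for i, s in enumerate([0, 3, 1])}
        assert character_min_steps(col, ordered=True) == 3

    def test_single_scored_taxon_zero(self):
        assert character_min_steps({"a": frozenset({2})}, ordered=True) == 0
        assert character_max_steps({"a": frozenset({2})}, ordered=False) == 0

    def test_binary_majority_root(self):
        col = {f"t{i}": frozenset({s}) for i, s in enumerate([0, 0, 0, 1, 1])}
        assert character_max_steps(col, ordered=False) == 2

    def test_max_steps_equals_star_tree_length(self, rng):
        for _ in range(40):
            n = rng.randint(3, 8)
            labels = [f"t{i}" for i in range(n)]
            star = tree_from_string("(" + ",".join(labels) + ");")
            rows = random_column(rng, labels, rng.randint(2, 5))
            ordered = rng.random() < 0.5
            matrix = matrix_from_rows(rows, ordered=[0] if ordered else [])
            column = matrix.column(0)
            assert character_max_steps(column, ordered) == \
                _character_length_on_tree(column, ordered, star)

    def test_sandwich_over_whole_matrices(self, rng):
        for _ in range(10):
            labels = [f"t{i}" for i in range(6)]
            tree = tree_from_string(random_topology(rng, labels))
            rows = {lab: "" for lab in labels}
            for _c in range(6):
                col = random_column(rng, labels, 3)
                for lab in labels:
                    rows[lab] += col[lab]
            matrix = matrix_from_rows(rows, ordered=[0, 3])
            s = tree_length(matrix, tree)
            assert min_steps(matrix) <= s <= max_steps(matrix)


class TestIndices:
    def test_perfect_fit(self):
        tree = tree_from_string("((A,B),(C,D));")
        matrix = matrix_from_rows({"A": "01", "B": "01", "C": "10", "D": "10"})
        s = tree_length(matrix, tree)
        assert s == min_steps(matrix)
        assert ci(matrix, s) == 1.0
        assert ri(matrix, s) == 1.0

    def test_worst_fit_ri_zero(self):
        tree = tree_from_string("((A,C),(B,D));")
        matrix = matrix_from_rows({"A": "0", "B": "0", "C": "1", "D": "1"})
        s = tree_length(matrix, tree)
        assert s == max_steps(matrix) == 2
        assert ri(matrix, s) == 0.0

    def test_impossible_length_rejected(self):
        matrix = matrix_from_rows({"A": "0", "B": "1"})
        with pytest.raises(ValidationError):
            ci(matrix, 0)

    def test_uninformative_characters_excluded_consistently(self):
        tree = tree_from_string("((A,B),(C,D));")
        # char 2 is an autapomorphy: g = m = 1 on every tree
        matrix = matrix_from_rows({"A": "00", "B": "00", "C": "10", "D": "11"})
        s = tree_length(matrix, tree)
        stats = score_tree(matrix, tree)
        assert stats["tree_length"] == s
        assert 0 <= stats["ri"] <= 1
        assert 0 <= stats["ci_informative_only"] <= stats["ci"] <= 1

    def test_values_within_unit_interval(self, rng):
        for _ in range(10):
            labels = [f"t{i}" for i in range(6)]
            tree = tree_from_string(random_topology(rng, labels))
            rows = {lab: "" for lab in labels}
            for _c in range(5):
                col = random_column(rng, labels, 3)
                for lab in labels:
                    rows[lab] += col[lab]
            matrix = matrix_from_rows(rows)
            s = tree_length(matrix, tree)
            assert 0 <= ci(matrix, s) <= 1
            r = ri(matrix, s)
            assert r != r or 0 <= r <= 1  # NaN when no informative characters
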