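"""Parsimony scoring of fixed trees against discrete morphological matrices.

This module scores trees — it performs no tree search.  Given a character
matrix (NEXUS standard data or TNT ``xread``) and a rooted tree, it computes:

* ``tree_length`` — the minimum number of state changes (steps) needed to
  explain every character on the tree, by Sankoff dynamic programming with a
  per-character cost matrix: unit cost between distinct states for unordered
  characters, ``|i - j|`` for ordered (additive) characters.  The DP runs
  directly on polytomies; missing cells impose no constraint and polymorphic
  cells may realize any member state (soft polymorphism).
* per-character minimum steps ``m`` (best-case over all trees) and maximum
  steps ``g`` (the star-tree length), and from them the ensemble consistency
  index CI = Σm/S and retention index RI = (Σg − S)/(Σg − Σm), with
  uninformative characters (g = m, constant length on every tree) excluded
  from the RI sums to avoid 0/0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import dendropy

from .phylo_io import PhyloIOError, ValidationError

__all__ = [
    "CharacterMatrix",
    "read_matrix",
    "matrix_from_rows",
    "write_matrix",
    "tree_length",
    "min_steps",
    "max_steps",
    "character_min_steps",
    "character_max_steps",
    "ci",
    "ri",
    "score_tree",
]

# a cell is None (missing) or a frozenset of non-negative integer states
Cell = frozenset | None


@dataclass
class CharacterMatrix:
    """Discrete character data: taxa × characters with ordered flags.

    ``cells[i][j]`` is taxon ``i``'s scoring for character ``j``: ``None``
    for missing/inapplicable, else a non-empty frozenset of integer states
    (singleton for a plain scoring, larger for polymorphism).
    """

    taxa: list[str]
    cells: list[list[Cell]]
    ordered_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.taxa):
            raise ValidationError("one row of cells required per taxon")
        ncols = {len(r) for r in self.cells}
        if len(ncols) > 1:
            raise ValidationError(f"ragged matrix rows: lengths {sorted(ncols)}")
        if not self.ordered_flags:
            self.ordered_flags = [False] * self.n_characters
        if len(self.ordered_flags) != self.n_characters:
            raise ValidationError("ordered_flags length != number of characters")
        for row in self.cells:
            for cell in row:
                if cell is not None and (not cell or any(s < 0 for s in cell)):
                    raise ValidationError(f"invalid cell {cell!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def column(self, j: int) -> dict[str, frozenset]:
        """Scored cells of character ``j`` keyed by taxon (missing dropped)."""
        return {
            t: row[j]
            for t, row in zip(self.taxa, self.cells)
            if row[j] is not None
        }

    def percent_missing(self) -> float:
        total = self.n_taxa * self.n_characters
        miss = sum(1 for row in self.cells for c in row if c is None)
        return 100.0 * miss / total if total else 0.0


def matrix_from_rows(rows: dict[str, str], ordered: Sequence[int] = (),
                     missing: str = "?", gap: str = "-") -> CharacterMatrix:
    """Build a matrix from raw symbol strings (``{..}``/``[..]`` = polymorphic).

    ``ordered`` lists 0-based indices of additive characters.
    """
    taxa = list(rows)
    cells = [list(_parse_symbol_row(rows[t], missing, gap)) for t in taxa]
    ncols = len(cells[0]) if cells else 0
    flags = [False] * ncols
    for j in ordered:
        flags[j] = True
    return CharacterMatrix(taxa=taxa, cells=cells, ordered_flags=flags)


def _parse_symbol_row(text: str, missing: str, gap: str):
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in (missing, gap):
            yield None
            i += 1
        elif ch in "{[(":
            close = {"{": "}", "[": "]", "(": ")"}[ch]
            j = text.index(close, i)
            states = frozenset(int(c) for c in text[i + 1:j] if not c.isspace())
            if not states:
                raise PhyloIOError(f"empty polymorphic set at position {i}")
            yield states
            i = j + 1
        elif ch.isdigit():
            yield frozenset({int(ch)})
            i += 1
        elif ch.isalpha():
            # letter symbols continue the digit series (A=10, B=11, ...)
            yield frozenset({10 + ord(ch.upper()) - ord("A")})
            i += 1
        else:
            raise PhyloIOError(f"undeclared symbol {ch!r} in matrix row")


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, format: str | None = None,
                ordered: Sequence[int] | None = None) -> CharacterMatrix:
    """Read a NEXUS standard-data or TNT ``xread`` matrix.

    Ordered (additive) flags come from a NEXUS ASSUMPTIONS ``TYPESET``
    (``ord:``/``unord:`` groups) or a TNT ``ccode`` line where present; an
    explicit ``ordered`` argument (0-based character indices) overrides both.
    """
    path = Path(path)
    text = path.read_text()
    if format is None:
        format = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "tnt"
    if format == "nexus":
        matrix = _read_nexus_matrix(path, text)
    elif format == "tnt":
        matrix = _read_tnt_matrix(text)
    else:
        raise ValueError(f"unsupported matrix format: {format!r}")
    if ordered is not None:
        matrix.ordered_flags = [False] * matrix.n_characters
        for j in ordered:
            matrix.ordered_flags[j] = True
    return matrix


def _read_nexus_matrix(path: Path, text: str) -> CharacterMatrix:
    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except dendropy.utility.error.DataParseError as exc:
        raise PhyloIOError(f"cannot parse NEXUS matrix {path}: {exc}") from exc
    taxa, cells = [], []
    ncols = None
    for taxon in dmat:
        label = taxon.label.replace(" ", "_")
        row: list[Cell] = []
        for state in dmat[taxon]:
            symbols = [fs.symbol for fs in state.fundamental_states]
            if state.symbol in ("?", "-") or "-" in symbols and len(symbols) > 1:
                row.append(None)
            elif symbols == ["-"]:
                row.append(None)  # gap treated as missing (morphology)
            else:
                row.append(frozenset(int(s, 36) for s in symbols))
        if ncols is None:
            ncols = len(row)
        elif len(row) != ncols:
            raise PhyloIOError(f"ragged row for taxon {label} in {path}")
        taxa.append(label)
        cells.append(row)
    matrix = CharacterMatrix(taxa=taxa, cells=cells)
    ordered = _ordered_from_assumptions(text, matrix.n_characters)
    if ordered is not None:
        matrix.ordered_flags = ordered
    return matrix


def _ordered_from_assumptions(text: str, nchar: int) -> list[bool] | None:
    m = re.search(r"TYPESET\s*\*?\s*\w+\s*=\s*([^;]+);", text, re.IGNORECASE)
    if not m:
        return None
    flags = [False] * nchar
    for group in m.group(1).split(","):
        if ":" not in group:
            continue
        kind, idx_text = group.split(":", 1)
        is_ord = kind.strip().lower() in {"ord", "ordered"}
        for tok in idx_text.split():
            if "-" in tok:
                lo, hi = tok.split("-")
                rng = range(int(lo), int(hi) + 1)
            else:
                rng = range(int(tok), int(tok) + 1)
            for one_based in rng:
                if 1 <= one_based <= nchar:
                    flags[one_based - 1] = is_ord
    return flags


def _read_tnt_matrix(text: str) -> CharacterMatrix:
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)\s*(.*?);", text,
                  re.DOTALL | re.IGNORECASE)
    if not m:
        raise PhyloIOError("no xread block found in TNT file")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    taxa, cells = [], []
    for line in m.group(3).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        name, _, states = line.partition(" ")
        row = list(_parse_symbol_row(states.strip(), "?", "-"))
        if len(row) != nchar:
            raise PhyloIOError(
                f"taxon {name}: {len(row)} characters, expected {nchar}"
            )
        taxa.append(name)
        cells.append(row)
    if len(taxa) != ntax:
        raise PhyloIOError(f"{len(taxa)} taxa read, header says {ntax}")
    matrix = CharacterMatrix(taxa=taxa, cells=cells)
    cc = re.search(r"ccode\s+([^;]+);", text, re.IGNORECASE)
    if cc:
        flags = [False] * nchar
        additive = False
        for tok in cc.group(1).split():
            if tok in "+-[]":
                additive = tok == "+"
            elif tok == "*":
                continue
            else:
                tok = tok.rstrip(";")
                if "." in tok:
                    lo, hi = tok.split(".")
                    rng = range(int(lo), int(hi) + 1)
                else:
                    rng = range(int(tok), int(tok) + 1)
                for zero_based in rng:  # TNT numbers characters from 0
                    if 0 <= zero_based < nchar:
                        flags[zero_based] = additive
        matrix.ordered_flags = flags
    return matrix


def write_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write as a NEXUS standard-data block (plus an assumptions TYPESET)."""
    max_state = 0
    for row in matrix.cells:
        for cell in row:
            if cell:
                max_state = max(max_state, max(cell))
    symbols = "".join(np.base_repr(s, 36) for s in range(max_state + 1))
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        txt = []
        for cell in row:
            if cell is None:
                txt.append("?")
            elif len(cell) == 1:
                txt.append(np.base_repr(next(iter(cell)), 36))
            else:
                txt.append("{" + "".join(np.base_repr(s, 36) for s in sorted(cell)) + "}")
        lines.append(f"{taxon:<{width}}{''.join(txt)}")
    lines += [";", "END;"]
    if any(matrix.ordered_flags):
        ord_idx = " ".join(str(j + 1) for j, f in enumerate(matrix.ordered_flags) if f)
        unord_idx = " ".join(str(j + 1) for j, f in enumerate(matrix.ordered_flags) if not f)
        parts = [f"ord: {ord_idx}"]
        if unord_idx:
            parts.append(f"unord: {unord_idx}")
        lines += ["BEGIN ASSUMPTIONS;", f"TYPESET * chartypes = {', '.join(parts)};", "END;"]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tree length (Sankoff DP, polytomy-ready)
# ---------------------------------------------------------------------------

def _cost_matrix(n_states: int, ordered: bool) -> np.ndarray:
    idx = np.arange(n_states)
    if ordered:
        return np.abs(idx[:, None] - idx[None, :]).astype(float)
    return (idx[:, None] != idx[None, :]).astype(float)


def _character_length_on_tree(column: dict[str, frozenset], ordered: bool,
                              tree: dendropy.Tree) -> int:
    """Minimum steps for one character on one (possibly non-binary) tree."""
    if not column:
        return 0
    n_states = max(max(c) for c in column.values()) + 1
    cost = _cost_matrix(n_states, ordered)
    inf = np.inf
    dp: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            vec = np.zeros(n_states)
            if label in column:
                vec = np.full(n_states, inf)
                vec[list(column[label])] = 0.0
            dp[id(node)] = vec
        else:
            vec = np.zeros(n_states)
            for child in node.child_nodes():
                vec += np.min(cost + dp[id(child)][None, :], axis=1)
            dp[id(node)] = vec
    best = float(np.min(dp[id(tree.seed_node)]))
    return int(round(best))


def tree_length(matrix: CharacterMatrix, tree: dendropy.Tree) -> int:
    """Total steps S: the parsimony length of the tree for every character."""
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    absent = tip_labels - set(matrix.taxa)
    if absent:
        raise ValidationError(f"tree tips absent from matrix: {sorted(absent)}")
    total = 0
    for j in range(matrix.n_characters):
        column = {t: s for t, s in matrix.column(j).items() if t in tip_labels}
        total += _character_length_on_tree(column, matrix.ordered_flags[j], tree)
    return total


# ---------------------------------------------------------------------------
# Per-character bounds, CI, RI
# ---------------------------------------------------------------------------

def character_min_steps(column: dict[str, frozenset], ordered: bool) -> int:
    """Fewest steps the character can require on any tree (m)."""
    if len(column) <= 1:
        return 0
    cells = list(column.values())
    if ordered:
        lo = max(min(c) for c in cells)
        hi = min(max(c) for c in cells)
        return max(0, lo - hi)
    forced = {next(iter(c)) for c in cells if len(c) == 1}
    open_sets = [c for c in cells if len(c) > 1 and not (c & forced)]
    # minimal number of extra states hitting every uncovered polymorphic set
    extra = 0
    if open_sets:
        candidates = sorted(set().union(*open_sets))
        from itertools import combinations
        for k in range(1, len(candidates) + 1):
            if any(
                all(set(combo) & s for s in open_sets)
                for combo in combinations(candidates, k)
            ):
                extra = k
                break
    n_states = len(forced) + extra
    return max(0, n_states - 1)


def character_max_steps(column: dict[str, frozenset], ordered: bool) -> int:
    """Steps on the star tree (g): the worst tree for any character."""
    if len(column) <= 1:
        return 0
    states = sorted(set().union(*column.values()))
    best = None
    for root in range(states[0], states[-1] + 1):
        if not ordered and root not in states:
            continue
        total = 0
        for cell in column.values():
            if ordered:
                total += min(abs(s - root) for s in cell)
            else:
                total += 0 if root in cell else 1
        best = total if best is None else min(best, total)
    return int(best)


def min_steps(matrix: CharacterMatrix) -> int:
    """Σm over characters."""
    return sum(
        character_min_steps(matrix.column(j), matrix.ordered_flags[j])
        for j in range(matrix.n_characters)
    )


def max_steps(matrix: CharacterMatrix) -> int:
    """Σg over characters."""
    return sum(
        character_max_steps(matrix.column(j), matrix.ordered_flags[j])
        for j in range(matrix.n_characters)
    )


def _per_character_bounds(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    ms = np.array([
        character_min_steps(matrix.column(j), matrix.ordered_flags[j])
        for j in range(matrix.n_characters)
    ])
    gs = np.array([
        character_max_steps(matrix.column(j), matrix.ordered_flags[j])
        for j in range(matrix.n_characters)
    ])
    return ms, gs


def ci(matrix: CharacterMatrix, tree_len: int, informative_only: bool = False) -> float:
    """Ensemble consistency index Σm / S.

    With ``informative_only``, characters whose length is the same on every
    tree (g = m) are removed from both Σm and S (each contributes exactly m
    steps to any tree's length).
    """
    ms, gs = _per_character_bounds(matrix)
    total_m = int(ms.sum())
    if tree_len < total_m:
        raise ValidationError(f"tree length {tree_len} < minimum possible {total_m}")
    if informative_only:
        uninf = int(ms[gs == ms].sum())
        num, den = total_m - uninf, tree_len - uninf
        return num / den if den else 1.0
    return total_m / tree_len if tree_len else 1.0


def ri(matrix: CharacterMatrix, tree_len: int) -> float:
    """Ensemble retention index (Σg − S)/(Σg − Σm) over informative characters.

    Uninformative characters (g = m) are excluded from both sums; their fixed
    contribution (m steps each, on any tree) is likewise removed from S.
    """
    ms, gs = _per_character_bounds(matrix)
    if tree_len < int(ms.sum()):
        raise ValidationError(f"tree length {tree_len} < minimum possible {int(ms.sum())}")
    informative = gs > ms
    if not informative.any():
        return float("nan")
    s_prime = tree_len - int(ms[~informative].sum())
    g_sum, m_sum = int(gs[informative].sum()), int(ms[informative].sum())
    return (g_sum - s_prime) / (g_sum - m_sum)


def score_tree(matrix: CharacterMatrix, tree: dendropy.Tree) -> dict:
    """TL, CI (both conventions) and RI for one tree, as one dict."""
    s = tree_length(matrix, tree)
    return {
        "tree_length": s,
        "min_steps": min_steps(matrix),
        "max_steps": max_steps(matrix),
        "ci": ci(matrix, s),
        "ci_informative_only": ci(matrix, s, informative_only=True),
        "ri": ri(matrix, s),
        "percent_missing": matrix.percent_missing(),
    }
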