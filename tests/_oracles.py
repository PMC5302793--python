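"""Independent oracles used by the test suite.

Everything here is deliberately brute-force (exhaustive enumeration, direct
set algebra) and independent of the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import random

import dendropy


def random_topology(rng: random.Random, labels: list[str],
                    max_children: int = 3) -> str:
    """Random rooted topology (polytomies allowed) as a Newick string."""

    def build(labs: list[str]) -> str:
        if len(labs) == 1:
            return labs[0]
        k = rng.randint(2, min(len(labs), max_children))
        shuffled = labs[:]
        rng.shuffle(shuffled)
        groups = [g for g in (shuffled[i::k] for i in range(k)) if g]
        if len(groups) == 1:
            return build(groups[0])
        return "(" + ",".join(build(g) for g in groups) + ")"

    return build(labels[:]) + ";"


def exhaustive_max_ages(tree: dendropy.Tree, tip_ages: dict[str, float]) -> dict[frozenset, float]:
    """Strict-calibration oracle: each internal node's age is the maximum of
    its descendant tip ages, computed by explicit descendant-set enumeration."""
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out[tips] = max(tip_ages[t] for t in tips)
    return out


def brute_force_tree_length(column: dict[str, frozenset], ordered: bool,
                            tree: dendropy.Tree) -> int:
    """Minimum steps by enumerating every internal-node state assignment."""
    if not column:
        return 0
    n_states = max(max(c) for c in column.values()) + 1
    states = range(n_states)
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = list(tree.leaf_node_iter())

    def cost(a: int, b: int) -> int:
        return abs(a - b) if ordered else int(a != b)

    leaf_options = [
        sorted(column[lf.taxon.label]) if lf.taxon.label in column else list(states)
        for lf in leaves
    ]
    best = None
    for assignment in itertools.product(states, repeat=len(internals)):
        amap = {id(nd): s for nd, s in zip(internals, assignment)}
        total = 0
        for nd in internals:
            if nd.parent_node is not None:
                total += cost(amap[id(nd.parent_node)], amap[id(nd)])
        for lf, opts in zip(leaves, leaf_options):
            total += min(cost(amap[id(lf.parent_node)], s) for s in opts)
        if best is None or total < best:
            best = total
    return best


def random_column(rng: random.Random, labels: list[str], n_states: int,
                  p_missing: float = 0.15, p_poly: float = 0.15) -> dict[str, str]:
    """Random character scorings as raw symbol strings (one char each)."""
    rows = {}
    for lab in labels:
        r = rng.random()
        if r < p_missing:
            rows[lab] = "?"
        elif r < p_missing + p_poly:
            members = rng.sample(range(n_states), rng.randint(2, n_states))
            rows[lab] = "{" + "".join(map(str, sorted(members))) + "}"
        else:
            rows[lab] = str(rng.randrange(n_states))
    return rows
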