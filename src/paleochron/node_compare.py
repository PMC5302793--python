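"""Node-age comparison across differently dated trees.

Nodes are matched across trees by exact descendant tip-set equality after all
trees are pruned to their common tip set; named clades (for headline nodes
such as "Archosauria") are resolved as the MRCA of a user-given tip list and
reported only where that MRCA is exactly monophyletic for the listed tips.

"Corrections" follow the convention of measuring every method against the
strict minimum-age calibration: correction(method, node) = age_method(node)
− age_base(node), in Myr.  Summaries report mean and median corrections per
method plus pairwise percentage ratios (rounded to the nearest 10% for
display, computed separately on means and on medians since the two can rank
methods differently).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo_io import Chronogram, ValidationError, prune_to_shared

__all__ = [
    "NodeAgeComparison",
    "clade_index",
    "match_nodes",
    "resolve_named_clades",
    "summarize_corrections",
    "fraction_younger",
    "comparisons_to_frame",
]


@dataclass
class NodeAgeComparison:
    """Ages of one matched clade under every method, plus corrections."""

    clade_key: frozenset[str]
    age_by_method: dict[str, float]
    corrections: dict[str, float] = field(default_factory=dict)
    hpd_by_method: dict[str, tuple[float, float]] = field(default_factory=dict)
    clade_name: str | None = None

    def compute_corrections(self, base: str) -> None:
        if base not in self.age_by_method:
            raise ValidationError(f"base method {base!r} missing for {set(self.clade_key)}")
        ref = self.age_by_method[base]
        self.corrections = {m: a - ref for m, a in self.age_by_method.items()}


def clade_index(tree: dendropy.Tree | Chronogram) -> dict[frozenset[str], dendropy.Node]:
    """Map each internal node to the set of its descendant tip labels."""
    raw = tree.tree if isinstance(tree, Chronogram) else tree
    return {
        frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd
        for nd in raw.preorder_node_iter()
        if not nd.is_leaf()
    }


def _hpd_of(node: dendropy.Node) -> tuple[float, float] | None:
    for ann in node.annotations:
        if "HPD" in ann.name.upper():
            try:
                lo, hi = (float(v) for v in ann.value)
                return (min(lo, hi), max(lo, hi))
            except (TypeError, ValueError):
                return None
    return None


def match_nodes(reference: Chronogram, others: Mapping[str, Chronogram],
                reference_name: str = "GLA") -> list[NodeAgeComparison]:
    """Match internal nodes across chronograms and collect their ages.

    All trees are pruned to the common tip set first; a comparison is emitted
    for every clade key present in *all* trees.  The reference method's
    correction is zero by construction.  HPD annotations found on matched
    nodes are carried along for reporting.
    """
    names = [reference_name, *others.keys()]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate method names: {names}")
    trees = [reference, *others.values()]
    shared = set.intersection(
        *({lf.taxon.label for lf in t.tree.leaf_node_iter()} for t in trees)
    )
    if len(shared) < 2:
        raise ValidationError("fewer than 2 tips shared across all trees")
    from .phylo_io import _prune_one
    pruned = [Chronogram(_prune_one(t.tree, shared)) for t in trees]
    indices = [clade_index(p) for p in pruned]
    common_keys = set.intersection(*(set(ix) for ix in indices))
    comparisons = []
    for key in sorted(common_keys, key=lambda k: (len(k), tuple(sorted(k)))):
        cmp = NodeAgeComparison(clade_key=key, age_by_method={})
        for name, ix in zip(names, indices):
            node = ix[key]
            cmp.age_by_method[name] = float(node.age)
            hpd = _hpd_of(node)
            if hpd is not None:
                cmp.hpd_by_method[name] = hpd
        cmp.compute_corrections(reference_name)
        comparisons.append(cmp)
    return comparisons


def resolve_named_clades(comparisons: Sequence[NodeAgeComparison],
                         clade_defs: Mapping[str, Sequence[str]]) -> dict[str, NodeAgeComparison | None]:
    """Attach clade names where the named tip set matches a comparison exactly.

    A name whose tip set is not a matched (monophyletic-in-all-trees) clade
    maps to ``None`` — unmatched, not an error.
    """
    by_key = {c.clade_key: c for c in comparisons}
    out: dict[str, NodeAgeComparison | None] = {}
    for name, tips in clade_defs.items():
        key = frozenset(tips)
        hit = by_key.get(key)
        if hit is not None:
            hit.clade_name = name
        out[name] = hit
    return out


def comparisons_to_frame(comparisons: Sequence[NodeAgeComparison]) -> pd.DataFrame:
    """Flatten comparisons to a table (one row per clade)."""
    rows = []
    for c in comparisons:
        row: dict[str, object] = {
            "clade": c.clade_name or ";".join(sorted(c.clade_key)),
            "n_tips": len(c.clade_key),
        }
        for m, a in c.age_by_method.items():
            row[f"age_{m}"] = a
        for m, d in c.corrections.items():
            row[f"corr_{m}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_corrections(comparisons: Sequence[NodeAgeComparison],
                          base: str = "GLA") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/median corrections per method, plus pairwise percentage ratios.

    Returns ``(summary, ratios)``.  ``summary`` has one row per non-base
    method with its mean and median correction (Myr) over all matched nodes.
    ``ratios`` holds methodA/methodB percentages computed on the means and on
    the medians separately, both raw and rounded to the nearest 10%.
    """
    if not comparisons:
        raise ValidationError("no matched nodes to summarize")
    methods = [m for m in comparisons[0].age_by_method if m != base]
    for c in comparisons:
        c.compute_corrections(base)
    stats = {}
    for m in methods:
        vals = np.array([c.corrections[m] for c in comparisons], dtype=float)
        stats[m] = (float(vals.mean()), float(np.median(vals)))
    summary = pd.DataFrame(
        {
            "method": methods,
            "mean_correction_myr": [stats[m][0] for m in methods],
            "median_correction_myr": [stats[m][1] for m in methods],
            "n_nodes": len(comparisons),
        }
    )
    ratio_rows = []
    for a, b in itertools.permutations(methods, 2):
        for stat_name, idx in (("mean", 0), ("median", 1)):
            denom = stats[b][idx]
            pct = float("nan") if denom == 0 else 100.0 * stats[a][idx] / denom
            ratio_rows.append(
                {
                    "numerator": a,
                    "denominator": b,
                    "statistic": stat_name,
                    "ratio_pct": pct,
                    "ratio_pct_rounded10": float("nan") if np.isnan(pct) else round(pct / 10.0) * 10.0,
                }
            )
    return summary, pd.DataFrame(ratio_rows)


def fraction_younger(comparisons: Sequence[NodeAgeComparison], method: str,
                     base: str = "sGLA") -> tuple[int, int, float]:
    """Count matched nodes dated younger by ``method`` than by ``base``."""
    for name in (method, base):
        if any(name not in c.age_by_method for c in comparisons):
            raise ValidationError(f"method {name!r} absent from some comparisons")
    total = len(comparisons)
    if total == 0:
        raise ValidationError("no comparisons given")
    count = sum(1 for c in comparisons if c.age_by_method[method] < c.age_by_method[base])
    return count, total, count / total
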