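"""Ghost-lineage diagnostics on strictly calibrated chronograms.

On a strict minimum-age chronogram, a tip's terminal branch duration is the
span of its implied-but-unsampled history (its ghost lineage): the taxon must
have existed since the divergence from its sister group, yet left no fossils
until its first appearance.  Long terminal ghosts flag uneven fossil sampling
through time — the regime that violates constant-rate serial-sampling
assumptions in model-based tip-dating.

The per-taxon (terminal-branch) view is canonical for the summary counts and
the mean; the full per-branch table, internal edges included, is retained for
plotting and threshold classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .phylo_io import Chronogram, ValidationError, clade_digest

__all__ = ["GhostSummary", "branch_durations", "ghost_summary", "DEFAULT_THRESHOLDS"]

#: Classification bands (Myr): plotting bands 25/50/75 plus the 65 Myr cutoff
#: used in the textual taxon counts.
DEFAULT_THRESHOLDS: tuple[float, ...] = (25.0, 50.0, 65.0, 75.0)


@dataclass(frozen=True)
class GhostSummary:
    """Threshold counts and mean ghost duration for one chronogram.

    ``counts_terminal[t]`` is the number of taxa whose terminal branch exceeds
    ``t`` Myr; ``counts_all`` counts every branch.  Means are in Myr.
    """

    branch_table: pd.DataFrame
    thresholds: tuple[float, ...]
    counts_terminal: dict[float, int]
    counts_all: dict[float, int]
    mean_terminal: float
    mean_all: float


def branch_durations(chronogram: Chronogram) -> pd.DataFrame:
    """One row per edge: identities, duration (Myr) and terminal flag."""
    rows = []
    for node in chronogram.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        child_tips = sorted(lf.taxon.label for lf in node.leaf_iter())
        parent_tips = sorted(lf.taxon.label for lf in parent.leaf_iter())
        rows.append(
            {
                "branch_id": clade_digest(child_tips),
                "parent_clade": clade_digest(parent_tips),
                "child": child_tips[0] if node.is_leaf() else clade_digest(child_tips),
                "duration_myr": float(parent.age - node.age),
                "is_terminal": node.is_leaf(),
            }
        )
    return pd.DataFrame(rows, columns=["branch_id", "parent_clade", "child",
                                       "duration_myr", "is_terminal"])


def ghost_summary(chronogram: Chronogram,
                  thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> GhostSummary:
    """Summarize ghost-lineage durations against ascending thresholds."""
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds:
        raise ValidationError("threshold list must not be empty")
    if list(thresholds) != sorted(thresholds):
        raise ValidationError(f"thresholds must be ascending: {thresholds}")
    table = branch_durations(chronogram)
    terminal = table.loc[table["is_terminal"], "duration_myr"]
    everything = table["duration_myr"]
    return GhostSummary(
        branch_table=table,
        thresholds=thresholds,
        counts_terminal={t: int((terminal > t).sum()) for t in thresholds},
        counts_all={t: int((everything > t).sum()) for t in thresholds},
        mean_terminal=float(terminal.mean()) if len(terminal) else 0.0,
        mean_all=float(everything.mean()) if len(everything) else 0.0,
    )
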