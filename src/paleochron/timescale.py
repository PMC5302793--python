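"""Time-calibration of cladograms from fossil first-appearance ages.

Two calibrations are provided:

``calibrate_basic``
    Strict ghost-lineage calibration: each node is dated to the oldest
    first-appearance age among its descendant tips, so every node age is a
    minimum divergence estimate.  Old taxa nested deep in a clade constrain
    several nested nodes at once, producing runs of zero-length internodes
    and terminal branches.

``calibrate_equal``
    Temporal smoothing of those zero-length runs.  A stem of length
    ``vartime`` is added above the root as the ultimate time donor.  Each
    maximal chain of consecutive zero-length branches borrows time from the
    nearest strictly-ancestral branch with positive duration (the root stem
    if there is none): the donor's current duration ``x`` is divided equally
    between the donor and the ``y`` chain members, so every share is

        z = x / (y + 1).

    Chains are discovered in preorder (rootward first) and each resolution
    reads the durations as already adjusted by earlier resolutions; sibling
    chains competing for one donor are therefore served first-come.  Tip
    ages are data and are never moved: a chain is stretched by sliding its
    internal nodes older while its youngest end stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

from .phylo_io import (
    Chronogram,
    OccurrenceRecord,
    ValidationError,
    ZERO_LENGTH_THRESHOLD,
)

__all__ = [
    "SmoothingParams",
    "DonorChain",
    "smoothing_correction",
    "calibrate_basic",
    "calibrate_equal",
    "find_donor_chain",
]

#: Sentinel donor id for the virtual stem above the root.
ROOT_STEM = "<root-stem>"


@dataclass(frozen=True)
class SmoothingParams:
    """Parameters of the 'equal' smoothing.

    ``vartime`` is the Myr of slack added as a virtual stem above the root;
    it seeds the smoothing of zero-length chains that have no positive-length
    ancestor branch of their own.
    """

    vartime: float = 1.0

    def __post_init__(self) -> None:
        if self.vartime <= 0:
            raise ValidationError(f"vartime must be > 0, got {self.vartime}")


@dataclass(frozen=True)
class DonorChain:
    """One resolved borrowing: a positive donor branch and the zero-length
    chain below it that shares its duration equally."""

    donor_id: str                 # clade digest of donor child end, or ROOT_STEM
    donor_duration: float         # x, Myr (current duration at resolution time)
    chain_length: int             # y, number of zero-length branches
    share: float                  # z = x / (y + 1), Myr
    chain_ids: tuple[str, ...] = ()


def smoothing_correction(x: float, y: int) -> float:
    """Equal-division share z = x/(y+1) for a donor of duration ``x`` Myr and
    ``y`` intervening zero-length internodes."""
    if x < 0:
        raise ValidationError(f"donor duration must be >= 0, got {x}")
    if y < 0:
        raise ValidationError(f"chain count must be >= 0, got {y}")
    return x / (y + 1)


# ---------------------------------------------------------------------------
# Strict calibration
# ---------------------------------------------------------------------------

def _point_ages(occurrences: Sequence[OccurrenceRecord] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(occurrences, Mapping):
        return {str(k): float(v) for k, v in occurrences.items()}
    return {r.taxon_label: r.point_age for r in occurrences}


def calibrate_basic(topology: dendropy.Tree,
                    occurrences: Sequence[OccurrenceRecord] | Mapping[str, float]) -> Chronogram:
    """Strict ghost-lineage calibration of a rooted topology.

    Tips are dated to their occurrence point ages; each internal node to the
    maximum point age among its descendant tips.  The input topology is not
    modified.  ``occurrences`` may also be a plain ``{tip label: age}``
    mapping (used heavily in tests and simulation).
    """
    ages = _point_ages(occurrences)
    tree = topology.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    if not leaves:
        raise ValidationError("cannot calibrate an empty tree")
    missing = [lf.taxon.label for lf in leaves if lf.taxon.label not in ages]
    if missing:
        raise ValidationError(f"tips without occurrence records: {sorted(missing)}")
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.age = ages[node.taxon.label]
        else:
            node.age = max(c.age for c in node.child_nodes())
    chron = Chronogram(tree, validate=False)
    chron.sync_edge_lengths()
    chron.validate()
    return chron


# ---------------------------------------------------------------------------
# 'Equal' smoothing
# ---------------------------------------------------------------------------

def _node_id(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    from .phylo_io import clade_digest
    return clade_digest(lf.taxon.label for lf in node.leaf_iter())


def _duration(node: dendropy.Node) -> float:
    return node.parent_node.age - node.age


def find_donor_chain(chronogram: Chronogram, zero_branch: dendropy.Node,
                     vartime: float | None = None) -> DonorChain:
    """Identify the donor for a zero-length branch (given by its child node).

    The donor is the nearest strictly-ancestral branch with positive current
    duration, or the virtual root stem (of length ``vartime``) if every
    ancestor branch is zero-length.  ``y`` counts the zero-length branches on
    the path from the donor (exclusive) down to ``zero_branch`` (inclusive).
    """
    if _duration(zero_branch) >= ZERO_LENGTH_THRESHOLD:
        raise ValidationError("branch is not zero-length")
    chain = [zero_branch]
    node = zero_branch.parent_node
    while node.parent_node is not None and _duration(node) < ZERO_LENGTH_THRESHOLD:
        chain.append(node)
        node = node.parent_node
    if node.parent_node is None:
        if vartime is None:
            raise ValidationError(
                "chain reaches the root; a vartime stem length is required"
            )
        donor_id, x = ROOT_STEM, float(vartime)
    else:
        donor_id, x = _node_id(node), _duration(node)
    chain.reverse()  # rootward-first
    y = len(chain)
    return DonorChain(
        donor_id=donor_id,
        donor_duration=x,
        chain_length=y,
        share=smoothing_correction(x, y),
        chain_ids=tuple(_node_id(n) for n in chain),
    )


def _extend_chain_down(top: dendropy.Node) -> list[dendropy.Node]:
    """Greedily extend a zero-length chain downward from its topmost branch.

    At each step the first child (input order) whose branch is currently
    zero-length continues the chain; extension stops at a tip or when no
    child branch is zero-length.
    """
    chain = [top]
    node = top
    while True:
        nxt = None
        for child in node.child_nodes():
            if _duration(child) < ZERO_LENGTH_THRESHOLD:
                nxt = child
                break
        if nxt is None:
            return chain
        chain.append(nxt)
        node = nxt


def calibrate_equal(topology: dendropy.Tree,
                    occurrences: Sequence[OccurrenceRecord] | Mapping[str, float],
                    params: SmoothingParams | float = SmoothingParams()) -> Chronogram:
    """'Equal' temporal smoothing of the strict calibration.

    Runs :func:`calibrate_basic` first, then resolves zero-length chains in
    preorder as described in the module docstring.  The returned chronogram
    carries a ``smoothing_log`` listing every :class:`DonorChain` resolution
    in the order applied; within each resolution the donor's new duration
    plus the chain's new durations equal the donor's old duration plus the
    chain's old durations (time is moved, never created), and the root moves
    older by at most ``vartime`` in total.
    """
    if not isinstance(params, SmoothingParams):
        params = SmoothingParams(vartime=float(params))
    chron = calibrate_basic(topology, occurrences)
    tree = chron.tree
    stem_remaining = params.vartime
    log: list[DonorChain] = []

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if _duration(node) >= ZERO_LENGTH_THRESHOLD:
            continue
        # maximal consecutive zero-length chain through this branch: walk up
        # to the nearest positive ancestor, then greedily down
        top = node
        up = node.parent_node
        while up.parent_node is not None and _duration(up) < ZERO_LENGTH_THRESHOLD:
            top = up
            up = up.parent_node
        chain = _extend_chain_down(top)
        donor_child = top.parent_node  # child end of the donor branch
        if donor_child.parent_node is None:
            donor_id, x = ROOT_STEM, stem_remaining
        else:
            donor_id, x = _node_id(donor_child), _duration(donor_child)
        y = len(chain)
        z = smoothing_correction(x, y)
        # bottom of the chain keeps its age; everything above slides older
        anchor = chain[-1].age
        for i, member in enumerate(chain):
            # member i (0-based from the top) sits i+1 shares above the anchor
            member.age = anchor + (y - 1 - i) * z
        if donor_id == ROOT_STEM:
            donor_child.age = anchor + y * z
            stem_remaining = z
        else:
            donor_child.age = anchor + y * z
        log.append(
            DonorChain(
                donor_id=donor_id,
                donor_duration=x,
                chain_length=y,
                share=z,
                chain_ids=tuple(_node_id(n) for n in chain),
            )
        )

    chron.sync_edge_lengths()
    chron.validate()
    chron.smoothing_log = log
    return chron
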