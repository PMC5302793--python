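"""Tree and occurrence-table I/O and the shared data model.

Conventions used throughout the package:

* Node ages are in Ma before present (larger = older).
* Branch durations are in Myr and always equal ``age(parent) - age(child)``.
* A branch is treated as zero-length iff its duration is below
  :data:`ZERO_LENGTH_THRESHOLD` (float-safe strict-calibration arithmetic).
* Polytomies are first-class everywhere; trees are rooted.

Trees are :class:`dendropy.Tree` objects.  A :class:`Chronogram` wraps a
dendropy tree whose every node carries an ``age`` attribute; edge lengths are
kept in sync with the ages.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "ZERO_LENGTH_THRESHOLD",
    "OccurrenceRecord",
    "Chronogram",
    "PhyloIOError",
    "ValidationError",
    "read_tree",
    "tree_from_string",
    "read_occurrences",
    "occurrences_from_frame",
    "write_occurrences",
    "write_chronogram",
    "read_chronogram",
    "write_tree",
    "prune_to_shared",
    "clade_digest",
]

#: Durations below this many Myr are considered zero-length.
ZERO_LENGTH_THRESHOLD = 1e-8


class PhyloIOError(ValueError):
    """Malformed input file (parse failure)."""


class ValidationError(ValueError):
    """Input parsed but violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Occurrence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccurrenceRecord:
    """A taxon's stratigraphic age bounds and derived point age.

    ``point_age`` is the radioisotopic age when one is given, otherwise the
    midpoint of the stratigraphic bounds — the age actually used to place the
    taxon's first appearance on a calibrated tree.
    """

    taxon_label: str
    older_bound: float
    younger_bound: float
    radioisotopic_age: float | None = None
    point_age: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.taxon_label:
            raise ValidationError("occurrence record with empty taxon label")
        if self.younger_bound < 0:
            raise ValidationError(
                f"{self.taxon_label}: younger bound {self.younger_bound} < 0"
            )
        if self.older_bound < self.younger_bound:
            raise ValidationError(
                f"{self.taxon_label}: older bound {self.older_bound} < "
                f"younger bound {self.younger_bound}"
            )
        if self.radioisotopic_age is not None:
            pa = float(self.radioisotopic_age)
            if not (self.younger_bound <= pa <= self.older_bound):
                raise ValidationError(
                    f"{self.taxon_label}: radioisotopic age {pa} outside "
                    f"[{self.younger_bound}, {self.older_bound}]"
                )
        else:
            pa = (self.older_bound + self.younger_bound) / 2.0
        object.__setattr__(self, "point_age", pa)


def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read a delimited occurrence table (CSV or TSV, sniffed by delimiter).

    Required columns: ``taxon``, ``older_bound``, ``younger_bound``; optional
    ``radioisotopic_age`` (blank = absent).  Row order is preserved.
    """
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise PhyloIOError(f"cannot parse occurrence table {path}: {exc}") from exc
    return occurrences_from_frame(frame)


def occurrences_from_frame(frame: pd.DataFrame) -> list[OccurrenceRecord]:
    """Build validated occurrence records from a dataframe."""
    required = {"taxon", "older_bound", "younger_bound"}
    missing = required - set(frame.columns)
    if missing:
        raise PhyloIOError(f"occurrence table missing columns: {sorted(missing)}")
    records: list[OccurrenceRecord] = []
    errors: list[str] = []
    seen: set[str] = set()
    for i, row in frame.iterrows():
        taxon = str(row["taxon"])
        if taxon in seen:
            errors.append(f"row {i}: taxon {taxon!r} repeated")
            continue
        seen.add(taxon)
        radio = None
        if "radioisotopic_age" in frame.columns and pd.notna(row["radioisotopic_age"]):
            radio = float(row["radioisotopic_age"])
        try:
            records.append(
                OccurrenceRecord(
                    taxon_label=taxon,
                    older_bound=float(row["older_bound"]),
                    younger_bound=float(row["younger_bound"]),
                    radioisotopic_age=radio,
                )
            )
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError("invalid occurrence rows: " + "; ".join(errors))
    return records


def write_occurrences(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    """Write occurrence records as CSV (column order fixed)."""
    pd.DataFrame(
        {
            "taxon": [r.taxon_label for r in records],
            "older_bound": [r.older_bound for r in records],
            "younger_bound": [r.younger_bound for r in records],
            "radioisotopic_age": [r.radioisotopic_age for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _raise_parse_error(what: str, exc: Exception) -> None:
    if "Duplicate taxon labels" in str(exc):
        raise ValidationError(f"duplicate tip labels in {what}: {exc}") from exc
    raise PhyloIOError(f"cannot parse {what}: {exc}") from exc


def _validate_tips(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label if lf.taxon else "" for lf in tree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise ValidationError("tree contains unlabeled tips")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")


def read_tree(path: str | Path, format: str | None = None) -> dendropy.Tree:
    """Read a rooted tree from Newick or NEXUS.

    NEXUS ``[&key=value,...]`` node comments (posterior probabilities, HPD
    interval bounds, ...) are captured into each node's ``annotations``.
    The format is inferred from the file extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".trees", ".tre"} else "newick"
    if format not in {"newick", "nexus"}:
        raise ValueError(f"unsupported tree format: {format!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema=format,
            extract_comment_metadata=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, dendropy.dataio.tokenizer.Tokenizer.UnexpectedEndOfStreamError) as exc:
        _raise_parse_error(f"{format} file {path}", exc)
    tree.is_rooted = True
    _validate_tips(tree)
    return tree


def tree_from_string(text: str, format: str = "newick") -> dendropy.Tree:
    """Parse a tree from a string (same semantics as :func:`read_tree`)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=format,
            extract_comment_metadata=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, dendropy.dataio.tokenizer.Tokenizer.UnexpectedEndOfStreamError) as exc:
        _raise_parse_error(f"{format} tree", exc)
    tree.is_rooted = True
    _validate_tips(tree)
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path, format: str = "newick") -> None:
    """Write a tree; annotations are emitted as [&...] comments in NEXUS only."""
    if format == "newick":
        tree.write(path=str(path), schema="newick", suppress_annotations=True,
                   unquoted_underscores=True, suppress_rooting=True)
    elif format == "nexus":
        tree.write(path=str(path), schema="nexus", suppress_annotations=False,
                   unquoted_underscores=True)
    else:
        raise ValueError(f"unsupported tree format: {format!r}")


def clade_digest(tip_labels: Iterable[str]) -> str:
    """Stable short digest identifying a clade by its descendant tip set."""
    joined = "|".join(sorted(tip_labels))
    return hashlib.sha1(joined.encode()).hexdigest()[:12]


def _tip_labels_below(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


# ---------------------------------------------------------------------------
# Chronograms
# ---------------------------------------------------------------------------

class Chronogram:
    """A rooted tree whose every node carries an absolute age (Ma).

    Ages live on ``node.age``; edge lengths are durations in Myr and are kept
    equal to the parent/child age difference by :meth:`sync_edge_lengths`.
    """

    def __init__(self, tree: dendropy.Tree, validate: bool = True):
        self.tree = tree
        #: per-resolution smoothing log, populated by the 'equal' calibration
        self.smoothing_log: list = []
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_ages(cls, tree: dendropy.Tree, ages: Mapping[frozenset, float] | Mapping[str, float]) -> "Chronogram":
        """Attach ages given by clade tip-set (internal nodes) or tip label."""
        for node in tree:
            if node.is_leaf():
                key: object = node.taxon.label
            else:
                key = _tip_labels_below(node)
            if key not in ages:
                raise ValidationError(f"no age provided for node {key}")
            node.age = float(ages[key])  # type: ignore[index]
        chron = cls(tree, validate=False)
        chron.sync_edge_lengths()
        chron.validate()
        return chron

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        for node in self.tree:
            if getattr(node, "age", None) is None:
                raise ValidationError("chronogram node without an age")
            for child in node.child_nodes():
                if child.age > node.age + 1e-9:
                    raise ValidationError(
                        f"child age {child.age} exceeds parent age {node.age}"
                    )

    def sync_edge_lengths(self) -> None:
        """Set every edge length to the parent-child age difference."""
        for node in self.tree:
            parent = node.parent_node
            if parent is not None:
                node.edge.length = parent.age - node.age

    # -- queries ----------------------------------------------------------

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def tip_ages(self) -> dict[str, float]:
        return {lf.taxon.label: float(lf.age) for lf in self.tree.leaf_node_iter()}

    def node_ages(self) -> dict[frozenset[str], float]:
        """Ages of all internal nodes keyed by descendant tip set."""
        return {
            _tip_labels_below(nd): float(nd.age)
            for nd in self.tree.preorder_node_iter()
            if not nd.is_leaf()
        }

    def durations(self) -> dict[frozenset[str], float]:
        """Branch durations keyed by the child-end clade (tip sets of size 1 for terminals)."""
        out: dict[frozenset[str], float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out[_tip_labels_below(node)] = float(node.parent_node.age - node.age)
        return out

    def clone(self) -> "Chronogram":
        c = Chronogram(self.tree.clone(depth=1), validate=False)
        return c


def write_chronogram(chronogram: Chronogram, newick_path: str | Path,
                     ages_path: str | Path | None = None) -> None:
    """Write a chronogram as Newick (durations) plus a node-age sidecar TSV.

    The sidecar maps every node (stable preorder id + clade digest) to its
    age in Ma; tips are included so the file alone suffices to re-anchor the
    Newick durations on the absolute timescale.
    """
    for lf in chronogram.tree.leaf_node_iter():
        if lf.taxon is None or not lf.taxon.label:
            raise ValidationError("chronogram has unnamed tips; cannot write")
    chronogram.sync_edge_lengths()
    newick_path = Path(newick_path)
    if ages_path is None:
        ages_path = newick_path.with_suffix(".ages.tsv")
    write_tree(chronogram.tree, newick_path, format="newick")
    rows = []
    for i, node in enumerate(chronogram.tree.preorder_node_iter()):
        tips = _tip_labels_below(node)
        rows.append(
            {
                "node_id": f"n{i}",
                "clade_digest": clade_digest(tips),
                "n_tips": len(tips),
                "tip_labels": ";".join(sorted(tips)) if len(tips) <= 1 else "",
                "is_leaf": int(node.is_leaf()),
                "age_ma": repr(float(node.age)),
            }
        )
    pd.DataFrame(rows).to_csv(ages_path, sep="\t", index=False)


def read_chronogram(newick_path: str | Path, ages_path: str | Path | None = None) -> Chronogram:
    """Read back a chronogram written by :func:`write_chronogram`.

    Ages are reconstructed from the recorded root age and the Newick
    durations, so they reproduce the written ages exactly up to float
    formatting.
    """
    newick_path = Path(newick_path)
    if ages_path is None:
        ages_path = newick_path.with_suffix(".ages.tsv")
    tree = read_tree(newick_path, format="newick")
    table = pd.read_csv(ages_path, sep="\t")
    root_age = float(table.iloc[0]["age_ma"])
    tree.seed_node.age = root_age
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.age = node.parent_node.age - (node.edge.length or 0.0)
    return Chronogram(tree)


# ---------------------------------------------------------------------------
# Pruning to a shared tip set
# ---------------------------------------------------------------------------

def _prune_one(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    has_ages = all(getattr(nd, "age", None) is not None for nd in tree)
    pruned = tree.extract_tree_with_taxa_labels(labels=sorted(keep))
    pruned.is_rooted = True
    for node in pruned:
        src = getattr(node, "extraction_source", None)
        if src is not None:
            for ann in src.annotations:
                node.annotations.add_new(ann.name, ann.value)
    if has_ages:
        # ages of retained nodes are unchanged; degree-2 suppression keeps
        # the deeper (younger-side) node of each collapsed path, whose source
        # reference carries the right age
        for node in pruned:
            node.age = node.extraction_source.age
        chron_like = Chronogram(pruned, validate=False)
        chron_like.sync_edge_lengths()
    # drop back-references so pruned trees do not pin their source in memory
    for node in pruned:
        if hasattr(node, "extraction_source"):
            del node.extraction_source
    return pruned


def prune_to_shared(tree_a: dendropy.Tree | Chronogram,
                    tree_b: dendropy.Tree | Chronogram):
    """Restrict two trees to their shared tip set.

    Degree-2 nodes created by pruning are suppressed with durations composed
    along the collapsed path; node ages (when present) are unchanged for
    retained nodes.  Returns objects of the same kinds as the inputs.
    """
    raw_a = tree_a.tree if isinstance(tree_a, Chronogram) else tree_a
    raw_b = tree_b.tree if isinstance(tree_b, Chronogram) else tree_b
    tips_a = {lf.taxon.label for lf in raw_a.leaf_node_iter()}
    tips_b = {lf.taxon.label for lf in raw_b.leaf_node_iter()}
    shared = tips_a & tips_b
    if len(shared) < 2:
        raise ValidationError(
            f"only {len(shared)} tip(s) shared between trees; need at least 2"
        )
    out_a = _prune_one(raw_a, shared)
    out_b = _prune_one(raw_b, shared)
    if isinstance(tree_a, Chronogram):
        out_a = Chronogram(out_a)
    if isinstance(tree_b, Chronogram):
        out_b = Chronogram(out_b)
    return out_a, out_b
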