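# Methods

This note records the modelling choices, conventions and caveats behind the
package. It is aimed at a reader who wants to know exactly what the numbers
mean, not how to call the API.

## Occurrence data and time conventions

All ages are in Ma before present; larger is older. An occurrence record
carries an older and a younger stratigraphic bound and an optional
radioisotopic date. The *point age* used in every calculation is the
radioisotopic date when present, otherwise the interval midpoint. Binning a
known age into stratigraphic bins of width *w* uses bins `[k·w, (k+1)·w)`
closed at the young edge, so the point age is always within *w*/2 of the true
age.

## Strict ghost-lineage calibration (GLA)

Each internal node receives the maximum point age over its descendant tips,
computed in postorder. Properties:

- Node ages are minimum estimates: the true divergence can only be older.
- Whenever a tip is the oldest in several nested clades, all nodes on that
  path receive the same age, producing zero-length internal branches and a
  zero-length terminal branch for the tip itself.
- *Ghost lineage* of a taxon means the duration of its terminal branch on
  this chronogram: time the lineage must have existed without a fossil
  record. Internal-branch durations are reported separately; summaries give
  both the per-taxon (terminal) and the all-branches view.

## Equal temporal smoothing (sGLA)

Zero-length branches (duration below 1e-8 Myr) are resolved by borrowing
time from below:

1. Walk the tree in preorder. At the first zero-length branch, find the
   maximal chain of zero-length branches it belongs to: extend upward while
   parents are zero-length, then downward through zero-length children
   (first such child in child order).
2. The *donor* is the branch immediately below the chain top — or, if the
   chain abuts the root, the stem reservoir of duration `vartime` supplied
   by the user.
3. A donor of duration *x* over a chain of *y* branches gives every
   participant exactly *z = x / (y + 1)*: the chain's bottom node keeps its
   (tip-anchored) age, every node above it slides older by cumulative
   multiples of *z*, and the donor keeps *z* itself.
4. Stem donations consume the reservoir: after donating, the remaining stem
   is *z*, so repeated root-adjacent chains draw geometrically shrinking
   shares and the root never rises more than `vartime` above its strict age.

Consequences worth knowing:

- Tip ages are immutable; smoothed node ages are never younger than strict
  ones; sibling branches of a lifted chain are stretched passively (their
  child ends do not move, their parent end does), so the *sum* of branch
  durations is not conserved — the conserved quantity is per-resolution:
  the donor's old duration *x* equals *z·(y + 1)* exactly, and total root
  growth equals the consumed stem.
- Resolution order is preorder, so when two sibling chains compete for the
  same donor the left one draws first. This is an arbitrary but deterministic
  convention; the alternative (proportional splitting among sibling chains)
  would complicate the exact share law.
- An alternative reading of "equal" smoothing resolves one branch at a time
  against the donor's *current* duration (giving shares x/2, x/4, … down a
  chain). We resolve whole maximal chains at once because only that choice
  reproduces the stated share law z = x/(y+1) for every chain member and
  keeps the result independent of within-chain traversal order.
- `vartime` defaults are a scientific choice, not a fitted quantity. Across
  vartime ∈ {1, 5, 10} Myr, node-age rank order on simulated data is
  essentially preserved (Spearman ρ > 0.95); only stem-adjacent nodes move
  differently.

## Ghost-lineage diagnostics

Branch-duration tables carry, per branch: the child clade, duration in Myr
and whether it is terminal. Threshold summaries count branches exceeding
25/50/65/75 Myr by default (ascending thresholds enforced), for terminal
branches and for all branches.

## Node-age comparison

Trees dated by different methods are pruned to their shared taxa, clades are
keyed by their tip sets, and only clades present in all trees are compared.
Corrections are differences to a designated base method (default the strict
tree). Summaries report mean and median corrections per method, pairwise
percentage ratios of those statistics (raw and rounded to the nearest 10%),
and the fraction of nodes dated younger by one method than another. All
summary statistics are plain recomputations of the flattened comparison
table; an acceptance test asserts the equality exactly.

## Parsimony metrics

Tree length is computed per character by Sankoff dynamic programming (unit
cost for unordered characters, |i−j| for ordered), which handles polytomies,
missing data ('?' and gaps, treated identically since the matrices are
morphological) and polymorphic cells (the leaf may take any member state).
The minimum conceivable steps *m* use a minimal-hitting-set construction for
unordered characters with polymorphism and the max-of-minima minus
min-of-maxima range for ordered ones; the maximum *g* is the star-tree
length. CI = Σm/S includes uninformative characters by default (a variant
excludes them); RI = (Σg − S)/(Σg − Σm) is computed over informative
characters only (g > m), with the tree-length sum restricted accordingly,
and is NaN when no character is informative. Dialects: NEXUS (with
ASSUMPTIONS/TYPESET ordering) and TNT (`xread`, `ccode` with +/− ranges).

## The BDSS simulator

Forward simulation in Ma coordinates from a single origin lineage at
`origin_time`: constant birth rate λ (symmetric/cladogenetic splitting),
death rate μ, and fossil-sampling rate ψ per lineage-Myr. ψ may be piecewise
constant in time; sampling uses thinning against the dominating rate through
a single code path, so a zero-width gap is byte-identical to the constant
case at the same seed.

OTU semantics: an OTU is a *terminal edge* of the true tree that received at
least one fossil sample; its FAD is the oldest sample on that edge, and its
point age comes from midpoint binning of the FAD (bin width configurable,
default 10 Myr). Samples on internal edges are counted but do not create
OTUs. These semantics make two statements exact theorems rather than
approximations: the true age of every observed clade is at least its
strict-calibrated age minus half a bin, and denser sampling can only move
FADs older. The cost is realism: real taxa are stratigraphic ranges that may
span cladogenesis; a paraphyletic "ancestor" sampled on an internal edge is
not represented.

Defaults (λ = 0.03, μ = 0.015, ψ = 0.02, origin 250 Ma, 10–200 OTUs by
accept–reject) produce trees of a few dozen OTUs spanning most of the
simulation with sampling sparse enough that ghost lineages are common.
Determinism contract: one NumPy `default_rng(seed)` stream drives growth,
sampling and rejection; identical config + seed gives byte-identical output.

## The sampling-gap experiment

`run_gap_experiment` compares, over paired replicates, a constant-ψ control
against the same simulation with ψ = 0 inside a 30-Myr window
(`scenario_uneven`). Pairs share the seed and — because both arms run
without accept–reject and thinning consumes the same random draws regardless
of acceptance — the *same true tree*; they differ only in which fossils are
retained. Replicates are selected solely by dataset size (control 10–200
OTUs, gap arm ≥ 3), never by the compared statistics.

The experiment regime (λ = 0.10, μ = 0.08, ψ = 0.3, 80-Myr history, gap at
45–15 Ma, 2-Myr bins) was chosen so that the gap's mechanism is actually
active: high turnover spreads extinct taxa — and hence calibration anchors —
across the whole timescale, and sampling is dense enough that lineages
crossing the gap stay observed instead of disappearing. At sparser settings
the dominant effect of a gap is taxon loss, which tells one nothing about
ghost lineages.

Findings, reproduced by `analysis/06_sampling_experiments.py`:

- In aggregate over 200 pairs the gap lengthens mean terminal ghost
  durations (1.31 → 1.69 Myr) and enlarges mean smoothing corrections
  (5.75 → 8.14 Myr).
- Per pair the effect is noisy: only ~53% of pairs show both increases
  simultaneously (64% for ghosts, 85% for corrections). The reason is
  structural, not statistical: strict calibration carries no external time
  anchor, so deleting fossils *also* deflates node ages tree-wide, and in a
  growing birth–death tree a late-appearing taxon's sister is usually also
  late-appearing, so a shifted FAD often drags its own parent node down with
  it. The robust per-pair signal sits on internal (stem) branches and on the
  smoothing corrections, not on the per-taxon terminal means. A claim that
  nearly every paired replicate shows longer mean terminal ghosts would be
  wrong under this model; only the aggregate direction is a property of the
  method.

## Numerical conventions

- Zero-length threshold 1e-8 Myr everywhere.
- Clade keys are frozensets of tip labels; clade digests in sidecar files
  are the first 12 hex digits of the SHA-1 of the sorted labels.
- Chronogram files are Newick (durations) plus a TSV sidecar of node ages;
  reading reconstructs ages from the root age and durations, reproducing the
  written ages exactly up to float formatting.
- Monte-Carlo acceptance checks use 3-standard-error tolerances around
  closed-form expectations (Poisson sampling counts; e^{(λ−μ)t} surviving
  lineages).
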