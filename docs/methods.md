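# Methods

This note documents the models, conventions and numerical choices
behind `phylopart`, in the spirit of a statistical software appendix:
what is computed, under which assumptions, which knobs matter, and what
the synthetic calibration experiments do and do not establish.

## Parsimony scoring

Characters are discrete (digit states 0–9) and are scored on a fixed
leaf-labelled topology by dynamic programming over ancestral state
assignments (Sankoff). Two cost regimes are supported:

* **unordered** — any change costs 1 (Fitch counting);
* **ordered** — changing between integer states *i* and *j* costs
  |i − j| (linear / Wagner ordering). With two states the linear cost
  reduces to the unit cost, and the two regimes agree (tested).

Conventions, chosen where matrices in the wild are ambiguous:

* **Missing** (`?` and `-` alike) contributes no constraint: the cell
  may take any state at zero cost.
* **Polymorphic** cells `(01)`/`{01}` use union semantics: the cell may
  be resolved to any member. The same semantics apply in the step
  bounds: `m` minimizes over resolutions (smallest hitting set for
  unordered, minimal achievable span for ordered), `g` resolves
  adversarially-optimally on the star tree.
* **Polytomies** are scored as hard polytomies — the DP runs on the
  multifurcating topology as given; literature reference trees are
  routinely incompletely resolved.

Step bounds per character: `m` = minimum steps over all trees
(unordered: one less than the smallest state set hitting every cell;
ordered: the minimal state span), `g` = maximum steps = the star-tree
length (unordered: non-missing cells minus the best single-state count;
ordered: the weighted-median cost). Retention index
`ri = (g − s)/(g − m)` is defined only for parsimony-informative
characters (`g > m`); ensemble `RI` uses summed terms over informative
characters only, because uninformative ones have undefined `ri` and
would silently distort the sums.

The general scorer is vectorized numpy; the search hot path uses
numba-compiled kernels (bitmask Fitch for unordered characters, a
small-K Sankoff for ordered ones) over a rooted-array tree
representation. Both paths are cross-checked against each other and
against exhaustive enumeration of internal labelings in the tests.

## Tree search

Heuristic maximum-parsimony search follows the classic recipe:
stepwise random-addition starting trees, steepest-descent hill climbing
under a configurable rearrangement neighbourhood (NNI, SPR or TBR), and
a final plateau walk that collects every distinct topology tied at the
best length, deduplicated by bipartition set, up to `max_trees`
(`capped` is flagged when the store limit is hit, since truncated MPT
sets bias the IRD statistic — the cap is recorded in the run audit).
Defaults (`n_starts=10`, SPR, `max_trees=100`) are desk-scale choices;
the calibration and power experiments use a lighter documented battery
configuration (`n_starts=2`, NNI, `max_trees=12`) — under the
permutation null this only trades statistical sharpness, not validity,
because observed and null repartitions are searched identically.

Two deliberate design choices: zero-length branches are *not*
collapsed (keeping RF distances between binary MPTs well defined), and
the SPR neighbourhood omits moves that prune the subtree containing the
root leaf of the array representation (random-addition restarts
compensate; the NNI neighbourhood is complete, and TBR — implemented by
explicit bisection/reconnection — subsumes the omitted moves).
Exhaustive enumeration (guarded to ≤ 9 taxa, `(2n−5)!!` topologies) is
provided both as an exact search and as the oracle used to validate the
heuristic.

## Partition homogeneity (ILD, IRD)

Both tests permute the assignment of pooled characters to the two
partitions, preserving the original sizes exactly (sampling without
replacement). Parsimony-uninformative characters are excluded from the
pool by default (the classic ILD recommendation; a switch retains
them). P-values use the add-one rule `(b + 1)/(R + 1)` with *b* the
count of null replicates at or beyond the observed value — always
valid, never zero. Tails are one-sided in the incongruence direction:
lower for ILD (incongruent partitions shorten their within-partition
optima), upper for IRD. The IRD nearest-neighbour statistic pools both
directions (A→B and B→A) by default, making it symmetric; a
single-direction variant is available for sensitivity analysis. Each
replicate draws from an independent seed substream, so results are
reproducible regardless of execution order, and both statistics can be
computed from one set of shared searches (`partition_homogeneity_tests`)
without changing either test's null distribution.

**Discreteness caveat.** The ILD statistic is a sum of two integer tree
lengths. At small matrix sizes its permutation null concentrates on few
distinct values (typically 7–14 at 12 taxa with 30+30 characters in the
calibration experiments), with substantial tie mass at the observed
value. Under the at-or-beyond convention this makes the ILD p-value
conservative (super-uniform): its empirical type-I rejection at
α = 0.05 runs well below 0.05 in the calibration experiment, while the
near-continuous IRD statistic calibrates close to nominal. This is a
property of the statistic at these data sizes, not of the
implementation (lengths are verified against exhaustive enumeration);
on large matrices the statistic's support widens and the conservatism
shrinks.

## Molecular consistency

Characters are optimized onto an independent reference tree taken as a
fixed benchmark (the package never infers trees from sequences). Order
of operations matters and is enforced: taxa absent from the reference
are excluded *first*, then `m` and `g` are recomputed on the pruned
taxon set, then characters uninformative on that set (invariant or
autapomorphic) are dropped, and only then are `ri`/`RI` computed.
Datasets sharing fewer than 10 taxa with their reference are excluded
(the threshold is configurable). The hard/soft contrast within a
dataset uses a two-sided MWW test: exact by enumeration when the pooled
sample is ≤ 20 without ties, otherwise the normal approximation with
mid-ranks, tie-corrected variance and continuity correction; an
all-tied sample (e.g. every `ri` = 1) carries no rank information and
returns p = 1. Because `ri` comparisons are made within datasets, taxon
and character counts cancel; the direction of the difference is
reported separately as `RI_hard − RI_soft`.

## Meta-analysis

Fisher's combined probability (`X² = −2 Σ ln p`, df = 2k) treats
datasets as independent — a documented assumption, reasonable for
separately published matrices. Permutation p-values are bounded below
by `1/(R+1)` by construction, so `log p` is always finite. Clade-level
families use a Bonferroni threshold `α/k` (reported with a
two-significant-figure rendering; nine families at α = 0.05 give
0.0056). The "mixed ANOVA" of partition type × clade with repeated
measures over datasets is realized as the difference-score reduction:
with a two-level within factor, the clade effect on `d = RI_hard −
RI_soft` computed by a one-way ANOVA is exactly the clade × partition
interaction of the full decomposition, and the paired main effect is a
one-sample t-test of mean `d`. Full multi-stratum decompositions are
out of scope.

## Synthetic data generator

The generator emulates the structure of a published morphological
dataset, not its biology:

* topology uniform over labelled unrooted binary trees (stepwise
  addition with uniform edge choice, which is a bijection onto
  topologies); branch lengths exponential, rescaled to unit mean
  root-to-tip depth so `rate` reads as expected changes per character
  along an average lineage;
* characters i.i.d. under a symmetric k-state Markov process simulated
  event-by-event (Poisson substitutions, uniform target state), so
  realized change counts can be checked against `rate × tree length`;
* incongruence injected by evolving the hard partition on a tree a
  controlled number of SPR moves from the soft partition's tree;
  reference-tree error likewise by SPR distortion from the soft tree;
* missing data masked completely at random with partition-specific
  rates (taphonomic loss concentrates in soft anatomy, so the soft rate
  is the one usually raised);
* a `perfect` character model (exactly one change on one internal
  edge) provides homoplasy-free data for parameter-recovery checks.

Defaults — 12 taxa, 30 + 30 characters, 3 states, rate 1.0, no
incongruence, no masking — describe a modest published matrix and are
the study conditions of the calibration experiments. What passing
calibration shows: the permutation machinery attains (at most) nominal
type-I error and responds monotonically to injected incongruence under
a clean exchangeable null. What it does not show: robustness to
correlated characters, modular rate variation, non-random missingness
within partitions, or reference trees with topological error
concentrated in particular clades — real-data features the generator
deliberately omits.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale:
exhaustive oracles up to 7–8 taxa, 200 calibration datasets and 100
power datasets at 12 taxa with 199 permutation replicates, and
collection demos of 4–6 datasets. Determinism is end-to-end: one master
seed fans out through named `SeedSequence` substreams to dataset
generation, every search, and every permutation, and rerunning a
collection with the same seed reproduces the results table
byte-for-byte. Degenerate inputs are handled explicitly: all-missing
columns score zero and are uninformative; a repartition side with no
informative characters has the same optimal length on every topology
(its length is computed analytically and its contribution to the IRD
nearest-neighbour distance is zero); all-tied MWW inputs and zero
within-variance ANOVAs are reported as p = 1 and not-available
respectively rather than erroring.

## Known limitations

* Heuristic searches at noisy small sizes can return capped or
  incomplete MPT sets; the IRD statistic inherits that noise
  symmetrically between observed and null, but audit fields
  (`score`, `n_trees`, `capped`) should be checked before interpreting
  a single dataset's IRD in isolation.
* The ILD conservatism described above means its desk-scale power and
  size are both understated relative to large matrices.
* Step matrices other than uniform and linear-ordered (e.g. custom
  transition costs) are not supported; differential character weights
  are not supported.
* Reference trees are consumed as fixed topologies; their uncertainty
  is not propagated.
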