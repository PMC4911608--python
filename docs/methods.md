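# Methods

This note documents the models, conventions and numerical choices behind
`apoclass`, in the package's own words.

## Data model

The substrate is a taxa × columns amino-acid matrix (1-based, closed
intervals for gene blocks) on a fixed rooted topology with a designated
outgroup. Three non-residue symbols are kept distinct in storage — `-`
(alignment gap), `X` (missing residue inside a sequenced gene), `?`
(whole gene segment absent) — because the identification stage reports
the provenance of missing states. The parsimony engine treats all three
as non-constraining missing data. Unknown letters in input alignments are
mapped to `X` with a logged warning rather than rejected: real
supermatrices contain B/J/Z/U and similar symbols whose identity is not
informative here.

Taxa present in the tree but absent from the matrix are pruned by default
(configurable to an error); matrix taxa absent from the tree always
raise, since reconstruction would silently ignore their data.

## Parsimony reconstruction

Per column the engine computes, under unweighted parsimony with the
topology held fixed:

* the tree length *s* (minimum number of state changes);
* exact per-node **MPR sets** — the states a node takes in at least one
  most-parsimonious reconstruction — via the unit-cost inside/outside
  dynamic program (subtree cost plus outside cost per state). On
  bifurcations this coincides with Fitch's set operations; on polytomies
  it is the exact generalization (equivalent to Hartigan's counts). We
  chose the exact DP over iterated pairwise Fitch intersections because
  the latter can overcount length at polytomies, and the package's test
  contract is agreement with exhaustive enumeration on every topology.
  The alphabet is restricted to the states observed at the column; for
  unit costs an unobserved state never appears in an MPR, which the test
  oracle verifies by enumerating with one extra state.
* a single **DELTRAN** assignment, resolved in pre-order: the root takes
  the alphabetically smallest MPR state that also occurs among the
  outgroup leaves at the column (falling back to the smallest MPR state);
  every other node inherits its parent's state whenever its own MPR set
  allows, otherwise it takes the alphabetically smallest member of
  (MPR ∩ down-pass set), falling back to the smallest MPR state.
  Inheriting whenever possible delays changes toward the tips — the
  defining DELTRAN behaviour — and the alphabetical rule makes the output
  byte-for-byte deterministic. The assignment is always a true MPR (its
  edge differences sum to *s*); in rare ties the alphabetical choice may
  not be the single most tip-heavy MPR, a documented tie-break rather
  than a correctness issue.

**Root polarization.** With a single outgroup leaf, unrooted parsimony
often leaves the root MPR set two-state for a clean ingroup-wide
apomorphy (the change could equally sit on the outgroup stem). Because
the tree is explicitly rooted on the outgroup, the root is considered
resolved whenever the outgroup's observed states pin a unique member of
its MPR set; without this, no root-level clade could ever be coded.
Ambiguity elsewhere is defined as an MPR set with more than one state at
either endpoint of a change; such changes are flagged and dropped before
filtering.

Changes on edges leading into outgroup taxa are never apomorphy
candidates; the edge from the root into the ingroup is (it diagnoses the
root-most coded clade).

**Consistency index.** CI = (k − 1)/s with k the number of distinct
non-missing states at the column (the Kluge–Farris minimum conceivable
changes for an unordered character; missing symbols excluded from k).
Invariant columns have no defined CI and carry no apomorphies. CI
comparisons against thresholds are done in exact rational arithmetic, so
a column with 9 changes over 10 states passes a 0.9 threshold exactly.

## Screening and selection

Defaults: `max_missing_fraction = 0.5`, `min_clade_taxa = 2`,
`codes_per_clade = 1`, multistate codes allowed. The missing-fraction cap
operationalizes "missing taxa should be limited", which the source
methodology states without a number; it is an explicit knob, logged with
every run. The "basal lineage" whose total absence disqualifies a
candidate is taken to be the child lineage of the coded clade with the
fewest sampled leaves (ties broken by child order) — the ladderized
"basal" side — since on a rooted bifurcation all children branch
simultaneously and some convention is required.

Priority classes: `unique` (derived state absent everywhere outside the
clade at that column) > `clade_unique` (recurs outside but not in the
sister group, carriers uniform) > `multistate_trend` (exactly two carrier
states, each uniform within one child subclade — the binary `|T/V|`
pattern). Three or more per-subclade-uniform states are rejected: a code
carries at most two states. Within a class, candidates with fewer missing
clade members rank first, then genes covering more matrix taxa
(gene breadth), then lexicographic (gene, site) for determinism. Gene
economy — preferring markers already used by other clades — applies only
on exact ranking ties, as a preference rather than a constraint.

## Coding and barcodes

IDs are two-character base-36 tokens assigned densely in pre-order over
coded nodes, optionally carrying a one-letter dataset prefix for
secondary (nested) databases. Sparse numbering is accepted on input so
published code tables load verbatim. The barcode serialization is
`<state>_<id>_` repeated; the parser is its exact inverse and applies one
normalization: a single-character ID token is interpreted as missing its
leading "1" (the one malformed token in the embedded fixture), logged.
Binary codes display compactly as `|T/V|`; in per-terminal designed
barcodes a binary code resolves to the state of the child lineage the
terminal descends through. A designed binary state matches an observed
token iff the token is in the state set.

The code database is a trie: terminal categories are coded nodes without
coded descendants, each with a designed barcode that provably has every
ancestor's barcode as a prefix, and with IDs strictly increasing along
every root-to-leaf path.

## Identification

A query observation holds one token per database code. The matcher walks
the trie from the root: a child clade is matched when its token is in the
code's state set, excluded on any contradicting residue (no fuzzy
matching — a single wrong amino acid vetoes the branch), and skipped on
`X`/`?`, in which case deeper codes discriminate among children: a branch
counts only if something inside it is positively confirmed. The assigned
clade is the deepest node whose own code matched non-missing with no
non-missing mismatch on its path. When two branches under a missing code
are both confirmed deeper (contradictory evidence, possible only with
conflicting data), the walk stops at the last unambiguously confirmed
node rather than guessing a ranking.

Codes absent from an observation altogether (e.g. off-lineage codes in
published query-test tables, which list only the true lineage) are
"unknown": they can never confirm a clade but do not exclude it. This is
what makes zero false positives a checkable property of such tables.

Categories against a truth label: `positive` (assigned = true terminal),
`false_positive` (a different terminal), `false_negative` (stopped above
terminal level with only missing states on the remaining true path),
`negative` (a non-missing mismatch on the true path). A complete match
additionally has every code on the true path matched non-missing.

With code redundancy (`codes_per_clade > 1`) a clade is judged matched
when at least half of its non-missing codes match and missing only when
all are missing — a majority rule consistent with using redundant codes
to absorb rare single-site variants.

## Synthetic data

The generator emulates the features the pipeline depends on: a known
rooted topology (balanced, caterpillar or random; one outgroup leaf), a
gene-partitioned alignment whose background columns are fully conserved,
and one planted apomorphy per internal ingroup clade by default. Default
study conditions: 32 ingroup taxa, balanced shape, 10 genes × 50 columns,
homoplasy and missingness off. Conserved backgrounds make planted CI
values analytic: 1 without homoplasy, and exactly 0.5 when the
convergence process re-derives the state in one outside leaf. A
`background_noise` option adds low-rate random substitutions for stress
tests. Missingness applies the two observed processes — whole-gene
absence (`?`) per (taxon, gene) and residue-level masking (`X`) per
surviving cell — with recorded masks.

What passing synthetic tests do **not** show: real supermatrices have
non-conserved backgrounds, alignment error, rate heterogeneity and
non-random missingness, so recovery there depends on the CI filter and
screening criteria in ways the clean generator does not probe. The noisy
options exercise the machinery but are not a substitution-model
simulation.

## Problem sizes and verification

The test suite checks the parsimony engine (lengths, MPR sets, DELTRAN
finals, change lists, CI) against exhaustive enumeration over all
internal labelings on 200 random trees of 4–8 leaves, two variable
columns each, with missing data; the enumeration oracle is vectorized but
conceptually a plain brute force, independent of the dynamic program.
End-to-end checks run at the default 32-taxon scale. The embedded
51-transcriptome query test is evaluated in full; its category counts
(48 positive, 3 false-negative, 0 false-positive, 0 negative), its
per-row assignments, and the order-level coverage of the positives (18
orders) are all recomputed, not stored. One discrepancy in the printed
fixture is preserved rather than corrected: one row whose generated and
designed barcodes are identical is not starred as a complete match in the
printed table, so the matcher reports 6 complete matches where the table
stars 5; tests assert the computed set is a superset of the starred one.

## Known limitations

* DELTRAN tie-breaking is one deterministic convention among several a
  parsimony program might use; apolists from other implementations can
  differ at ambiguous or tied sites, so absolute apomorphy counts on
  external datasets are not expected to replicate exactly.
* Polytomies are handled exactly by the DP, but coding a polytomous clade
  still selects a single diagnostic per node; no attempt is made to
  resolve the polytomy.
* The identification walk assumes codes are conditionally independent
  given the lineage; correlated loss (e.g. one missing gene carrying many
  codes) degrades resolution exactly as missing genes do in real
  transcriptomes.
* Orthology prediction, alignment, masking and tree inference are out of
  scope: queries must arrive pre-aligned to the database gene blocks.
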