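# Methods

## The problem

Copepoda (~14,500 described species) contains free-living plankton and
benthos alongside thousands of parasites, but only a few percent of its
species have ever been placed in a molecular phylogeny, scattered across
dozens of small single-to-few-marker studies with little taxon overlap.
`copsynth` implements the *synthesis tree* route to a comprehensive
phylogeny: published rooted trees are decomposed into grouping
constraints and grafted together by study rank; every species never
sampled in a phylogeny is then attached from the reference taxonomy as a
polytomy; and a binary free-living/parasitic character is mapped onto
the result with parsimony to count and classify independent origins of
parasitism.

## Ranked synthesis

Each internal non-root node of a source tree yields one **grouping**:
the set of tips below it (ingroup) against the study's remaining tips
(exclude).  Two groupings conflict when each ingroup invades the other's
exclude while the ingroups overlap — precisely when no rooted tree can
display both.  Groupings are accepted greedily in study-rank order
(preorder within a study), skipping any grouping that conflicts with an
already-accepted, higher-ranked one; each skip is logged with the
winning rank.

The tree is then constructed jointly from the accepted set by a
BUILD-style subproblem decomposition: at each level the ingroups still
constrained there are merged into connected components, and components
become child subtrees.  This produces the *minimal* tree displaying
every accepted grouping — polytomies are retained wherever no source
asserts resolution, and they are always soft (absence of evidence).
Pairwise-compatible groupings can still be jointly unsatisfiable; when a
subproblem cannot be split, the lowest-ranked grouping among those
responsible is dropped, logged as "unresolvable", and construction
restarts.  Groupings of the rank-1 study are never dropped (a single
tree's groupings are jointly satisfiable), so the highest-ranked
study's topology is always displayed by the output.

An earlier design attached each grouping's new tips into the growing
tree one grouping at a time.  That approach over-commits: once a tip is
placed, an unsampled close relative arriving from a later study cannot
be inserted between it and its neighbours, and clean, jointly-compatible
inputs produced spurious skips.  The joint construction removes this
order dependence; the greedy stage now decides only *acceptance*, which
is where rank priority semantically belongs.

The reference taxonomy can join the synthesis as one extra,
lowest-ranked source of groupings (taxon monophyly over the sampled
tips).  This mirrors production synthesis pipelines, which graft
phylogenies together with the underlying taxonomic information; without
it, taxa whose members are never co-sampled remain unresolved polytomies
and are indistinguishable from genuinely broken (non-monophyletic) taxa.

Study ranking follows the published criteria — denser focal-clade
sampling first, then marker count, then method class (Bayesian/ML above
parsimony above distance methods) — but explicit ranks always win when
provided, because published rankings are not in general reproducible
from their printed metadata.

## Taxonomy grafting

The Linnaean hierarchy is treated as nested polytomies: species within
genus, genus within family, and so on.  A taxon is **broken** when the
MRCA of its sampled species also contains a sampled tip from outside the
taxon.  Every species absent from the synthesis tree attaches at the
lowest containing taxon that is sampled and unbroken: under the MRCA of
that taxon's sampled species (for a single sampled species, a fresh node
above that tip keeps the taxon's monophyly claim); a broken or wholly
unsampled taxon escalates to its parent's attachment point, which is how
large basal polytomies of never-sampled families arise.  "No rank"
containers are transparent; species recorded directly under the root
(uncertain ordinal status) join the root polytomy.  The attachment log
records, per species, the anchoring taxon, its rank, and whether
escalation was caused by brokenness.

## Parsimony ancestral-state reconstruction

The engine is the Sankoff dynamic program over an arbitrary out-degree
tree and a 2×2 cost matrix; Fitch parsimony is the unordered special
case.  Two presets:

* **unordered** — gains (0→1) and losses (1→0) both cost 1;
* **irreversible** (Camin–Sokal) — losses are forbidden (infinite cost)
  and the state above the root is fixed to free-living through a virtual
  root edge, so an all-parasitic tree is explained by one gain on that
  edge and the root itself is reported as the gained clade.

Tips coded *unknown* contribute zero cost in either state.  Ambiguity
among equally parsimonious histories is resolved during the preorder
backtrace: **ACCTRAN** prefers a child state different from its parent
(changes accelerate toward the root, favouring reversals), **DELTRAN**
prefers the parent's state (changes delay toward the tips, favouring
parallel gains).  A root-state tie under the unordered model defaults to
free-living — the analysed trees are rooted with free-living outgroups
and parasitism is the derived state — and the application of that rule
is recorded on the result.  Each resolution provably attains the DP
minimum (asserted at run time).  How a specific legacy phylogenetics
program breaks ties on polytomies is undocumented, so equivalence is
claimed against the exhaustive minimum-cost oracle, not against any
program byte-for-byte.

Change counting reads the reconstruction's edge list: gains, losses, and
per-gain clade records with any losses nested inside.  Note that
soft polytomies make parsimony counts conservative in a specific sense:
resolving a polytomy can only decrease or preserve the minimum cost
(any polytomy labelling extends to the refined tree at equal cost), so a
count obtained on an unresolved synthesis tree is an upper bound over
its resolutions.

## Support tiers and diversity

A parasitic clade has **direct** support when at least one of its
sampled tips is itself coded parasitic, **indirect** support when the
clade was sampled only through free-living (or unknown) members while
its parasitic species entered by grafting, and **taxonomic** support
when none of its members was ever sampled.  Direct clades are exactly
the gain clades of the reconstruction, re-expanded on the grafted tree
so grafted congeners are counted.  Indirect and taxonomic clades cannot
be found by parsimony (their parasitic members are terminal polytomy
tips under free-living-sampled ancestors), so they are declared in a
clade-definition table and verified against the tree and coding; a
declaration that classifies differently from its expected tier is an
error, as is any overlap between clade records.  Percentages are
rounded half-up (one decimal for table rows, zero for prose-style
figures), matching how such tables are conventionally printed.

## The synthetic copepod dataset

`copsynth.synthetic_copepod` builds a small stand-in (92 species, 48
sampled tips) for the full copepod synthesis, using real copepod names
for readability but claiming to be nothing more than a structural
model.  It encodes the features the analysis turns on: seven directly
supported parasitic clades separated by free-living lineages; a
poecilostome clade whose ladder topology nests two free-living clades
(Oncaeidae; Sapphirinidae + Corycaeidae + *Pachos*) such that
unconstrained parsimony explains it with one gain and two reversals
while the irreversible model requires eight separate gains; four
indirect and three taxonomic clades reachable only through grafting; a
broken family whose unsampled genus escalates to the order; and a
never-sampled order that lands in the root polytomy.  On this dataset
ACCTRAN and DELTRAN agree exactly — 7 gains, 2 reversals — and the
three support tiers partition 14 independent parasitic clades.

## The simulator

`copsynth.synthetic_data` generates complete toy datasets for testing:

* **True tree** — nested uniform random joins (species within genus,
  genus within family, family within order), so every taxon of the
  generated taxonomy is a clade of the true tree.  Topology only; the
  downstream methods never use branch lengths.  Default shape: 5 species
  × 5 genera × 4 families × 3 orders = 300 species.
* **Planted history** — default 14 gains and 2 reversals, the transition
  counts characteristic of the copepod analysis.  Gains fall on stems of
  disjoint genus/family clades, no two of which merge into a cheaper
  single gain; each reversal reverts a genus at depth ≥ 3 inside a
  gained family, leaving at least three parasitic blocks so that one
  gain plus one loss is strictly cheaper than parallel gains.  A
  placement is accepted only if unordered parsimony on the true tree,
  under both resolutions, recovers exactly the planted counts — the
  planted history is the unique most parsimonious explanation — and is
  redrawn otherwise (an error is raised if the shape makes placement
  impossible, e.g. reversals requested in two-genus families).
* **Studies** — restrictions of the true tree to overlapping random tip
  subsets (default 6 studies × 60 tips, 50% consecutive overlap); later
  studies optionally receive random sibling regrafts, the conflict
  injection used to test rank priority.  5% of species are coded
  unknown by default.
* **Fixtures** — newick, manifest CSV, OTT-dialect taxonomy, coding CSV
  and a truth JSON, byte-identical per seed.

What the simulator does not emulate: real marker-driven estimation
error (conflict is injected topologically, not via sequence evolution),
extinct or unsampled lineages outside the taxonomy, synonymy and
name-matching noise, and the ~8% extra-taxonomic terminals of real
sequence databases.  Passing recovery tests therefore demonstrates the
pipeline's correctness under its own assumptions, not robustness to
taxonomic curation error.

## Numerical and degenerate-input choices

Costs are exact small floats (0, 1, +inf); no tolerances are involved
anywhere.  Determinism throughout: stored child order drives all
traversals, BUILD components are ordered by smallest tip key, and every
random draw flows from one integer seed.  Degenerate inputs are
rejected loudly: empty study lists, unrooted input (no root can be
inferred from newick — a tree is taken as rooted as written), tips
without coding entries, taxa with rank-order violations, coding states
outside the three-value vocabulary.

## Problem sizes

The default test suite runs in about twenty seconds: exhaustive
parsimony oracles up to 12 tips (where enumeration is exact and cheap),
synthesis property checks on 36–60-species simulations, and end-to-end
recovery on the 300-species default.  These sizes were chosen so that
every stochastic claim is asserted over many seeds rather than once at
scale; the algorithms themselves are polynomial and run on the full
14,485-species taxonomy without modification.

## Known limitations

* The greedy acceptance order means a high-ranked but sparsely
  overlapping study can pre-empt groupings that a joint optimisation
  over all studies might have reconciled; this matches the rank
  semantics of production pipelines, including their artefacts (taxa
  sampled in non-overlapping studies accumulate toward the base).
* `diversity_report` expands a single-tip gain clade to just that tip on
  the grafted tree; grafted congeners above the gain edge are genuinely
  ambiguous members and are not counted.
* Exact-match name resolution only; synonymy and fuzzy matching are out
  of scope.
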