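# Methods

## Problem and model

Cluster-situated regulators (CSRs) are transcription factors encoded inside
biosynthetic gene clusters (BGCs). The package quantifies, per regulator
subclass, how preferentially its genes sit inside predicted BGC regions, and
then inverts the association: genes of strongly BGC-associated subclasses
found *outside* every predicted region become beacons for candidate clusters
that rule-based predictors missed. The unit of analysis is the gene (one
protein per gene); intervals are 0-based half-open throughout.

## Domain hits and architectures

A hit's evidence is its **normalized bitscore**, bitscore divided by the
Pfam family's curated gathering (GA) threshold, so scores are comparable
across families. Hits at exactly GA (normalized 1.0) are retained — the
threshold is the curated inclusion boundary. Envelope coordinates (not
alignment coordinates) define a hit's extent, since the envelope bounds where
the domain can actually lie.

Overlap resolution is greedy: candidates are visited by normalized bitscore
descending, ties broken by lower start then accession, and a hit is kept iff
it shares no amino acid with an already-kept hit. The published criterion
("highest normalized bitscore wins") does not fix a procedure; greedy with a
deterministic tie-break was chosen because it is order-independent,
idempotent, and reproducible — it does not maximise total score, and the
tests compare it against a definitional oracle, not an ILP.

Regulatory Pfam families are selected by case-insensitive substring match of
keywords against family descriptions, after normalising en/em dashes to
hyphens and collapsing whitespace; a parenthesised abbreviation such as
"helix-turn-helix (HTH)" also matches on either part alone. The shipped
keyword file carries only the widely cited example keywords and is explicitly
incomplete; real-genome analyses should substitute a curated list. A protein
qualifies as a putative regulator when ≥ 1 hit falls in the selected set; its
architecture is then built from *all* of its resolved hits, mirroring the
two-pass strategy of finding proteins with regulatory profiles and then
annotating them against the whole library.

## Co-occurrence network and MCL

Each protein contributes one count to every unordered pair of distinct
domains in its domain set. Edges below `min_count` (default 100) are dropped;
node frequencies are tallied over all proteins regardless of surviving edges.
Edge *containment* is count / min(endpoint frequencies) — the proportion of
the rarer domain's occurrences spent alongside the commoner one.

Markov Clustering is implemented from scratch on the count-weighted adjacency
matrix. Numerical choices:

* **Self-loops** equal each node's maximum incident weight (1 for isolated
  nodes) — standard regularisation that prevents oscillation on bipartite
  structure; comparable in spirit to what external MCL binaries do, but the
  exact published memberships need not be reproduced bit for bit.
* **Expansion power 2, inflation 6** (inflation is the analysis default),
  entries below 1e-8 pruned after each inflation, columns renormalised after
  every step so the matrix stays column-stochastic to ≤ 1e-9 (tracked in the
  result for verification).
* **Convergence**: max absolute matrix change < 1e-9, cap 200 iterations;
  non-convergence returns `converged=False` plus a warning rather than
  raising.
* **Interpretation**: attractors are nodes with positive diagonal mass;
  attractors attracting each other merge into attractor systems; every node
  joins the system holding most of its column mass, ties resolved toward the
  lexicographically smallest cluster label. Clusters therefore partition the
  node set and always refine connected components.

## Subclass rules

Rules test the unordered domain set. `exact` rules implement "solely these
domains" (duplicate copies allowed); evaluation is most-specific-first
(SARP_large and SARP_LAL before SARP_medium before SARP_small), since a set
matching a larger architecture would otherwise be swallowed by a less
specific rule. The four SARP subclasses follow published domain definitions;
the remaining nine rules (PAS-LuxR size split, LuxR-AAA_16, TetR_C_33, LitR,
ScbR, XRE, NrdR, LexA) are domain-level stand-ins for a manual curation
table, marked `editable: true` in the shipped YAML. In particular the
PAS-LuxR small/large boundary has no numeric definition in the literature we
encode; it is expressed here as presence of a second PAS-type domain.

## BGC association

* **Membership** is full containment of the gene interval in the region
  interval. Predicted regions deliberately extend beyond core genes, so a
  gene straddling a boundary is evidence of being outside; containment is the
  conservative choice.
* **Ratios** are exact counts; reports round half-up to one decimal
  (864/1053 → 82.1 %), unrounded values are kept internally. Ratios are
  per-gene by default; an optional per-domain weighting
  (`per_domain_weights`) reproduces the hit-weighted variant.
* **Nearest core gene** minimises the interval gap in nt (0 when
  overlapping), ties to the smaller core start; gap distance is robust to
  very long core genes where midpoint distance is not. Regions without core
  genes fall back to their first listed product class, flagged.
* **Function filters**: known-cluster similarity ≥ 50 % (inclusive) and
  association count ≥ 10 (inclusive); genes failing either contribute to the
  subclass's unknown-function fraction. Both filters are monotone by
  construction and tested as such.
* **Upper quartile**: 75th percentile with linear interpolation over subclass
  in-ratios, selection at ratio ≥ q75; subclasses with fewer than 20 genes
  are excluded *before* the percentile so that tiny noisy subclasses neither
  enter nor distort it. Fewer than four eligible subclasses is an error
  advising manual selection. How many subclasses pass is data-dependent — the
  pipeline reports however many clear the rule rather than a fixed dozen.

## Beacon discovery

Beacons are out-of-BGC genes of the target subclass whose interval-gap to
every region on the contig is ≥ 20 kb (inclusive; one approximate BGC
length). Distance is measured from the gene itself, not from a window around
it. Windows are 20 kb centred on the beacon gene's midpoint — centring is a
design choice; the convention of generating subregions "around" a locus does
not fix an anchor — clipped and flagged at contig edges.

Window similarity blends two content signals, Jaccard of the domain sets and
Jaccard of adjacent ordered domain pairs (weights 0.5/0.5); windows with no
shared adjacency information but identical sets score 1 on the adjacency
term. This is a documented re-implementation of the two shared components of
the external cluster-similarity tool, not an emulation of it: published
singleton/cluster counts are therefore not exactly reproducible and are not
asserted. Clustering is single-linkage connected components at cutoff 0.3;
raising the cutoff can only split components.

The direct-repeat scanner enumerates all (position, spacer) pairs on both
strands with an exact-match unit by default (`max_mismatch=0`); `N` matches
nothing and units under 4 nt are rejected as uninformative. Because an exact
direct repeat is strand-symmetric, a minus-strand hit occupying the same
placement as a plus-strand hit is the same repeat and is reported once.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not the
sequences: one contig per genome (complete assemblies have no contig-edge
truncation), disjoint non-adjacent regions of 20 kb, per-gene Bernoulli in/out
placement — labelled families at `family_p_in[f]`, unlabeled background genes
at 0.146, the genomic background fraction of coding regions inside predicted
regions. Region product classes are drawn from configurable weights, core
genes carry biosynthetic domains, and known-cluster matches get a similarity
from a configurable law (uniform on [0, 100] by default; neither the empirical
BGC length nor the similarity distribution is a claim, both are
configuration). Gene lengths (0.6–1.8 kb), core-gene lengths (2–6 kb) and
per-region core counts (1–3) are realistic orders of magnitude for bacterial
annotation, chosen once.

Decoy hits overlap a true hit by ≥ 1 aa with strictly lower normalized
bitscore; since every decoy's target outranks it, greedy resolution provably
removes all decoys, which the tests exploit. Hidden "planted BGC" windows put
a small-SARP gene ≥ 25 kb from every region (so the 20 kb beacon rule is met
with margin) surrounded by six biosynthesis-rich neighbours inside a 20 kb
window; planting geometry matches the discovery parameters so recall can be
asserted at 100 %.

Promoters are built as flank + unit + spacer + unit + flank, with the random
parts rejection-sampled so that the sequence contains no copies of the unit
(or its reverse complement) beyond the unavoidable baseline of the planted
core — self-periodic units such as "AA" legitimately create overlapping
copies inside the core, which is preserved.

What passing on synthetic data does **not** show: robustness to real
annotation noise (fragmented genes, miscalled boundaries), Pfam version
drift, real keyword curation, multi-contig assemblies, or realistic BGC
length/compositional distributions. Genome-scale published counts (hundreds
of thousands of regulators across hundreds of genomes) depend on database
snapshots and are out of scope at desk scale; the test suite works on
deliberately small cohorts (≤ 50 genomes, ≈ 1000 focal genes) sized so the
binomial error bands are tight enough to be meaningful.

## Determinism

Every stochastic component consumes a `numpy` Generator seeded from a single
integer; genomes use independent spawn keys `(seed, genome_index)`. Identical
config + seed reproduces byte-identical fixture directories, manifests and
acceptance JSON.

## Known limitations

* Keyword list and non-SARP rules are illustrative defaults, not curation.
* MCL memberships may differ marginally from external binaries (self-loop and
  pruning policy are internal choices).
* Window similarity is a two-component simplification; no Pfam-colored
  alignment or domain-duplication-sensitive index.
* No protein sequences anywhere; anything requiring HMM scoring or BLAST
  similarity is out of scope.
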