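# Methods

This note documents the models, conventions and numerical choices behind
`cablediv`, in the order the pipeline applies them. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Percent identity and the two alignment engines

All taxonomic decisions reduce to pairwise percent identity. The reference
definition (`identity.align_pair` + `identity.percent_identity`) is:

* optimal **affine semi-global** alignment — match +2, mismatch −1, a gap of
  length *k* costs −5 − 2(*k*−1), terminal gaps on either sequence free — so an
  800 bp fragment aligns against a full-length gene without end-gap penalties;
* a column matches when the IUPAC sets of its two symbols intersect (M matches
  A or C, N matches everything), which is required because degenerate bases
  occur in primers and Sanger consensus sequences;
* **pairwise deletion**: columns with a gap in either sequence are excluded
  from the denominator, so internal indels never count as mismatches.

The aligner is `Bio.Align.PairwiseAligner` with a custom IUPAC substitution
matrix; of all co-optimal alignments the first produced by its deterministic
iterator is used, so results are reproducible. An O(nm) affine alignment of two
~1,500 bp genes costs ~50 ms, which is fine for individual calls but not for
the ~10,000 pairs of an all-vs-all matrix. Bulk operations (`identity_matrix`,
`screen_references`, profile construction) therefore default to a **fast
engine** built on edlib's bit-parallel unit-cost alignment, with
`method="exact"` available everywhere.

The fast engine deliberately deviates from pairwise deletion in one respect:
internal gap columns count in its denominator (identity = matches / all path
columns; terminal overhangs of the longer sequence remain free via edlib's
infix mode). Under unit costs a minimum-edit path may explain clustered
substitutions with indel pairs; with pairwise deletion that would both remove
mismatches and shrink the denominator, letting the path choice inflate identity
by several points on diverged pairs. With the gap-inclusive denominator the
estimator is maximised by edlib's own objective and is therefore insensitive to
which co-optimal path is returned. On high-identity pairs (the regime where the
98.7%/94.5% thresholds operate) the two engines agree to a few tenths of a
point; the suite asserts |fast − exact| ≤ 0.35 at 1% divergence and ≤ 1.6 at 5%.

## Reference screen

Each record's best identity against a small trusted query panel (one sequence
per known genus-level group in the synthetic scenario, mirroring the five-query
panel used for database mining of this clade) decides retention at ≥92%. A
whitelist can retain curated exceptions below the cutoff, which reproduces the
documented practice of keeping one database sequence at 90.9% on taxonomic
grounds. Retention is monotone in the cutoff (tested).

## Conserved-region filter

The manual curation step "remove sequences with indels and mutations in
conserved regions" is operationalised as follows:

1. A **profile** is built from a trusted set — in the pipeline, the whole
   screen-retained pool, since per-column conservation estimated from only a
   handful of references misclassifies variable columns. The longest sequence
   is the coordinate backbone; every sequence is aligned to it, and each
   column records its majority base, the fraction of *covering* rows agreeing
   with it (fragments do not vote on regions they never reach), and its
   coverage.
2. A column is **conserved** when its agreement fraction reaches
   min(0.95, 1 − 1/coverage) — the second term prevents a single aberrant
   sequence in a small panel from demoting the very column it violates — and
   the column lies in a *run* of at least 10 such columns. The run requirement
   encodes that the real gene's conservation is regional (conserved cores
   alternating with hypervariable regions V1–V9); isolated invariant columns
   inside variable regions are not conserved regions, and alignment jitter
   around them would otherwise masquerade as violations.
3. A record is flagged when more than 5 conserved columns carry a gap or an
   incompatible base. Counts use the fast engine first; any record over the
   budget is re-verified with the exact affine alignment, whose gap penalty
   does not produce spurious indels, so unit-cost jitter cannot cause false
   removals. Both knobs (0.95, 5) plus the run length are exposed in
   `PipelineConfig`.

## Trees, rooting, monophyly

Tree construction is neighbor joining (Studier–Keppler form) over corrected
distances: p-distance (100 − identity)/100 or Jukes–Cantor
−(3/4)·ln(1 − 4p/3) with fallback to p where p ≥ 0.75 (default: JC).
Implementation details that the literature leaves open are fixed as: ties in
the Q criterion broken by the lexicographically smallest pair of cluster
labels (a cluster's label is its smallest leaf id); negative estimated branch
lengths clamped to zero with the deficit moved to the sibling so path lengths
are preserved. NJ is exact on additive matrices; the suite verifies topology
and branch lengths to 1e-9 on random additive trees and cross-checks the
topology against scikit-bio's independent NJ. Maximum-likelihood inference
with model selection and bootstrapping is intentionally *not* reimplemented —
an externally computed Newick tree can be injected at any tree-consuming
stage, and bootstrap values on imported trees are carried, never computed.

Rooting places the root at the midpoint of the outgroup's pendant edge. The
monophyly filter keeps exactly the leaves under the MRCA of the trusted seed
sequences in the rooted tree; it is checked against a brute-force bipartition
oracle on random trees.

## Species-level clades

Complete-linkage agglomerative clustering on d = 100 − identity, cut at
100 − 98.7: merges processed smallest-distance-first, ties broken by the
lexicographically smallest pair of cluster labels. Complete linkage is chosen
because it guarantees the delineation statement — every pair inside a clade is
within 1.3% of each other — and because a brute-force/scipy oracle then pins
the semantics exactly; single linkage is available behind a flag for
sensitivity analysis. Validity (≥1,200 bp member) and representative choice
(longest member, ties to the smaller id) follow the convention that a clade
must contain a nearly complete gene to be taxonomically reliable.

## Genus-level clusters

Genus delineation is algorithmised as **monophyletic threshold decomposition**:
walk the rooted ingroup preorder; a node's leaves become one cluster as soon as
their linkage identity reaches 94.5% − tolerance, otherwise recurse. Clusters
are monophyletic by construction and jointly partition the representatives.
The linkage statistic defaults to the **minimum** pairwise identity: with the
mean, a node joining a large genus and a small sister genus passes the guide
because the abundant within-genus pairs swamp the average, and small genera can
never be split off. Min linkage is the genus-level analogue of the
complete-linkage guarantee used at species level; mean remains available.
The tolerance knob (default 0) exists because published genus partitions of
this clade are topology-led and admit sub-cutoff intra-cluster pairs (down to
~90%) and super-cutoff inter-cluster pairs (up to ~96%); reproducing such
partitions requires tolerance > 0, while the synthetic scenario is calibrated
to be decisive at tolerance 0.

## In-silico nested PCR

Primer annealing is sequence-level only: a site requires at most
`max_mismatch` (default 0) IUPAC-incompatible columns and an exactly
compatible 3′-terminal anchor of 3 bases, on either strand; melting
temperatures, cycle counts and chemistry are not modelled, so amplification
*success rates* are out of scope by design. Amplification enumerates
fwd-site × downstream-rev-site products within length bounds; nested consensus
runs the outer pair first, re-amplifies each product with every nested pair,
and merges fragments by best semi-global overlap (≥50 columns at ≥99%
identity; conflicting columns resolved by majority, ties become N).
Coordinates are 0-based half-open on the plus strand throughout. On error-free
templates the consensus equals the planted gene by string equality (tested).

## The synthetic radiation generator

The generator emits the statistical structure the analysis assumes, not real
sequence evolution:

* a random root gene (default 1,500 bp) carries verbatim copies of the four
  packaged primer windows (27F at the 5′ end, the reverse complement of 1492R
  at the 3′ end, family-specific DSBB windows internally) plus eight internal
  conserved blocks; all of these are masked from mutation;
* substitutions hit only **variable sites** — contiguous windows centred in
  each unmasked stretch, 30% of unmasked positions by default — giving the
  bimodal, regional conservation structure the conserved-region filter needs;
* per-branch substitution counts are fixed (rounded products of branch length
  × gene length) along a genus → species → individual star hierarchy with
  default pairwise divergences 0.005 within species, 0.025 between species of
  one genus, 0.10 between genera, 0.18 to off-clade contaminants and 0.25 to
  the outgroup. Substituted bases are redrawn uniformly from the three
  alternatives (Jukes–Cantor-like); optional indels are single events of
  geometric length (mean 3);
* the packaged survey-scale scenario plants 90 species over six genera as
  (14, 3, 1, 2, 35, 35) — the per-cluster clade counts of the published
  partition — with 38 singleton species allocated (2, 1, 0, 1, 20, 14) and two
  sequences for every other species, 142 in-clade records in all. Sites span
  the four salinity categories; each genus has a home category, most species
  are endemic to one site, and one brackish site hosts species from three
  clusters, mirroring the observed co-occurrence hot spots;
* realized identities are re-measured on the emitted records with the same
  engine the pipeline uses, and the draw is **rejected and resampled** (at most
  100 attempts) unless every pair clears its cutoff by ≥0.3 identity points.
  The between-genus divergence (0.10 rather than a value closer to the 94.5%
  boundary) was chosen once so both engines clear the cutoff by more than one
  point. All randomness flows from one integer seed; identical seeds give
  byte-identical output.

What the generator does **not** emulate: rRNA secondary-structure-constrained
evolution, chimeras, sequencing error profiles, rate heterogeneity beyond the
variable/invariant dichotomy, and realistic phylogenetic branch-length
variation. Passing the recovery tests therefore shows the pipeline is correct
under its stated assumptions (identity bands separated from the cutoffs), not
that the thresholds themselves are optimal for field data.

## Pipeline order and accounting

Filters run screen → conserved-region → tree/monophyly → length, because the
monophyly tree is built before short sequences are dropped (fragments still
inform the topology); a flag moves the length filter first. Every record ends
in exactly one status (retained, screen_rejected, conserved_violation,
off_clade, too_short); the per-source accounting table row-sums equal the
input sizes at every stage. The outgroup sequence bypasses all filters and
participates only in trees. Invalid species groups (no ≥1,200 bp member) are
excluded from genus clustering but reported in all summaries. Runs are fully
deterministic given config and inputs; `write_outputs` emits the resolved
config next to the results for provenance.

## Problem sizes

The packaged scenario (142 sequences of 1,500 bp) makes an all-vs-all matrix
of ~10,000 pairs, which the fast engine computes in a few seconds; a full
pipeline run, generation included, takes ~7 s on one CPU, and the 20-seed
recovery sweep a few minutes. These sizes were chosen as the smallest that
still realise the published headline structure (90 clades / 6 clusters / 38
singletons) exactly.

## Known limitations

* The fast identity is an approximation; analyses operating within ~1 point of
  a threshold should use `identity_method="exact"` (slower) or widen the
  generator's band margins.
* Genus decomposition assumes the tree places genera as clades; on trees with
  deep topological errors the identity guide cannot rescue the partition.
* The conserved-region profile is estimated from the data being curated (after
  screening); with very few sequences (< ~6) the filter effectively trusts the
  exact-alignment recheck only.
* Salinity metadata is a point value per site; habitats with ranges must be
  reduced to a representative value upstream.
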