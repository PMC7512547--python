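# Methods

## Overview

`autotax` builds ecosystem-specific reference databases from full-length
16S rRNA gene sequences and assigns every reference a complete, reproducible
seven-rank taxonomy. The pipeline is deliberately rule-based rather than
model-based: every decision is a deterministic function of percent identity
and a fixed set of rank thresholds, so a database can be regenerated — and,
critically, *extended* — without any name of an existing reference changing.

The stages are:

1. **Orientation.** Input sequences are flipped to the reference strand by
   shared 12-mer counts against the backbone database; sequences sharing no
   12-mer on either strand are dropped (they are not 16S).
2. **Dereplication.** Exact string duplicates (plus strand only) collapse
   into uniques carrying a `size` abundance, sorted by size descending with
   first-appearance tie-breaks.
3. **Denoising (FL-ASVs).** A greedy UNOISE-style pass in descending
   abundance order: unique *M* merges into an accepted centroid *C* when
   `size(M)/size(C) <= beta(d) = 1 / 2^(alpha*d + 1)`, with *d* the
   Levenshtein distance (unit costs) between *M* and *C*. Uniques with
   `size < minsize` (default 2) cannot found centroids, which removes
   singleton sequencing errors. Accepted centroids are renamed
   `FLASV1..FLASVn` in acceptance order; this numbering is the anchor for
   all placeholder names.
4. **Optional FL-OTUs.** Uniques (including singletons) are greedily
   clustered at 99% identity and screened for chimeras against the FL-ASVs;
   the surviving centroids extend rare-biosphere coverage. The branch is
   marked experimental in the output manifest: keeping OTUs in a maintained
   database propagates errors and destabilises placeholder names, so they
   are intended for exploratory use only.
5. **Taxonomy assignment.** Per FL-ASV: exhaustive best-hit search against
   the backbone, threshold trimming of the hit's taxonomy, a type-strain
   species call, placeholder names from per-rank greedy clusterings, a
   precedence merge, and a bottom-up conflict-resolution pass.

## Identity definition and its assumptions

Percent identity is computed from a global Needleman–Wunsch alignment with
match +1, mismatch −2, gap open −10, gap extension −1, and **free terminal
gaps**; identity = matching columns / counted columns, where terminal-gap
columns are excluded and internal-gap columns count as differences. These
constants are configurable (`seqcore.AlignScoring`); the defaults mirror
the behaviour of the global mapping mode of common USEARCH-style tools.
Operands are put in a canonical (lexicographic) order before aligning so
identity is exactly symmetric even when co-optimal alignments disagree.

One consequence deserves emphasis: because the terminal gaps are free, the
identity of two sequences below roughly two-thirds identity is not
meaningful — the full-length alignment scores negative there, and a short
spurious perfect overlap becomes optimal. All quantities the pipeline
interprets are comparisons against thresholds of 75% and above between
homologous full-length 16S genes, where this regime is never entered, but
the `global_identity` function should not be applied to non-homologous
sequences.

## Rank thresholds

The per-rank identity cutoffs default to the statistically derived values
used throughout the 16S literature: phylum 75.0, class 78.5, order 82.0,
family 86.5, genus 94.5, species 98.7 (percent). They are used twice, with
deliberately different boundary conventions:

* **Trimming / cluster joining:** identity **≥** threshold retains the rank
  (and joins the cluster). Novelty at a rank is therefore identity
  **strictly below** the threshold.
* **Type-strain species calls:** identity **strictly above** 98.7 puts a
  type strain in range. A species name is adopted only when exactly one
  distinct binomial is in range; two or more distinct species in range
  block the call entirely (misclassification risk beats coverage).

Kingdom has no threshold: any 16S best hit shares a domain, so the backbone
kingdom is adopted regardless of identity.

## Placeholder taxonomy and stability

The six per-rank clusterings are greedy and **order-stable**: sequences are
processed in canonical FL-ASV numeric order, and each sequence joins the
*first* centroid at or above the threshold — not the best one. First-match
semantics are what make the clustering prefix-stable: clustering `S ++ E`
restricted to `S` equals clustering `S` alone, for any extension `E`.
Placeholder names are `denovo_<rank letter>_<centroid FL-ASV number>`
(rank letters k, p, c, o, f, g, s), so prefix stability guarantees that a
database update — new FL-ASVs appended with the next numbers — never
renames an existing taxon. Greedy clusters are not guaranteed optimal; the
reproducibility is the point.

An update run denoises only the new reads (the original pool need not be
retained), drops exact duplicates of existing FL-ASVs, and re-runs taxonomy
on the combined list; the manifest records this choice.

## Merge precedence and conflict resolution

Per rank: trimmed backbone name > type-strain species (species rank only) >
placeholder. If the backbone hit's own lineage is missing a retained rank,
the gap falls through to the placeholder so the completeness guarantee
(all seven ranks non-empty) always holds.

Because backbone names and placeholder clusters are derived independently,
a lower-rank taxon can initially straddle two parent names (in practice:
species near the genus threshold). A bottom-up pass (species → phylum)
rewrites, inside each child taxon whose members disagree on the parent
name, every member's parent to that of the taxon's centroid FL-ASV (for
backbone-named taxa, the lowest-numbered member stands in). One pass makes
the name hierarchy a tree — every taxon has exactly one parent — and the
operation is idempotent. The generalisation to all adjacent rank pairs
(rather than only species/genus) is a design choice: the tree property is
asserted on every pipeline output, so it must hold at every rank.

## Chimera screen (simplification)

The reference-based screen is a deliberate simplification of full
two-parent chimera scoring. For each candidate, per-position match
profiles against every FL-ASV are computed from the global alignments; the
best single-parent identity `s1` and the best two-segment identity `s2`
(prefix explained by one parent, suffix by another, maximised over ordered
parent pairs and the breakpoint) are matches over candidate length. A
candidate is flagged when the two-parent model is perfect and no single
parent is, or when it beats the best single parent by at least the
divergence margin (default 1.0 percentage point). There is no vote or
score model beyond this; candidates identical to an FL-ASV are silently
deduplicated rather than flagged.

## The classifier used for evaluation

The bundled classifier is a k-mer bootstrap classifier: 100 bootstrap
iterations, each drawing 32 of the query's 8-mers with replacement, score
every reference by drawn-k-mer membership; the top reference's lineage is
one vote (ties go to the earlier reference), and per-rank confidence is
the winning lineage-prefix's vote fraction, reported down to the last rank
at or above the cutoff (default 0.8). Confidence is monotone non-increasing
with depth by construction. Both strands are tried (k-mer overlap decides),
and a fixed seed makes every classification bit-reproducible. The constants
(k = 8, 100 iterations, 32 k-mers) follow the published description of this
classifier family; only the cutoff is anchored by the pipeline's own usage.

Two evaluation procedures are built on it and on the assignment path:

* **Amplicon self-classification:** amplicons are extracted *in silico*
  (IUPAC-aware exact primer matching, forward primer removed, reverse site
  removed by default — a config flag retains it) from every reference and
  classified against the full-length database; per rank, the fractions
  classified to the same name / a different name / no name sum to one.
  Directions `fwd`/`rev` truncate to the first 200 bp read from either end
  to model single-read sequencing.
* **Leave-one-out:** a seeded sample of references is held out and
  classified against the remainder via the exhaustive top-hit + trimming
  path; per-rank tallies use the standard metrics accuracy = TP/(K+OC),
  misclassification = MC/K, overclassification = OC/L, true-positive =
  TP/K, underclassification = UC/K, with `None` marking undefined
  denominators.

## Synthetic data generator

The generator builds a lineage tree over a random 1,400-nt root (the scale
of a trimmed full-length 16S gene) by assigning every tree edge a
*disjoint* block of substitution positions. Pairwise leaf identities are
then exact by construction (the Hamming distance is the sum of edge sizes
on the connecting path) and are placed strictly between adjacent rank
thresholds, at least a guard band (default 0.3 points) away from every
threshold, so realized identities classify unambiguously. Realized
identities are re-measured with the alignment identity before the world is
returned; assertions rest on measured values.

Default divergences (per-edge substitutions 20/23/32/45/38/25 for
phylum..species) realize sibling identities of 96.43 (species), 91.00
(genus), 84.57 (family), 80.00 (order), 76.71 (class) and 73.86 across
phyla. Backbone references sit 5 substitutions from their source leaf
(99.64%), type strains 4 (99.71%). Abundances decrease strictly down the
designed order (100, 95, 90, …) so the FL-ASV numbering is predictable.
Planted artifacts exercise each pipeline defence: a 1-mismatch variant at
skew 0.10 ≤ β(1) = 0.125 (merged by the denoiser), a 3-mismatch singleton
(discarded by `minsize`), a 50/50 two-parent chimera (flagged by the
screen), an off-target junk read (dropped by orientation), and a third of
the reads reverse-complemented (flipped back by orientation).

What the generator does *not* emulate: 16S secondary structure and
conserved/variable region architecture (substitutions are uniform outside
the embedded priming sites), indels, PCR/sequencing error profiles, and
realistic abundance distributions. Passing the recovery suite therefore
demonstrates the correctness of the pipeline's decision logic under
controlled divergences, not its behaviour on the error structure of real
libraries.

## Numerical choices and degenerate inputs

* Ties everywhere are broken deterministically: first appearance
  (dereplication, denoising), database order (top-hit), earlier centroid
  (clustering), earlier reference (classifier votes). Everything is
  single-threaded; reruns are bit-identical.
* Identity exactly at a threshold joins/retains (≥); type-strain range is
  strict (>). Both follow from the novelty ("< threshold") and species
  ("more than 98.7%") conventions, and both are parameters.
* Empty input produces empty outputs and a warning, not an error.
* Percentages in the novelty and census tables print with one decimal at
  ≥ 10% and two below — the convention of the tables this report format
  follows.
* The denoiser compares against the centroid's founding abundance (sizes
  are not accumulated as members merge), keeping the pass independent of
  merge order.

## Problem sizes

The bundled test-suite and acceptance runs use worlds of 8–16 designed
FL-ASVs (≈ 700 raw reads) and toy databases of ≤ 10 sequences where
brute-force oracles (exhaustive alignment enumeration, explicit chimera
model construction, Levenshtein DP) are tractable; the pipeline itself has
no size-dependent switches, so behaviour on larger inputs differs only in
runtime (top-hit search and clustering are exhaustive by design,
O(n·m) alignments).

## Known limitations

* The chimera screen's identity is matches over candidate length, which
  equals the alignment identity only for (near-)gapless alignments; with
  long indels the two diverge slightly.
* Conflict resolution above the genus rank is a generalisation; on
  adversarial inputs it may re-parent taxa that a species/genus-only rule
  would leave alone (it never breaks the tree property).
* The classifier is not trained and has no kingdom-level rejection beyond
  k-mer overlap; queries unrelated to every reference are unclassified,
  not flagged.
* `global_identity` assumes homologous inputs (see above).
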