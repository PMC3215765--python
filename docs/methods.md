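# Methods

## The question the package answers

Orthologs (homologs separated by speciation) are widely assumed to conserve
function better than paralogs (homologs separated by duplication) at the
same evolutionary distance. Because a protein's function is largely carried
by its *domain architecture* — the N- to C-terminal order of its Pfam-A
domains — one observable consequence would be that orthologs conserve
domain architecture better than paralogs *after controlling for sequence
divergence*. `domarch` implements the full measurement machinery for that
comparison on any two-species dataset, plus a synthetic data generator so
the machinery can be validated end-to-end against known ground truth.

## Architectures

Raw domain hits (protein, Pfam accession, coordinates, Pfam type class) are
sorted by start coordinate. Two normalizations make architectures
comparable across homologs:

* **Repeat/Motif collapsing.** Copy number in tandem Repeat- or Motif-type
  stretches drifts far more easily than any other architectural feature, so
  a maximal run of consecutive same-label Repeat/Motif hits becomes one
  pseudo-domain unit. The run length is kept as metadata only; a collapsed
  unit counts as exactly one domain in every downstream count.
  Family/Domain-type stretches are never collapsed. Collapsing is applied
  after clan mapping, so two Repeat families of one clan collapse together
  (the pre-clan-mapping alternative is equally defensible; this choice
  makes "identity" mean one thing — label equality — everywhere).
* **Clan equivalence.** Families in the same Pfam clan are treated as
  identical. Every unit carries an *effective label*: the clan accession if
  the family has one, otherwise the family accession. All matching,
  classification and event logic compares effective labels.

Proteins with no domain hits are excluded; pairs touching them are skipped
with a logged count.

Overlapping hit coordinates are tolerated by default (Pfam envelopes can
abut or overlap slightly); a strict mode rejects them.

## Architecture alignment and the DA-score

Two architectures are aligned globally with a Needleman-Wunsch variant over
domain labels: match 0, gap 3, mismatch 10, linear (non-affine) gap costs,
minimizing total cost. Because one mismatch (10) costs more than two gaps
(6), optimal alignments never pair two different labels; the constructor
warns if a user-supplied scheme breaks that guarantee. End gaps are charged
like internal gaps. Traceback ties are broken deterministically (diagonal,
then gap in the second architecture, then gap in the first); the
alternative order is available, and the event-category outputs are
invariant to the choice (tested).

The conservation score of a pair is

    DA(p1, p2) = a12 / (n1 + n2)

with n1, n2 the domain counts and a12 the number of domains over *both*
proteins sitting in match columns (twice the match-column count). It is 0
for disjoint domain sets, 1 for identical architectures, and insensitive to
the cost parameters as long as alignments stay sensible.

Pairs are also placed in four similarity classes: `Identical` (equal label
sequences), `SameContentNotAligned` (equal label *sets*, different
sequences), `DiffContent` (overlapping sets), `NoShared` (disjoint sets).

## Event annotation

For pairs that share content but are not identical, every unaligned unit is
explained by exactly one of five domain-swapping categories, tested in
priority order; earlier rules mask later ones:

1. **Segment duplication/deletion** — the unit is part of a maximal
   unaligned run that is a whole-number tandem repeat of an adjacent
   aligned segment of ≥ 2 units with ≥ 2 distinct labels. The flanking
   aligned segment may lie on either side; when the unaligned run is longer
   than a whole number of copies, only the covered units take this
   category and the excess falls through.
2. **Repetition difference** — the unit's immediate neighbor (same
   protein) is an *aligned* unit of the same label. Unaligned same-label
   neighbors do not qualify.
3. **Insertion/deletion of a new domain** — the partner protein has no
   unit of this label.
4. **Insertion/deletion of an existing domain** — the partner has an
   *aligned* unit of this label. (Requiring alignment here is what leaves
   rule 5 a non-empty case; if any unit of the label merely existing in the
   partner sufficed, shuffling could never be reached.)
5. **Domain shuffling** — everything left; the label is then necessarily
   unaligned in both proteins, i.e. an order rearrangement.

Insertion and deletion are indistinguishable from a pair alone, so all
categories are direction-agnostic. Each unaligned unit's *position* is
middle if aligned units flank it on both sides within its own protein,
N-terminal if aligned units lie only C-terminal of it, C-terminal in the
mirror case. For tallies, a maximal run of consecutive same-category
unaligned units counts as one change event.

## Pair categories and aggregation

From InParanoid-style two-species ortholog clusters the package draws four
pair types: ortholog (O, cross-species within a cluster), inparalog (iP,
same-species within a cluster), and closest same-species / cross-species
outparalogs (oPs / oPx) — for each cluster member, the highest-bit-score
protein outside its cluster in the relevant species, subject to InParanoid
default cutoffs (40 bits; overlap 50% and segment 25% when coverage fields
are present). Bit-score ties break on lexicographic protein id; asymmetric
score tables use the better of the two directions.

All aggregate scores are **means of per-cluster means**, so each cluster
contributes equally regardless of size. A pair whose proteins sit in two
different clusters and are mutually closest non-clustermate homologs
contributes to both clusters' means; every other pair contributes once.
O pairs are additionally split by whether their cluster is 1-1 (one member
per species) or duplicated.

## Divergence

Sequence divergence is computed from user-supplied pairwise alignments (or
precomputed identities): identity = identical residues / aligned (non-gap)
columns, p-distance d = 1 − identity, converted to expected substitutions
per site with the amino-acid Jukes-Cantor correction
d_JC = −(19/20)·ln(1 − (20/19)·d), which is undefined at the saturation
point d ≥ 19/20 (an error, by design). Comparison is case-insensitive; 'X'
counts as a difference by default, with a flag to exclude ambiguous
columns instead.

## Binned comparison and significance

To ask whether two pair categories differ in architecture conservation *at
equal divergence*, per-cluster (mean d_JC, mean DA) points of the two
categories are placed into N bins (default 10): each category is cut into
equal-count bins, the two threshold sets are averaged, and thresholds are
refined iteratively — the smallest bin×category cell is found, its
thresholds are shifted to equalize it with its neighbor bins under a
uniform-density approximation (transfer divided by the donor bin's point
density), and a shift is kept only if the then-smallest cell strictly
grows. Refinement stops on a rejected shift, when the smallest cell holds
≥ 1% of all points, or at an iteration cap (default 200; the cap is a
safety net, not a tuning knob). Bins where one category is empty are
flagged and skipped.

Within each remaining bin, the difference in mean DA-score is tested with a
randomized permutation test: 1000 without-replacement relabelings of the
pooled points into the original group sizes; p = fraction of relabelings
whose absolute mean difference is at least the observed one (no +1
smoothing by default; the (c+1)/(n+1) estimator is a flag). Bins are
significant when raw p < 0.05/N (Bonferroni across bins).

Class and event-category count tables (O vs oPx) are compared with a
Pearson chi-square homogeneity test: expected counts from pooled margins,
f = (M−1)(N−1); rows too sparse for the test (NoShared; segment
duplication and shuffling) are excluded before testing, and a flag reports
any remaining expected cell below 5 rather than failing.

## The synthetic generator

Each simulated dataset holds two species and clusters generated in sister
pairs from a common pre-speciation family ancestor, giving every member a
natural outparalog pool. Along every branch of each known gene tree
(pre-speciation outparalog branches, speciation branches, optional
post-duplication branches), architecture events are applied at configured
per-branch probabilities and recorded with the identities of the affected
units, so annotation output can be scored against truth.

Defaults encode the study conditions: duplication probability 0.3 per
lineage; event rates dominated by new-domain insertion/deletion (0.08) and
repetition difference (0.06), with existing-domain insertion (0.02),
segment duplication (0.01) and shuffling (0.01) rare, all three-fold
elevated on post-duplication and pre-speciation branches; 150 clusters;
ancestral architectures of 2 + Poisson(1.5) units over a 40-family
alphabet with 8 clans at density 0.2 and a 25% Repeat fraction; cluster
ages uniform on [0.05, 0.40] expected substitutions of per-branch
p-distance. Event placements deliberately avoid built-in confounds (e.g.
an "existing-domain" copy is never inserted next to a same-label unit,
repetition copies use non-collapsing Family units); multi-event histories
can still confound each other, which the recovery report counts as
category confusion, not error. A `max_events_per_cluster=1` setting
produces the non-confounding single-event histories used to measure
per-category recovery.

Residue evolution is emulated only at the aligned-pair level: each needed
pair gets an ungapped alignment of length 300 with Binomial(300, d)
differing sites, where d is the summed branch p-distance capped at 0.88 to
stay clear of Jukes-Cantor saturation. Bit scores are 600·(1−d) plus
Gaussian noise (σ=15), floored at 25 — only their ordering matters, for
closest-outparalog selection. Everything is deterministic per seed.

What passing on synthetic data does *not* show: the generator has no
realistic Pfam family frequencies, no per-site rate heterogeneity or indel
realism, no terminal bias in event placement (events land uniformly along
the architecture, so the position-bias summary on synthetic data centers
on "middle" for long proteins), and exactly two species. Results on real
proteomes depend on upstream domain calling, clustering and alignment
quality in ways the synthetic suite cannot probe.

## Numerical and degenerate-input choices

* Costs are penalties; alignment minimizes. Architecture ties in traceback
  are deterministic (documented order).
* Equal-count thresholds are midpoints between flanking sorted values;
  averaging two categories' thresholds can make per-category counts
  deviate from perfectly equal — that is inherent to the procedure.
* Refinement accepts only strict improvement of the smallest cell; ties
  reject, guaranteeing termination.
* Permutation p-values live on the grid {0, 1/n, ..., 1}; identical groups
  give p = 1.
* Empty architectures, single-species clusters, a protein in two clusters,
  saturated p-distances, and zero-margin chi-square tables are errors;
  missing bit-score entries and missing divergences are non-fatal
  (no-hit / excluded-from-binning, logged).

## Problem sizes

The shipped validation runs use 150 clusters (≈ 380 proteins, ≈ 800 pairs)
for the end-to-end comparison, 60 clusters per event category for recovery,
500 random pairs against the brute-force alignment oracle, and 1000
replicates × 1000 permutations for type-I-error calibration. These sizes
give stable statistics (the headline comparisons reproduce across seeds)
while keeping the whole suite under a minute of compute.
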