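# Methods

## The measurement model

The quantity of interest is the copy number of a gene family per
genome-equivalent of community DNA, estimated from a paired-end clone
library without any absolute calibration. Three assumptions carry the whole
construction:

1. **Coverage is proportional to template abundance.** The number of read
   nucleotides overlapping a locus is proportional to how many copies of
   that locus the community carries, times sequencing depth.
2. **Universal single-copy markers estimate depth.** A gene present exactly
   once in essentially every genome has community copy rate 1 by
   definition, so the mean coverage of a panel of such markers *is* the
   sequencing depth expressed in genome-equivalents.
3. **Ortholog groups aggregate fragments.** Metagenomic gene calls are
   fragments; dividing summed overlap nucleotides by the *expected* length
   of the group (mean of its reference members) rather than the observed
   call length corrects fragment-length bias.

Under these, `acr(g) = cov(g) / mean(cov(markers))` is an unbiased
estimator of the family's abundance-weighted copies per genome, and the
mean `acr` over the marker panel is exactly 1 by construction (a useful
internal control, asserted in the tests).

Clone deduplication: when a clone's two reads overlap on one contig they
derive from a single contiguous insert and are merged into their union
interval before counting; non-overlapping mates and mates on different
contigs are counted separately. Deduplication can only decrease counted
nucleotides. Coverage is strand-agnostic.

## Marker selection

A group qualifies as a universal single-copy marker when it is present
(copy ≥ 1) in ≥ 95% of complete archaeal genomes, ≥ 95% of complete
bacterial genomes (both conditions required — conjunction is what makes the
panel domain-independent), and its mean copy number among complete genomes
of each domain is < 1.2. Incomplete genomes are excluded from all
denominators: absence from a draft genome is not evidence of absence. The
thresholds (0.95, 1.2) are exposed as parameters `frac` and `copy_max`.

## Overrepresentation statistics

Per group: `S` = coverage summed over member genes and pools;
`F` = `(S / S̄_markers) / r_ref`, where `r_ref` is the group's reference
copies per genome. `F` is reported as +inf for groups with no reference
members (metagenome-only groups), and is 1 in expectation for the markers.

The test treats gene counts as draws from a finite pool: with `q = ⌊S⌋`
(coverage sums are *floored* to integers so they can act as counts), `k` the
total floored metagenome count, `m` the group's gene count (reference
members plus `q`) and `n` all other genes, the p-value is the hypergeometric
upper tail `P(X ≥ q)`, identical to a one-sided Fisher exact test on the
corresponding 2×2 table. The exact split of reference vs. metagenome genes
into the urn is a convention choice; the implemented one (group's own
floored count included in `m`) is slightly conservative under the null,
which the calibration simulation confirms (0/1000 null groups flagged at
adjusted p < 1e-4). Groups flooring to `q = 0` stay in the testing family
with `p = 1` so the Benjamini–Hochberg correction (step-up, capped at 1,
order-preserving) is computed over a well-defined family. The
overrepresentation flag is strict: `p_adj < alpha`, default `alpha = 1e-4`.

A practical regime note: the urn test only has power when the reference
pool is large relative to the floored metagenome count (`k/(m+n)` small).
The default synthetic configuration therefore uses a 200-genome reference
against ~600 clones per pool; shrinking the reference without shrinking
depth quietly destroys power long before it biases the coverage ratios.

## Homology assignment

Percent identity over the aligned region converts to Kimura's corrected
protein distance `d = −ln(1 − p − 0.2p²)`, `p = 1 − identity`. The formula
saturates at the positive root `p* = (√1.8 − 1)/0.4 ≈ 0.854102`; at or
beyond the root the distance is reported as undefined and such hits are
dropped from ranking. Homology pairs are unidirectional best hits requiring
*both* `E ≤ 0.001` and bit score ≥ 60; among passing hits the minimum
distance wins, with ties broken by higher bit score then lexicographic
subject id (determinism). Each metagenomic gene joins its best hit's group;
genes with no passing hit become singleton groups. This nearest-group
assignment deliberately replaces full tree-based ortholog-table merging and
domain-splitting: the downstream statistics consume only group membership,
coverage and expected length, none of which depend on the clustering
internals. Multi-domain genes are not split.

## Sequence screens

* **TAT signal**: regex `[ST]RR.[FGAVML]` (paired arginines mandatory)
  within the first 50 residues; configurable. Genes without a start codon
  return `not_assessable` — a truncated N-terminus cannot show or lack a
  signal peptide.
* **Twin Fe-S motif**: non-overlapping matches of the ferredoxin-type
  four-cysteine spacing `C-x2-C-x2-C-x3-C` (spacings configurable); a
  typical RdhA carries two.
* **Transmembrane helices**: mean Kyte–Doolittle hydropathy over a 19-aa
  sliding window, threshold 1.6, overlapping passing windows merged into
  one helix. This is a deliberate heuristic replacement for HMM topology
  prediction; the only consumed quantity is the 2–3 helix count. Unknown
  residues (`X`) score 0, so masked runs can never reach the threshold, and
  none of the detectors can fire on masked sequence.
* **rdhB neighborhood**: candidate companions lie within 2 kb of an rdhA
  interval boundary (nearest-boundary distance, strand-agnostic, invariant
  under coordinate translation), encode < 150 aa and carry 2–3 helices.
  Genes abutting a contig end are reported separately as
  unassessable-length flanking homologs rather than rejected — their true
  length is unknown.

These regex/hydropathy detectors are stand-ins for profile-HMM domain
models; HMM-based domain calls can also be ingested as tabular annotations,
and the rdhA group chooser requires ≥ 50% of a group's members (boundary
inclusive) to carry a passing RdhA-family annotation.

## Trees and clusters

Trees arrive as Newick with internal-node labels as support values in
[0, 1]; the root, having no parent edge, counts as support 1.0, and an
unlabeled internal node counts 0.0 (never silently "supported"). Pruning by
domain evidence removes maximal all-negative clades — internal nodes none
of whose leaves carry the domain — while a lone negative leaf inside a
positive clade is retained (elimination is per-subtree, not per-leaf; the
operation is idempotent). Clusters are named from seed leaves: the smallest
clade containing the seeds defines membership, `supported` iff its support
is ≥ 0.90 (inclusive), else `tentative` with the support recorded; where
clades nest, a leaf keeps the smallest (most specific) cluster. External
reads inherit the cluster of their best-scoring classified subject, ties
broken by identity then subject id; unhit reads are `unclassified`.

## 16S fragment rules

An rRNA hit is accepted iff the alignment is ≥ 100 bp and either reaches a
query end (tolerance 0 bp by default, configurable) or covers the reference
gene over its full length — an internal partial match against a longer
reference is rejected. LSU/SSU conflicts on one region resolve to the
higher score. Overlapping accepted fragments of one clone on one subject
merge into their union. Coverage of a reference gene is total accepted
fragment length over its length; taxon frequencies are tabulated per pool
at a chosen rank of the subject's taxonomy path, with unresolvable paths
binned as `unclassified`. Classification itself is external; only the
acceptance arithmetic is implemented here.

## The synthetic community generator

The generator emulates the study conditions the analysis assumes: a
reference catalog of hundreds of genomes in which the target family is rare
(default 0.04 copies/genome) while universal markers are single-copy
everywhere; a community carrying the family at a planted rate (default
0.5 copies/genome); and paired-end clone libraries (default 2–3 kb inserts,
650–800 bp reads — the insert length interval is exposed as configuration
since only the shearing range is known) sampled from genomes proportional
to abundance × genome length. Scaled-down sizes are used throughout
(hundreds of genomes, 10²–10³ groups, 10³–10⁴ clones per pool) so the full
suite runs in seconds while keeping every estimator in its working regime.

Notable choices:

* The target family's total copy count is `round(rate × n_genomes)` spread
  round-robin rather than drawn binomially, so the community's true
  abundance-weighted rate equals the requested rate exactly and recovery
  tests compare against a known constant.
* Gene order within each genome is shuffled: a linear synthetic genome
  under-covers its two ends (no insert extends past a boundary), and a
  fixed order would bias the same groups low in every genome. Real
  prokaryotic genomes are circular; shuffling is the cheap fix that leaves
  the marker-mean identity intact.
* Synthetic proteins use a reduced alphabet without C or R, so planted
  Fe-S blocks and TAT signals are the only possible matches; coding
  sequence is one fixed codon per residue; genes are ungapped forward-strand
  ORFs. Uniform base composition, no chimeras, no sequencing-error or
  amplification-bias model — passing tests demonstrate estimator
  correctness under the model's assumptions, not robustness to real-world
  artifacts.
* Planted rdhA/rdhB loci and decoys (160 aa, > 2 kb, single-TM variants)
  are appended to contigs with recorded coordinates, followed by a trailing
  spacer so planted genes never touch the contig end (which would read as
  truncation).
* Read quality is uniform Q40 by default; the trimming rule (longest run of
  non-overlapping 20-bp windows with ≥ 80% of bases ≥ Q20, trailing partial
  window judged on its own length, leftmost tie kept) and the masking rule
  (bases < Q15 → `X`) are implemented and tested on constructed quality
  strings.

## Numerical and formatting conventions

Coordinates are 0-based half-open internally, 1-based inclusive only in
GFF-like files on disk. All randomness flows through one explicit integer
seed per call; identical seeds give byte-identical outputs, including the
pipeline's analytical tables. Ratios print with two decimals below one and
one decimal at or above one (half-up, after clearing float representation
noise at the 9th decimal); machine outputs keep full precision. Whether the
marker mean should be gene-length-weighted is not determined by the
measurement model; the unweighted mean of per-group coverages is used.

## Known limitations

Assembly, gene prediction, HMM scanning, multiple alignment and tree
inference are out of scope — contigs, gene calls, domain annotations and
support trees are inputs (or synthesized). The urn composition for the
overrepresentation test is a documented convention, not uniquely pinned
down by the measurement model. The hydropathy helix counter approximates
but does not reproduce HMM topology prediction near its decision boundary.
The synthetic generator's realism limits are listed above; in particular
conclusions about multiple-displacement-amplification bias are outside what
these simulations can support.
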