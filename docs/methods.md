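# Methods

`heatmir` implements an integrative analysis of paired miRNA/mRNA
time-course expression data from a heat-stress experiment on rice
post-meiosis panicles: five timepoints (0 min control, 10 min, 20 min,
60 min, 2 h at 40 °C), two biological replicates each, miRNA and mRNA
probes measured on one single-dye array platform and expressed as log2
intensities. This note records the model, the numerical choices, and what
the synthetic validation does and does not establish.

## Preprocessing

**Present-call filtering.** Each cell of the matrix carries a detection
flag: P (detected), A (not detected), M (compromised). A probe is kept when
at least `min_present` samples call it P; the default generalizes the
design's "6 of 10" rule as `ceil(0.6 * n_samples)` so the same rule applies
to simulated designs of any size. Filtering is monotone in the threshold
and never reorders probes.

**Quantile normalization.** Every sample's distribution is forced to the
cross-sample mean of order statistics. Within-sample ranks are preserved.
Ties receive the mean of the target quantiles their tied block spans — a
deterministic, permutation-invariant rule. A consequence worth knowing:
with ties present, the post-normalization sorted columns are equal only up
to the tie-averaging; on continuous (tie-free) data they are exactly equal.
Probes containing missing values must be dropped beforehand; the pipeline
does this with a logged count.

**Baseline to median.** Each probe is centered on its own median across all
samples (idempotent, rank-preserving within a probe). Values then read as
per-probe deviations in log2 units. Raw-scale input can be log2-transformed
at load with a configurable floor (default: clip at 1.0) to avoid −∞.

## Differential expression

Each treatment timepoint is contrasted against the 0-min control with a
two-sample test on the normalized values; an entity is differentially
expressed (DE) when |log2FC| ≥ 1.0 (inclusive) **and** p < 0.05 (strict) at
one or more timepoints. No multiple-testing correction enters the call — a
deliberate mirror of threshold-based microarray practice at n = 2 — but a
BH-FDR column is emitted for reference.

Two tests are provided:

* **student_t** — pooled-variance two-sample t with n₁+n₂−2 df. Pooled
  rather than Welch because the Welch df estimate degenerates with two
  replicates per group.
* **moderated_t** (default) — empirical-Bayes variance moderation. Writing
  s² for an entity's pooled variance on d df, the across-entity spread of
  s² is matched to the scaled-F model s² ~ s₀²·F(d, d₀) by method of
  moments (matching the mean and variance of s² gives d₀ and s₀²; when the
  observed dispersion is no larger than sampling noise alone predicts, d₀ =
  ∞ and all variances shrink fully to s₀²). The posterior variance
  (d₀s₀² + d s²)/(d₀+d) then enters a t statistic on d+d₀ df. With two
  replicates per group the raw variances are extremely unstable, which is
  why moderation is the default. Setting the prior weight to zero recovers
  the plain t exactly (tested).

Degenerate inputs: groups with identical values and identical means give
p = 1; zero variance with a non-zero difference gives p = 0.

**Family aggregation.** Mature miRNA ids collapse to families by the naming
convention: strip variant letters and arm/isoform suffixes
(osa-miR169g → osa-miR169, osa-miR397b.2 → osa-miR397). Only DE members
enter a family profile. Per timepoint, the family is *up* if at least one
member is significantly up and none significantly down (*down*
symmetrically), *conflict* if both occur, *none* otherwise. The overall
label is the common direction when all significant member calls agree,
else *up_down*. Direction at a timepoint requires significance there, not
merely the sign of the fold change.

## Target-site scoring

Plant miRNAs pair near-perfectly with their targets, so target prediction
is complementarity scanning with a cumulative penalty (the *expectation*;
lower is better): match 0, G:U wobble 0.5, mismatch 1.0, each gapped
position 2.0, all doubled in the seed region (miRNA positions 2–13 from the
5′ end). Sites with expectation ≤ 3.0 (default cutoff) are reported. The
scheme and cutoff reproduce the penalty structure of the established plant
target predictors while being fully specified here; all constants are
configurable.

The scanner evaluates the antiparallel duplex at every transcript window:
the gapless configuration plus, with `max_gaps = 1` (default), every
single-bulge configuration — one unpaired miRNA base at any position, or
one unpaired target base at any internal position (a bulge at a duplex
terminus is not a duplex feature and is excluded). A gap column takes the
miRNA position of the next miRNA base (clipped to the miRNA length) for
seed weighting. The implementation vectorizes each bulge family with
prefix/suffix cumulative penalty sums; a test proves it equal to exhaustive
enumeration of the same space on random instances.

Overlapping passing sites collapse to the best-scoring one (ties to the
smallest start). Coordinates are 1-based fully-closed transcript
coordinates, 5′-most base first.

**Regulation mode.** Plant AGO-mediated cleavage occurs opposite miRNA
positions 10–11; a site whose alignment carries a mismatch or gap at either
central position is classified `translation_inhibition`, otherwise
`cleavage`.

**Family-level prediction.** Targets are predicted for DE miRNAs; within a
family, member predictions are unioned and each gene kept once with the
best member site ("removing repeated genes").

## Anti-correlation pairing

A predicted (family, gene) pair is *high confidence* when both sides are DE
and their expression changes oppose during the time course. Two readings
are implemented because the informal rule "opposite direction within any
time period" is ambiguous:

* `same_timepoint` (default, stricter) — some timepoint exists at which
  both sides are significant with opposite directions; the supporting
  timepoints are reported.
* `overall` — the overall direction labels oppose; an `up_down` label on
  either side is compatible with anything, matching how mixed families
  carry targets of both signs in the curated table.

A family timepoint in `conflict` supports no pair at that timepoint. The
per-timepoint up/down count table over DE miRNAs and high-confidence
targets is the plotting input for the time-lag figure.

## Network and modules

Nodes are families and genes; family→gene edges carry the best site's
regulation mode; gene–gene edges carry PPI combined scores in [0, 1] and
are admitted only when the score is strictly greater than 0.7 and both
endpoints already appear in a pair. A *coregulatory module* is a connected
component containing ≥ 2 family nodes — the simplest definition consistent
with modules formed either through shared target genes or through
interactions among target proteins. The hub is the family of maximum
degree, ties to the lexicographically smallest id. Construction is
deterministic; identical inputs give byte-identical GraphML.

## Annotation

GO-Slim classification counts (not enrichment statistics): per aspect
(BP/CC/MF), the number of input genes carrying each term, with percentages
over the aspect's annotated genes — a gene may carry several terms, so
percentages within an aspect can sum past 100. Characterized-gene lookup is
an inner join of the gene list against a static table of curated records
(one row per locus–character record, plus the distinct-locus count). Both
consume file snapshots; the packaged GO-Slim table is a small synthetic
stand-in for a live classification-service export, so its counts
characterize the code path, not rice biology.

## Packaged curated tables

`rice_hc_pairs.tsv` (183 rows: 29 families, 178 distinct genes, five genes
shared by two families) and `rice_ogro_records.tsv` (20 records over 13
loci) are version-controlled transcriptions of the published
high-confidence pair and characterized-gene tables for this experiment,
pinned by checksum tests. Fixture mode drives pairing, network and
annotation from them directly, which reproduces the headline counts —
29 families, 178 targets, a maximum of 18 targets (osa-miR414), 13
characterized loci, and three shared-target coregulatory modules
(osa-miR156/529/531, osa-miR160/166/390, osa-miR419/440) — without the raw
arrays. Site-level modes are not part of the curated table, so fixture-mode
regulation edges default to `cleavage`.

## Synthetic-data generator

The generator emulates the study design and plants recoverable ground
truth:

* **Expression.** Entity i in sample s at timepoint t:
  y = baseline_i + sign_i · effect · profile(t) · 1[i ∈ DE] + ε,
  ε ~ N(0, noise_sd²). Defaults: 200 miRNA probes (grouped into families of
  1–3 members that move together) plus 1800 gene probes, effect 2.0 log2
  units, noise sd 0.2, two replicates. The default *ramp* profile
  (0.5, 0.75, 1.0, 1.0 of the full effect over the four treatment
  timepoints) mirrors a response that builds to its maximum late in the
  course; a constant *step* profile is available.
* **Dynamic range.** Expressed probes draw baselines from U(6, 14);
  a `frac_background = 0.1` population draws from U(4, 6.5) and is never
  DE — these are the not-detected probes that occupy the low tail of every
  sample, as on a real array. Cells below the detection floor (6.5, the top
  of the background range) are flagged A with probability 0.3. Without this
  population, quantile normalization visibly compresses fold changes at the
  distribution tails (only treated samples would occupy them), which is an
  artifact of a truncated simulation, not of the method. Planted DE
  entities draw baselines from [floor + effect, top − effect] so the
  planted change stays inside the measurable range on both sides — an
  induction of a saturated probe, or repression into background, is not
  recoverable by any method and would contaminate the ground truth.
* **Pairs.** 80 % of DE families (the study observed 29 of 37) receive one
  anti-correlated DE target gene: opposite-signed effects at the same
  timepoints.
* **Sequences.** Random 21-nt miRNAs and 500-nt transcripts. Each planted
  pair receives a real site in its gene's transcript (alternating classes:
  perfect complement, expectation 0; one non-seed mismatch, expectation
  1.0); an equal number of non-paired DE genes receive decoy near-sites
  with two seed mismatches (expectation 4.0, safely past the 3.0 cutoff).
  Intended expectations are recorded and verified.
* **PPI.** Planted modules group genes of different planted pairs;
  within-module scores are U(0.75, 0.99), background scores U(0, 0.65), so
  the 0.7 cutoff separates them with a margin.

All randomness flows from one mandatory seed; the same seed reproduces
every matrix, sequence and edge table bit for bit.

**What passing tests show — and don't.** At this design the full pipeline
recovers planted pairs with precision and recall ≥ 0.9 and the planted PPI
modules exactly, and the DE caller holds sensitivity ≥ 0.9 at type-I error
≤ 0.05 over 2000 entities. The generator draws independent Gaussian noise
per cell and plants clean, margin-separated truth: it does not model
probe-specific biases, spatial artifacts, correlated replicates, saturated
probes, cross-hybridization, or target sites of intermediate quality, so
these results certify the inference chain's correctness under its own
assumptions, not its behavior on any real array.

## Problem sizes and runtime

Default synthetic runs use 2000 probes × 10 samples and scan DE-miRNA
members against the DE-gene transcript set (a few tens of thousands of
window scans); a full run takes seconds on one CPU. The reproduction
script (`scripts/acceptance.py`) performs one fixture-mode run, one full
default synthetic run, and one 2000-entity DE calibration.

## Known limitations

* The exact scoring of the original online target predictor is proprietary;
  the documented scheme reproduces its penalty structure but not its exact
  numbers, so absolute expectations are comparable only within this
  implementation.
* The moderated test is a method-of-moments fit, not the maximum-likelihood
  empirical Bayes of the reference microarray packages; with two replicates
  the two agree closely in calls but not bit-for-bit.
* "Baseline to median of all samples" is implemented per probe (the usual
  desktop-software default); a global-scalar reading would differ by a
  constant per probe only.
* Family totals reported for the original experiment are internally
  inconsistent (21 + 16 + 3 ≠ 37); the pipeline reports its own consistent
  tally from whatever data it is given.
* At most one bulge per duplex (`max_gaps = 1`); multi-bulge plant duplexes
  are rare but exist.
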