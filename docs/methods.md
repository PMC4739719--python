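# Methods

This note documents the statistical model, the decision rules, the synthetic
data the pipeline is validated on, and the numerical choices — in enough
detail to judge what passing tests do and do not demonstrate about real data.

## Study design and coordinate conventions

The pipeline targets knockout-cohort designs in which total RNA from
homozygous (HOM) biological replicates is pooled per tissue before library
construction, so each (mutant line, tissue) contributes exactly one HOM
library compared against one wild-type (WT) library. Two allele classes are
modelled: gene traps (TRAP), a cassette inserted in an intron 5′ of a
critical exon, and deletions (DEL), removing the ORF from the translational
start to the 3′ UTR (or only the proximal exons of very large genes).

Coordinates are 1-based inclusive throughout; BED input is converted on
read. A gene's *centrum* is the floor of the midpoint of its span (the
rounding convention is ours; the choice is irrelevant at the 50-kb bin
scale). Neighbor distances are centrum-to-centrum, signed and
strand-adjusted: for a minus-strand target the genomic difference is
negated, so negative always means 5′ of the target's transcription
direction. The ±500 kb window is boundary-inclusive. Exon ordinals (trap
introns, deleted-exon ranges, exon profiles) count in transcription
direction.

## Differential calls without replicates

With one library per group, a per-gene dispersion is not estimable. The
model:

- **Normalization.** Median-of-ratios size factors over genes with nonzero
  counts in every library; normalized count = raw / factor.
- **Dispersion trend.** Counts are negative-binomial with
  Var(K) = μ + αμ². For each gene in each pair, with normalized counts
  (x, y), m = (x+y)/2 estimates the null mean and (x−y)²/2 the within-pair
  variance. Genes are pooled across pairs and binned by m (20 quantile
  bins); per bin the moment estimator α̂ = (mean var − mean m) / μ̂² is
  formed with μ̂² = mean(m²) − mean(var)/2, which removes the upward noise
  bias of m². The trend α(μ) = a₀ + a₁/μ is a weighted least-squares fit to
  the bin estimates with nonnegative coefficients, floored at
  α_min = 0.01. On simulated NB counts at α = 0.1 the fit recovers the
  dispersion within a few percent; on Poisson counts it collapses to the
  floor. Caveat: the estimator ignores the 1/s inflation of normalized-count
  variance for size factors far from 1; with library sizes within ~2× this
  bias is below the fit's own noise.
- **Pair test.** Under the null both counts share the normalized mean
  m = (k_h/s_h + k_w/s_w)/2. Conditional on the total S = k_h + k_w, the
  distribution of the HOM count over outcomes (a, S−a) is enumerated from
  the NB model with dispersion α(m); the two-sided p doubles the smaller
  tail (point included), capped at 1. For S > 20,000 the enumeration is
  windowed to ±50 SD around the conditional centre; the excluded mass is
  far below double precision. Equal normalized counts give p = 1 exactly;
  swapping the groups preserves p and flips the direction.
- **Calling.** Direction (up/down/ns) uses unadjusted p < 0.05 — the
  deliberately permissive criterion appropriate to a replicate-poor screen —
  with Benjamini–Hochberg adjusted p (within pair) reported alongside.
  log₂ ratios use a pseudocount of 0.5.

Like any exact count test, the doubled-tail p is conservative when totals
are small: genes at a few counts per library cannot reach p < 0.05 at all.
Calibration is therefore asserted where it can hold — among quantifiable
genes (normalized mean ≥ 50) the empirical type-I error sits within
Monte-Carlo error of the nominal 0.05, and the same discreteness argument
applies to the empirical-null rates below. On a transcriptome dominated by
barely-detected genes the test is conservative, not anticonservative.

## Flanking survey, topography and empirical null

Per target, every annotated gene or miRNA within the window (target
excluded) is a neighbor; a library flags `has_up`/`has_down` if any
neighbor is called up/down in that library, and target-level flags are the
OR over the line's libraries. Topography bins dysregulated neighbors into
half-open 50-kb intervals tiling [−500, +500) kb by signed distance (a
neighbor exactly on the +500 kb boundary joins the last bin; co-located
centrums, d = 0, fall in [0, 50)). Histograms and totals count unique
(target, neighbor) pairs across libraries by default; a per-library
instance convention is available (`dedupe="instance"`), since a published
total may follow either convention.

The genome-wide empirical null takes every (gene, library) down-regulated
at unadjusted p < α as a focal instance and every annotated gene within
±500 kb of it (itself excluded) as a neighbor instance; f_up/f_down are the
fractions of neighbor instances up-/down-regulated in that same library.
Because one (gene, library) call is counted once per focal gene whose
window covers it, instances are clustered; the result therefore carries an
effective sample size n_eff = (Σw)²/Σw² over the per-call multiplicities w,
and Monte-Carlo error statements about f_up/f_down use n_eff, not the raw
instance count.
Observed flanking counts are compared against it with a Pearson
goodness-of-fit (df = 1, no continuity correction — the plain reading of a
"chi-squared statistic"), and allele classes with a 2×2 Pearson homogeneity
test. Note the unit mismatch inherited from the original analysis: the
flanking frequencies are per *target* while the null is per
*neighbor-instance*; the comparison is performed as published, and both
definitions are exposed so the reader can judge it.

The 3′-bias estimator (`pipeline.estimate_3prime_bias`) uses only
up-regulated neighbors that remain significant after BH adjustment. At the
nominal unadjusted threshold, the thousands of neighbor instances in a
cohort contribute chance calls in numbers comparable to the true local
effects, and chance calls are side-symmetric — they dilute the spatial
signal toward 1/2. Confident calls are a side-independent subsample of the
true effects, so the estimator remains unbiased for the planted fraction.

## Targeting-confirmation classifier

Mutants are flagged for inspection when the targeted gene is expressed
(≥100 normalized reads in either library) yet the HOM library retains at
least 20% of the WT signal; flags aggregate across tissues by OR. Flagged
mutants' per-exon HOM/WT profiles (5′→3′, transcription order) run through
a fixed cascade, most specific structural evidence first:

1. both profiles (exonic + intronic) below the expression floor
   F = 100 → **indeterminate**;
2. DEL with HOM reads on the deleted exons (≥ 20% of WT there, and > 0)
   → **failed_targeting**;
3. DEL with more intronic than exonic HOM reads → **intronic_only**;
4. partial DEL with silent deleted exons but retained distal exons at or
   above the WT level → **distal_retention**;
5. TRAP with *no post-trap exon present* → **trap_complete**;
6. TRAP with the first post-trap exon absent but a later one present
   → **splice_around**;
7. every expressed exon within 2-fold of the (reduced) gene-level HOM/WT
   ratio → **uniform_hypomorph**;
8. otherwise **confirmed_null** if the HOM total is below 20% of WT, else
   **failed_targeting**.

Per-exon presence in steps 5–6 is *relative*: exon e is present when its
HOM count is at least max(1, 0.20 × WT count). An earlier absolute
formulation (post-trap total below F) conflated two distinct patterns —
a late trap leaves so few post-trap exons that even clear splice-around
resumption stays under an absolute floor, and a uniformly reduced hypomorph
can likewise dip under it. The relative rule separates all three at any
depth where WT is quantifiable. The constants F = 100 and r = 0.20 reuse
the flag criteria rather than introducing new thresholds.

The classifier is total over non-negative profiles and scale-invariant
wherever the floor is not binding. Mutant-level aggregation: failed
targeting in any library fails the mutant; otherwise the most common
confirming verdict; indeterminate only if every library is.

## Regulatory-element disruption

Inputs are static BED files (TFBS with a high/low confidence column; ChIP
peaks for Pol2/CTCF/p300); no live database is queried. TRAP: disruptive
iff ≥2 *high-confidence* TFBS overlap the gene body 3′ (transcription
direction) of the insertion intron — the reading of "inserted between the
promoter and ≥2 distal sites". DEL: disruptive iff ≥2 TFBS of any
confidence and ≥1 ChIP peak of any factor overlap the deleted span (the
deleted exons plus the introns between them); high confidence is required
only where stated, i.e. for TRAP. Overlap is any-intersection on 1-based
inclusive intervals. Calls are monotone in the evidence.

## Synthetic cohorts: what they emulate, and what they do not

Defaults mirror the study shape: 29 DEL and 15 TRAP lines, 4 tissues,
gene density 20/Mb, log-normal gene lengths (median 15 kb) and expression
(median 100 normalized reads, log-sd 1.5), NB dispersion α = 0.05, an
8-fold knockdown of each target. Local effects are planted per
(target, neighbor) — shared across that line's tissues, as cis effects
are — with probability p·exp(−|d|/100 kb) (p = 0.20 up, 0.25 down; the
decay scale reflects that most local effects concentrate within ~200 kb,
and the p values were chosen once so that roughly half the targets show
some local effect, the cohort-level rate reported for deletion alleles).
Planted up-effects land 3′ with probability 0.774 — the published 3′
fraction — via side-dependent planting probabilities, down-effects are
side-symmetric, and planted effects are ±2 on the log₂ scale. Exon-profile
scenarios realize each QC verdict at a default WT depth of 1,000 reads per
gene (the well-expressed regime in which flagged genes are actually
inspected), with optional Poisson noise. Every draw is fixed by the seed.

Calibration analyses (type-I error, empirical-null rates) use a null
variant of this generator — no knockdown, no planted effects — with
expression centred at 300 (log-sd 1.0): the exact test's low-count
conservatism would otherwise mask miscalibration rather than reveal it, as
discussed above.

Deliberately not emulated: read-level sampling (counts are drawn directly,
so mapping artefacts, multi-mapping and 3′ coverage bias are absent),
isoform structure, correlated co-regulation of gene clusters,
tissue-specific effect presence (planted effects are fully shared across
tissues), and overlapping genes. Passing the recovery tests therefore shows
the inference machinery is correct under the stated model, not that the
model captures every failure mode of real libraries.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of ~1,000–2,600 genes,
50–100 target lines and up to 100 library pairs — sizes at which the
planted spatial and calibration signals are measurable with useful
Monte-Carlo precision while a full run stays in the minutes range on one
CPU. Statistical checks use 3-SD Monte-Carlo bands (calibration) or 95%
binomial confidence intervals (planted-fraction recovery) at the achieved
event counts. All randomness flows through explicit seeds; re-running any
stage with the same seed and inputs is bit-identical, and the pipeline's
run log records the resolved parameters and per-stage record counts without
timestamps.

## Known limitations

- The pair test's conditional enumeration treats the plug-in common mean
  and the fitted trend dispersion as known; both are estimated, and the
  residual miscalibration (at the sub-percent level in our checks) is not
  propagated.
- The no-replicate design cannot separate biological variability from
  treatment effects; the permissive unadjusted-p criterion trades false
  positives for sensitivity exactly as the original screen did.
- The empirical-null chi-square comparison inherits the per-target vs
  per-instance unit mismatch described above.
- Verdicts from RNA evidence alone cannot establish loss of protein
  function; splice-around and hypomorph calls mark candidates for protein-
  level follow-up, not conclusions.
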