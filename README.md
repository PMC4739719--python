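# flankscan

Local **position effects** of targeted mouse mutations, measured from RNA-seq
read counts. When a gene is knocked out — whether by a gene-trap cassette
(TRAP) or by deletion of the open reading frame (DEL) — the insertion can
also dysregulate genes *flanking* the target: cis-regulatory elements are
deleted or separated from their promoters, the heterologous promoter in the
neo selection cassette acts on downstream genes, and exogenous DNA can
trigger local silencing. `flankscan` quantifies these effects and screens
whether each targeting event actually silenced its gene.

It is written for mouse geneticists and transcriptomics analysts working
with knockout-consortium-style designs: pooled biological replicates, one
HOM and one WT library per tissue, several tissues per mutant line.

## What it computes

- **Differential calls without replicates** (`de_test`). Libraries are
  normalized with median-of-ratios size factors. With n=1 per group, the
  HOM/WT pair is treated as pseudo-replicates of a common null mean and a
  mean-dispersion trend α(μ) = a₀ + a₁/μ (negative-binomial variance
  μ + αμ²) is fitted across genes. Each gene is tested with a two-sided
  exact NB test conditional on the pair total; direction is called at
  unadjusted p < 0.05, with BH-adjusted p carried alongside.
- **Strand-aware flanking survey** (`neighborhood`). All genes (miRNAs
  included) within ±500 kb of the target's centrum (span midpoint), with
  signed centrum-to-centrum distances: negative = 5′ of the target's
  transcription direction, positive = 3′. Per-target and per-library
  frequencies of ≥1 up-/down-regulated neighbor, 50-kb spatial topography
  histograms, median distances, and a gene-density contrast between targets
  with and without local effects.
- **Genome-wide empirical null** (`empirical_null`). The background
  frequency of up-/down-regulated genes within 500 kb of *any*
  down-regulated gene in any library, and Pearson chi-square comparisons
  (goodness-of-fit against the background rate; 2×2 homogeneity between
  allele classes).
- **Targeting confirmation** (`targeting_qc`). A flag rule (gene expressed
  at ≥100 reads and HOM retains ≥20% of WT) plus an exon-pattern classifier
  that distinguishes confirmed nulls from complete traps, splice-around
  events, uniform hypomorphs, distal-exon retention after partial deletion,
  intronic-only signal, and failed targeting.
- **Regulatory-element disruption** (`reg_disruption`). From user-supplied
  TFBS and ChIP-peak BED files: a TRAP is scored disruptive when ≥2
  high-confidence TFBS lie 3′ of the insertion intron inside the gene body;
  a DEL when ≥2 TFBS plus ≥1 corroborating ChIP peak fall in the deleted
  span.
- **Synthetic cohorts** (`synthetic`). A generator that emulates the study
  design end to end — NB counts, 8-fold target knockdown, planted local
  effects whose up-regulated neighbors are 77.4% 3′-biased and whose
  down-regulated neighbors are side-symmetric, with distance-decaying
  planting probability — plus exon profiles realizing every QC verdict and
  interval fixtures for the disruption rules. Every stage of the pipeline
  can therefore be exercised and validated without any external data.

## Worked example

Simulate a small cohort (4 DEL and 2 TRAP lines, 2 tissues each) and run
the full pipeline from the shell:

```sh
flankscan simulate --seed 7 --out-dir sim \
    --n-targets-del 4 --n-targets-trap 2 --n-tissues 2
flankscan report --annotation sim/annotation.tsv --alleles sim/alleles.tsv \
    --counts sim/counts.tsv --meta sim/libraries.tsv --out-dir report
```

`report/frequencies.tsv`:

```
allele_class	by	pct_up	pct_down	n
DEL	target	50.0	75.0	4
DEL	library	50.0	62.5	8
TRAP	target	100.0	50.0	2
TRAP	library	50.0	50.0	4
```

50% of the DEL targets had at least one up-regulated gene and 75% at least
one down-regulated gene within 500 kb, in at least one tissue; the
per-library rows count tissues instead of targets.

`report/topography_medians.tsv`:

```
median_abs_down_kb	median_3p_up_kb	median_abs_5p_up_kb	n_dysregulated	frac_up_3prime
145.0985	140.55	275.1075	16	0.75
```

Sixteen unique (target, neighbor) pairs were dysregulated; 75% of the
up-regulated ones lie 3′ of their target (this cohort plants up-effects 3′
with probability 0.774). `report/genome_wide_null.tsv` holds the
genome-wide background (here f_up = 0.0212, f_down = 0.0287 over 5,151
neighbor instances around 268 down-regulated focal genes — about α/2 each,
as expected when no planted effect inflates the rates), and
`report/null_comparisons.tsv` the chi-square tests of the flanking
frequencies against it.

The same analysis is available as a library:

```python
from flankscan import de_test, pipeline
from flankscan.synthetic import SyntheticConfig, generate_annotation, generate_counts

cfg = SyntheticConfig(seed=7, n_targets_del=4, n_targets_trap=2, n_tissues=2)
genes, alleles = generate_annotation(cfg)
counts, meta, pairs, truth = generate_counts(cfg, genes, alleles)
res = pipeline.analyze_cohort(genes, alleles, counts, pairs, meta)
print(res["frequencies"]["DEL"]["target"])   # {'pct_up': 50.0, 'pct_down': 75.0, 'n': 4}
```

## Working from a published supplementary table

If you have the study's supplementary data sheet exported as TSV (per-gene
normalized HOM/WT counts, centrum distances and stored p-values for every
library), `reproduce-s1` recomputes every table-derivable summary —
per-target and per-library dysregulation frequencies by allele class,
topography medians, the 3′ fraction of up-regulated neighbors, total
dysregulated pairs under both dedupe conventions, gene-density means, and
QC flag fractions — directly from the stored values, bypassing the internal
differential test:

```sh
flankscan reproduce-s1 --s1 data/s1_table.tsv \
    --classes data/s1_allele_classes.tsv --out s1_summary.json
```

The export itself is not redistributed with the package; place it at
`data/s1_table.tsv` with a two-column `line → allele_class` map beside it.

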