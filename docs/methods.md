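# Methods

## Scientific model

`endosign` implements an analysis of genomic imprinting in *Arabidopsis
thaliana* endosperm. The endosperm is triploid — two maternal genome
copies and one paternal — so a biallelically expressed gene is expected
to contribute maternal reads at a fraction of 2/3 of its informative
(parentally assignable) reads. Imprinted genes deviate from this
dosage: maternally expressed genes (MEGs) exceed it strongly, and
paternally expressed genes (PEGs) fall below parity.

The package couples two independent routes to PEG identification:

1. **Epigenetic signature.** The silenced maternal allele of a PEG
   carries a tripartite repressive signature: CHG methylation already
   present in the central cell of the female gametophyte, plus
   H3K27me3 (Polycomb) and H3K9me2 (heterochromatic) on the maternal
   allele in the endosperm. Each feature is discretized into a level
   0–4 and the levels are summed into a 0–12 score; the score-12
   category is the predicted PEG set.
2. **Expression caller.** Reciprocal-cross (Col×Ler and Ler×Col)
   allele-specific RNA counts are tested per gene against the 2:1
   dosage with a 1-df chi-square goodness-of-fit test,
   Benjamini–Hochberg adjusted per cross direction. A MEG call
   requires ≥ 85% maternal reads, a PEG call ≥ 50% paternal reads,
   each with q < 0.01 **in both cross directions**; genes with fewer
   than 20 informative reads in either direction are not testable.

The hypergeometric over-representation of predicted (score-12) genes
among expression-called PEGs quantifies how well the signature
predicts imprinting.

## ChIP normalization

Per-allele ChIP coverage is normalized against an H3 control as
`log2((C + ε)/(H + ε))` in 150-bp bins, with read-equivalent
pseudocount ε = 1. ε avoids ±∞ at empty bins and is symmetric in the
two channels; bins empty in *both* channels are missing (NaN), never
zero. Tracks are standardized genome-wide with a z-score
transformation using the population-sd convention (ddof = 0); a
per-chromosome mode is available by flag. A constant track z-scores to
all zeros with a warning rather than dividing by zero.

Per-gene summaries are the unweighted mean z over all bins overlapping
the gene body, with boundary-straddling bins counted whole — the
simplest reproducible rule at 150-bp resolution. Metagene profiles
cover −2 kb…TSS…TES…+2 kb with 100-bp flank bins and 40 equal-length
body bins (80 positions); profile values are overlap-weighted means of
the underlying track bins, minus-strand genes are orientation-flipped
before averaging, and missing bins are excluded per position.

## Methylation levels

The gene-level estimator is the *weighted* methylation level: summed
methylated reads over summed total reads across the gene's cytosines
of one context (CG, CHG or CHH). It is invariant to splitting a
cytosine's reads across records and robust to coverage variation; a
per-site mean is available by flag. A gene with zero covered cytosines
has a *missing* level, never 0. Gene intervals are the annotated body
only by default (flanks configurable).

## Epigenetic score

Level breakpoints default to the quantiles [0, ¼, ½, ¾] of the genes
with present (finite) signal: genes lacking signal score 0, present
genes split into quartile levels 1–4, summing to 0–12 across the three
features. The binning is closed-left (a value equal to a breakpoint
counts at or above it), and breakpoints are fully configurable for
users holding an explicit scoring table. A maternal-specific presence
flag (maternal z ≥ 1 and paternal z < 1, threshold configurable)
supports overlap analyses of singly- versus doubly-marked genes.

## Imprinting caller details

* No Yates continuity correction by default (flag provided): at 1 df
  with the caller's ≥ 20-read counts the correction is conservative
  and immaterial.
* FDR is controlled per cross direction over testable genes, matching
  the in-both-directions call criterion.
* Replicate libraries are summed per direction before testing.
* Contamination: maternal seed-coat transcripts are modeled as a
  purely maternal read source mixing into the endosperm signal, so
  the observed pooled maternal fraction is
  `f_obs = (1 − c)·(2/3) + c`. The estimator inverts this and clamps
  c to [0, 1]. By default all supplied genes are pooled — imprinted
  genes bias `f_obs` negligibly at genome scale — with an option to
  restrict to a known biallelic set. The estimate is reported per
  direction; replicate exclusion is left to the user.

## Enrichment statistics

Hypergeometric over-representation is the upper tail P(X ≥ k)
*including* the observed overlap, evaluated in log space
(`logsf`), so extreme enrichments report a finite log10 p rather than
0. Per-category composition tests are 2×2 chi-square (no correction)
against the score-12 reference category, switching to the exact
hypergeometric (Fisher) p when an expected cell falls below 1.
Wilcoxon rank-sum is exact by full enumeration of rank subsets
(ties included) up to a pooled size of 12 and otherwise uses the
tie-corrected normal approximation without continuity correction.

## Synthetic data generator

The generator emulates the statistical structure of the study design,
not its sequences:

* **Annotation** — `n_genes` non-overlapping stranded genes, lengths
  uniform on 1–3 kb, placed by multinomial gap allocation on a single
  chromosome (placement is gap-based, so non-overlap is guaranteed;
  infeasible configurations fail upfront with the violated
  constraint).
* **Classes** — 10% PEG, 10% MEG, 80% biallelic by default, with true
  maternal fractions 0.10, 0.95 and 2/3.
* **Histone marks** — coverage per 50-bp step is
  `H3 · 2^z`, `z ~ N(effect, noise_sd)` with effect = +2.0 log2 units
  on maternal-allele gene bodies of PEGs and 0 elsewhere; H3 control
  flat at depth 100. With `noise_sd = 0` the log2 ratio equals the
  effect exactly, which pins down the generator in tests. Default
  `noise_sd = 0.5` gives clear but not trivial class separation at
  40-bin gene bodies.
* **Methylation** — one cytosine per 50 bp per context within gene
  bodies; per-site coverage Poisson(10); methylation probability at
  genic baselines CG 0.24 / CHG 0.08 / CHH 0.03, with central-cell CHG
  elevated by +0.40 on PEGs. The five sources (central cell, sperm,
  vegetative cell, endosperm maternal/paternal) share baselines, so
  sperm and vegetative CHG stay low as in the biological motivation.
* **Counts** — per gene, direction and replicate: total reads
  Poisson(depth/replicates); maternal reads binomial at
  `f_eff = (1 − c)·f_class + c`. A beta-binomial overdispersion knob
  (rho, default 0) is provided because real allele-specific counts
  are noisier than binomial. Reciprocal directions swap accession
  labels but preserve parental roles.

All randomness derives from one seed through fixed per-stage
substreams, so outputs are bit-identical across runs and each stage is
reproducible in isolation.

**What the generator does not emulate:** mappability and SNP-density
variation in read assignability, transposon-adjacent mark spreading,
linked genes sharing contamination, batch effects between replicates,
and expression-level heterogeneity beyond Poisson totals. Passing
tests therefore demonstrate correctness of the estimators and the
internal consistency of the signature→expression logic under the
assumed model, not performance on real sequencing data.

## Problem sizes and numerical choices

Validation runs use: 1000 genes × depth 100 for caller parameter
recovery (sensitivity ≥ 0.90, biallelic false-call rate ≤ 0.02);
5000 biallelic genes for FDR calibration; 2000 genes × 100 reads for
contamination recovery (±0.02); and a 500-gene end-to-end run for the
signature-enrichment check (score-12 enrichment of true PEGs at
p < 1e−6, and p > 0.01 when mark effects are zeroed). These sizes give
statistically decisive checks while keeping the full suite fast.

Degenerate inputs are handled explicitly: empty bins/missing levels
propagate as NaN rather than 0; zero-total genes are never chi-square
tested; constant tracks z-score to 0 with a warning; heavily tied
quantile breakpoints raise instead of silently collapsing levels.

## Known limitations

* The discrete scoring scheme is a documented reconstruction
  (3 marks × levels 0–4); an alternative published weighting can be
  reproduced via explicit breakpoints but is not bundled.
* The contamination estimator assumes contaminating reads are purely
  maternal and uniform across genes.
* The exact Wilcoxon path is O(C(n, n_x)) and is therefore capped at
  pooled n ≤ 12 by default.
* Single-chromosome simulation only; all analysis code, however, is
  multi-chromosome aware.
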