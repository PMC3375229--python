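# Methods

This note documents the statistical models, the synthetic-data generator,
numerical choices and known limitations of `nslseq`.

## Enrichment model

Reads are binned at 25 bp by their strand-aware 5′ end (each read counted
once; mass conserved). ChIP and input libraries are normalized with
median-of-ratios size factors: per sample, the median over bins — among
bins where every sample is non-zero — of count / across-sample geometric
mean. The enrichment track is

    log2FC = log2( (chip/sf_chip + ε) / (input/sf_input + ε) )

with the pseudocount ε (default 1.0) applied on the *normalized*-count
scale so its meaning does not depend on depth. A centered 400 bp moving
average absorbs the sonication fragment size; chromosome edges average
over the available bins only, so constant tracks are preserved exactly.

**Empirical FDR.** Negative smoothed log2FC values are taken as
experimental noise. On a grid of cutoffs (step 0.01, matching the
two-decimal precision of reported thresholds),

    FDR(c) = #{v ≤ −c} / max(1, #{v ≥ c}),

and `c*` is the smallest grid value with FDR ≤ the target (default 0.05).
An alternative noise model fits a half-normal to the negative tail
(σ² = mean of squared negatives) and replaces the numerator with the
expected noise exceedance count `2·#neg·(1−Φ(c/σ))`; both are exposed
because only the mirroring idea, not the exact fit, is pinned down. The
threshold is computed genome-wide by default. On synthetic data the two
models agree to within a fraction of a log2FC unit (see the test suite).

**Peak calling.** Maximal runs of bins ≥ c* become regions. Within a
region, adjacent local maxima are kept as separate summits only when the
valley between them drops below 50% of the lower flanking maximum
(subpeak-splitter behaviour; the original splitter's constant is not
published, 0.5 is this package's choice). Regions are split at the valley
minimum; every summit carries a 40 bp summit region (±20 bp).

## Target calling

A TSS is bound by a protein when `[tss−200, tss+200)` intersects any
summit region `[summit−20, summit+20)`. All coordinates are 0-based
half-open and touching intervals do **not** overlap, which fixes the edge
case `|summit − tss| = 220` as unbound. The TSS of a − strand gene is
`end − 1`. Venn partitions are computed exactly over all 2^k − 1 protein
combinations; class enrichment uses two-sided Fisher's exact tests.

## Pol II response

ΔPol II is the bin-wise difference of knockdown and control log2FC tracks
(negative = loss); per-gene values are medians over the bins fully inside
the 400 bp promoter window. Response tertiles (type-7 quantile cut points,
the R default) are formed among non-overlapping genes with control
promoter median ≥ c* and ΔPol II < 0 — and, in the pipeline, *within* the
bound and non-bound groups separately, so that both groups populate all
three strata (bound genes dominate the severe-loss tail so a joint cut
would empty the non-bound stratum 1).

The stalling index is `SI = log2(r_tss / r_body)` with r the
input-adjusted, size-factor-normalized read count per bp; promoter =
TSS ± 200 bp, body = gene minus 500 bp after the TSS and 500 bp before the
TES (strand-aware, which for half-open coordinates is `[start+500,
end−500)` on either strand). Filters are applied in order — gene overlap,
length > 1,300 bp, promoter median log2FC ≥ c* — and the failing filter is
recorded per gene. "Adjusted by the input" is not defined in the original
description; the default subtracts the normalized input from the
normalized ChIP counts and floors at zero, with a ratio variant switchable
(`adjust="ratio"`). Edge bins contribute fractionally (bp-weighted), so
constructed piecewise-constant coverage reproduces `SI = log2 k` exactly.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact null
distribution for tie-free samples with both n ≤ 25, otherwise the normal
approximation with continuity correction and mid-ranked ties; two
identical constant groups return p = 1.

## TRAP affinities

For a PWM of width W (columns regularized by mixing in a pseudocount
fraction 0.01 and renormalizing), the mismatch energy of the site at
offset i is `E_i = (1/λ) Σ_j ln(p_max,j / p_j(base))`, its occupancy
`R0 e^{−E_i} / (1 + R0 e^{−E_i})`, and the affinity of a sequence is the
occupancy sum over all offsets on **both** strands — so the affinity of a
sequence equals that of its reverse complement exactly. The score is the
natural log of the affinity. Defaults λ = 0.7 and ln R0 = 0.584·W − 5.66
are the published TRAP parameterization; strand handling and log base are
config-exposed since only medians and ratios matter downstream. Sites
containing N are skipped; an all-N window yields a missing value.

Window conventions: motif enrichment (bound vs non-bound) scores the full
promoter `[−200, +200)`; the classical tertile-mode windows are 100 bp
around the TSS with TATA at `[−40,−20)`, Inr `[−20,+20)`, DPE `[+20,+40)`.
On synthetic data the pipeline uses the promoter-wide window for the
tertile association as well, because the generator embeds DRE/motif 1
anywhere in `[−150, −1)` — wider than the classical 100 bp window.
Enrichment is reported as `log(median score bound / median score
non-bound)`; when a median score is non-positive (scores are logs and can
be negative) the ratio is computed on the affinity scale and flagged.
P-values are star-coded at 1e−4 / 1e−3 / 0.01 / 0.5.

## Chromatin context

Nucleosome occupancy is the any-overlap read count in the 200 bp windows
up- and downstream of the TSS (a read spanning the TSS counts on both
sides; containment-only counting is switchable). Expression quartiles use
type-7 cut points with ties assigned downward. Metagene profiles average
strand-aware per-gene extractions, ignoring missing cells; histone tracks
can be normalized to H4 by log-space subtraction (ratio of ratios); scaled
mode interpolates each gene body onto 100 fractional bins. State
association reduces summits to 2 bp points (`[summit−1, summit+1)`) and
reports per-label fractions with Fisher and binomial tests against a
background set. Heatmap matrices exclude mitochondrial genes and sort by
cumulative signal (stable), genomic location, or ascending ΔPol II.

## Synthetic-data generator

The generator states a world; its defaults are fixed, not tuned:

* **Genome/genes**: 2 chromosomes × 4 Mb, 1,000 genes, lengths log-uniform
  on 1.5–10 kb, ≥ 1 kb gaps. (The 4 Mb default is forced by arithmetic:
  1,000 such genes plus gaps cannot fit in 2 × 2 Mb.) Class fractions
  0.45 / 0.30 / 0.25 (constitutive / regulated / inactive); expression
  log-normal and class-shifted (inactive = 0) so quartile stratification is
  exercised.
* **Promoters**: 600 bp (−400..+200), background GC 0.43. Constitutive
  promoters emit DRE (p=0.6), motif 1 (0.4), E-box (0.4) uniformly in
  −150..−1; regulated promoters emit TATA at −30 (p=0.7), Inr at the TSS
  (0.6), DPE at +28 (0.3). Instances are sampled uniformly over IUPAC
  degeneracies and recorded in the ground truth.
* **NSL binding**: each constitutive gene is bound with p=0.9, then 5%
  per-protein dropout. ChIP reads: Poisson background (0.02 reads/bp, 50 bp
  reads) plus Gaussian summits (sd 80 bp) with per-gene Gamma(shape 4,
  mean 200 reads) intensity shared across proteins.
* **Pol II**: promoter summit Gamma(4, mean 200) on active genes plus
  uniform gene-body coverage; the promoter:body density ratio is
  2^N(1.6, 0.5) per gene — median SI ≈ 1.6, matching the magnitude seen in
  real control samples — and is recorded as the true stalling ratio.
* **Knockdown**: the control read set is thinned read-by-read. Reads are
  assigned to genes by midpoint within the gene ± 400 bp (unambiguous,
  gaps ≥ 1 kb); bound-gene reads are kept with probability
  `f = exp(−softplus(α_DRE·z_DRE − α_M1·z_M1 + ε))` (α = 1.0, 1.0;
  ε ~ N(0, 0.25); z standardized promoter affinities across bound genes),
  non-bound-gene reads with 0.95, background untouched. Softplus keeps
  f ∈ (0,1]; only the *direction* of the DRE/motif-1 effects is given by
  the biology, the effect sizes are chosen so recovery is comfortably
  detectable at ≈ 450 bound genes. Thinning promoter and body alike shares
  the stalling ratio across conditions by construction, which is exactly
  the null the stalling comparison should reproduce.
* **Nucleosomes**: uniform 150 bp-read baseline (0.02 reads/bp); at bound
  promoters the −200..0 window is depleted to 0.2× and phased clusters are
  added at +135/+320/+505 (sd 30 bp, Poisson mean 25 reads decaying by
  0.75 per position so the +1 nucleosome is strongest, as in
  well-organized arrays).
* **Determinism**: every stage draws from its own child stream of the
  seed; regenerating any sample is byte-reproducible.

What the generator does **not** model: mappability, GC or duplication
bias, sequencing error, fragment-size variation, multiple TSSs per gene,
divergent transcription, biological replicates. A green recovery test
therefore establishes the correctness and calibration of the pipeline's
statistics on data with the stated structure — not robustness to the
artefacts of real libraries.

## Full-scale behaviour

The headline numbers of the original study (binding thresholds of
0.64/0.84/1.39 log2FC, thousands of bound promoters, an ~85% constitutive
core set, median stalling indexes ≈ 1.6–1.8) derive from deposited
deep-sequencing data and published annotation; they are not recomputable
at desk scale. The pipeline accepts that scale of input (BED reads, BED12
annotation, expression TSVs, labeled state maps), and agreement there
additionally depends on aligner and annotation versions.

## Numerical choices and degenerate inputs

Grid step 0.01 for thresholds; valley fraction 0.5 for summit splitting;
type-7 quantiles everywhere (R default); all-constant group comparisons
return p = 1; genes with zero body rate after input adjustment are
excluded with reason `zero_rate`; degenerate quartile cuts raise; windows
reaching outside chromosomes fill with NaN and are ignored by averages.
Size-factor estimation refuses matrices with no bin positive in all
samples (advising coarser bins).
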