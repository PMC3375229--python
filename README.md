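# nslseq

Promoter-centric ChIP-seq analysis of the *Drosophila* NSL complex — the
MOF-containing histone acetyltransferase complex (NSL1, NSL3, MCRS2,
MBD-R2, …) that binds the promoters of constitutively expressed
(housekeeping) genes. The package re-implements, as a tested and reusable
pipeline, the analyses with which that regulatory role is established:

* **Enrichment tracks** — reads are counted in 25 bp bins, normalized with
  median-of-ratios size factors, turned into log2 fold-change (ChIP/input)
  tracks and smoothed with a 400 bp sliding window.
* **Empirical-FDR binding calls** — the null is taken from the *negative*
  log2FC values (assumed experimental noise); the binding threshold `c*` is
  the smallest cutoff with `FDR(c) = #{v ≤ −c} / #{v ≥ c} ≤ 0.05`. Peaks
  are maximal super-threshold runs, split into subpeaks at valleys, each
  summit carrying a 40 bp summit region.
* **Target calling** — a TSS is NSL-bound when its 400 bp window
  `[tss−200, tss+200)` intersects a summit region (half-open intervals);
  per-protein sets are combined into Venn partitions and the all-protein
  core set, with Fisher-exact gene-class enrichment.
* **Pol II knockdown response** — ΔPol II = log2FC(knockdown) −
  log2FC(control) per bin; per-gene promoter medians; response tertiles;
  and the stalling index SI = log2(r(TSS)/r(gene body)) with r the
  input-adjusted, length-normalized Pol II density, computed only for
  non-overlapping genes > 1,300 bp with significant promoter signal
  (gene bodies trimmed by 500 bp at both ends).
* **TRAP motif affinities** — biophysical PWM scoring: per-site mismatch
  energy `E_i = (1/λ) Σ_j ln(p_max,j / p_j)`, occupancy
  `R0·e^(−E)/(1+R0·e^(−E))` summed over sites and strands; the score is the
  natural log of that expected bound-molecule count (λ = 0.7,
  ln R0 = 0.584·W − 5.66). Used for bound-vs-non-bound enrichment of core
  promoter motifs (DRE, motif 1, E-box, TATA, Inr, DPE, …) and for the
  association of motif strength with Pol II-loss tertiles.
* **Chromatin context** — nucleosome occupancy 200 bp up/downstream of
  TSSs by expression quartile, metagene profiles (anchored or scaled gene
  bodies, optional H4 normalization), chromatin-state association of summit
  points, heatmap matrices.
* **Synthetic data** — a seeded generator producing a toy genome, promoter
  sequences with class-specific motifs, ChIP/input/nucleosome reads and
  knockdown Pol II with full ground truth, so the entire pipeline runs and
  is testable without any download.

## Worked example

```sh
nslseq run --seed 2 --n-genes 300 --out runs/demo
```

prints

```
core set 99 (precision 1.00, recall 1.00); median delta Pol II bound -0.80 vs non-bound -0.07
wrote run directory runs/demo
```

and writes `bound_table.tsv`, `venn_partition.tsv`, `polii_response.tsv`,
`motif_enrichment.tsv`, `nucleosome_occupancy.tsv`, per-protein peak BEDs
and a `summary.json`. In this run the four simulated NSL ChIP samples gave
empirical-FDR thresholds of 0.69–0.70 log2FC units; 119 promoters were
bound by at least one protein and 99 by all four, exactly recovering the
planted core set. Bound genes lost far more Pol II upon knockdown than
non-bound ones (median promoter ΔPol II −0.80 vs −0.07), while median
stalling indexes were statistically indistinguishable between control and
knockdown (1.70 vs 1.72, rank-sum p = 0.69) — knockdown removes Pol II
without shifting the promoter/body balance. DRE was the most strongly
enriched motif in bound promoters (log median fold change 5.0), with
motif 1 and E-box also positive and TATA/Inr depleted, and the
upstream/downstream nucleosome occupancy ratio at bound promoters was
0.11–0.17 in every expression quartile — a well-defined nucleosome-free
region independent of expression level.

Other entry points: `nslseq simulate` (write a ground-truthed dataset),
`nslseq enrich` (ChIP + input BED → log2FC bedGraph, threshold, peaks),
`nslseq targets`, `nslseq trap`, `nslseq report`. The same functionality
is available as a library, e.g.
`nslseq.pipeline.run_synthetic_analysis(RunConfig(seed=1))`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete synthetic analysis from scratch at the given seed —
genome and read simulation, enrichment tracks and empirical-FDR
thresholds, target calling and recovery, ΔPol II / stalling statistics,
TRAP enrichment and nucleosome profiling — and writes the results file.

## Notes

Defaults throughout (25 bp bins, 400 bp window, FDR 0.05, 40 bp summit
regions, 400 bp TSS windows, the stalling filters, TRAP parameters) are
the canonical settings of this analysis; see `docs/methods.md` for the
model details, the generator's assumptions and known limitations. At full
scale the same code consumes real aligned-read BED files, gene annotation
(BED12/GTF-lite), expression tables and labeled chromatin-state maps.
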