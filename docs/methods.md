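# Methods

## Model and procedure

`tfactivity` infers differential transcription-factor (TF) activity between
two sample groups from the promoter composition of differentially expressed
genes. The underlying causal premise: an activated TF modulates only genes
whose promoters carry its binding motif, so the set of up-regulated genes
becomes enriched for that motif relative to the set of down-regulated genes.
Using the down-regulated set (rather than the genome) as the reference
restricts the comparison to genes demonstrably expressible in the assayed
cell pool, removing the bias that roughly half the genome is silent in any
given cell type.

The pipeline has four stages:

1. **Screen.** Per-gene fold difference from log2 data:
   fold(g) = 2^(x̄_A(g) − x̄_B(g)), i.e. a ratio of geometric means. Genes
   with fold > 1.15 are "up", fold < 1/1.15 "down" (strict inequalities at
   the boundary; a fold of exactly 1.15 is excluded). A paired variant uses
   the mean of within-subject post − pre log2 differences. This is a
   deliberately low-stringency screen producing stable gene *lists*; no
   per-gene inference is attempted or implied.

2. **Scan.** Promoters are TSS-anchored with half-open coordinates: position
   0 is the first transcribed base and the stored span [−1000, +200) holds
   1200 bases. Each TF is a TRANSFAC-style position count matrix; after
   adding a pseudocount of 0.5 per cell, position i has frequencies p_ib and
   information weight I_i = 2 + Σ_b p_ib log2 p_ib ∈ [0, 2]. A subsequence x
   scores mat_sim(x) = Σ I_i p_i(x_i) / Σ I_i max_b p_ib ∈ [0, 1], 1.0 at
   the consensus. The motif slides one base at a time over the forward
   strand and the reverse complement; every offset reaching the threshold is
   a hit, overlapping hits included. Counts are tabulated over the default
   grid of 3 thresholds (0.80, 0.90, 0.95) × 3 windows (−300, −600, −1000 to
   +200).

3. **Enrich.** At grid point k, the prevalence ratio is
   r_k = (prev_up + c/n_up) / (prev_down + c/n_down), where prev is mean
   hits per promoter, n the gene-list size, and c = 0.5 a symmetric
   zero-count guard that vanishes for large lists and yields exactly 1.0
   when both prevalences are 0 and the lists are equal-sized. The fold
   estimate is exp(mean_k ln r_k); its dispersion across the grid gives
   se_log = sd(ln r_k)/√K and, by the delta method, se_fold = fold × se_log.
   A two-tailed one-sample t-test of {ln r_k} against 0 (df = K − 1 = 8)
   tests the null of a 1.0-fold ratio. Bonferroni control across the tested
   matrices uses the per-comparison cutoff α/m (0.05/9 = 0.0056).

4. **qPCR.** Comparative-Ct: technical replicate wells are averaged on the
   Ct scale, ΔCt = Ct_target − Ct_reference per sample (reference default
   GAPDH), ΔΔCt = mean ΔCt_case − mean ΔCt_control, and relative fold
   = E^−ΔΔCt with amplification efficiency E defaulting to 2.0 (100%
   efficiency); E is exposed for assays that deviate from perfect doubling.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| screen threshold | 0.15 | fraction | low-stringency list-building; strict `>` at the boundary |
| mat_sim thresholds | 0.80 / 0.90 / 0.95 | score | spans permissive to near-exact matching |
| windows | −300, −600, −1000 to +200 | bp vs TSS | proximal to extended promoter |
| PWM pseudocount | 0.5 | counts/cell | avoids zero probabilities degenerating scores |
| zero-count guard c | 0.5 | counts | keeps all K ratios finite and df fixed |
| family-wise α | 0.05 | — | Bonferroni over the number of matrices tested |
| qPCR efficiency | 2.0 | fold/cycle | perfect doubling |

Simulator defaults model a small two-arm leukocyte transcriptome study:
200 genes, 20 samples per arm, 1200-base promoters at GC 0.5, group effect
±0.5 log2 units (~1.4-fold, comfortably past the 1.15 screen at n = 20 with
noise 0.3 log2 units), null planting prevalence 0.4 per matrix (within the
promoter occupancy range of broadly acting factors).

## What the generator emulates — and what it does not

Promoters are i.i.d. single-base sequences at a configurable GC content; a
planted instance is sampled base-by-base from the matrix frequencies (the
consensus is the modal planting), written at a uniform position and strand,
overwriting background so coordinates never shift. Expression is
baseline + group effect + covariate terms + Gaussian noise. Randomness is
hierarchical (per-component, per-gene seed substreams), so enlarging the
gene panel leaves existing genes' draws untouched, and a fixed seed
reproduces FASTA and expression bytes exactly.

Not emulated: dinucleotide/repeat structure of real promoters, CpG islands,
motif co-occurrence and clustering near the TSS, probe-level microarray
artifacts, batch effects, and correlated gene expression. Passing tests
therefore demonstrate the *machinery* (scoring, counting, estimator
arithmetic, screen logic) and the estimator's behaviour under a clean
sequence model — not performance on real genomic sequence, where background
hit rates are higher and position-dependent.

## Numerical conventions and degenerate inputs

- Natural log internally for ratio averaging (the base cancels in
  exp(mean ln r)); folds on the output scale.
- Information weights use log2 with the 2-bit ceiling; mat_sim is invariant
  to any positive rescaling of the weights.
- `N` bases contribute probability 0 at their position; windows containing
  `N` are still scanned. A fully uniform matrix (denominator 0) scores 0.
- Sequences shorter than the motif count 0 hits with a warning.
- Zero variance across the grid cannot support a t-test: all-unit ratios
  give the exact null (p = 1); a constant non-unit ratio is flagged
  degenerate with p reported as 0.
- Genes in the differential lists without a scanned promoter are dropped
  from both lists with a logged count, never imputed.
- Residualization regresses each gene on the covariates plus intercept
  (group excluded, preserving the contrast), returns residual + gene grand
  mean, and is idempotent to 1e-10; a rank-deficient design fails naming the
  collinear columns.
- Both s.e. conventions are emitted in verbose reports: fold-scale (delta
  method) and log-scale, since report tables in this literature do not state
  which is used.
- Hit counting defaults to total counts (prevalence as hit density);
  presence/absence counting is available via `binary=True` / `--binary`.

## Known limitations

**The grid t-test is descriptive, not calibrated for dataset-level
inference.** The nine grid combinations are threshold/window subsets of one
realized dataset: they share the gene lists, each promoter's background hit
propensity, and each motif instance's sequence and position. The
combo-to-combo standard deviation therefore measures only methodological
sensitivity to scan parameters and systematically understates the sampling
variability of the realized prevalence ratio. The test answers "do these
two fixed promoter sets differ in motif content, robustly across scan
settings?" — a question about the data in hand — and its p-values must not
be read as frequencies over hypothetically re-sampled studies. Our
replicated null simulations (the calibration check in the acceptance test
suite) make this concrete: with motif planting independent of regulation
direction, the test rejects at α = 0.05 roughly half the time — about an
order of magnitude above nominal — because it faithfully detects the chance
motif imbalances present in each realized dataset; the inflation persists
even when realized planted counts are exactly matched between the sets
(background-sequence heterogeneity alone suffices) and is independent of
the gene-panel size. For study-level error control, a gene-label
permutation or promoter-resampling null would be required; that is future
work, and the Bonferroni flags produced here inherit the descriptive
interpretation.

Other limitations: no permutation/bootstrap alternative null; no
genome-based promoter extraction (users supply FASTA); curated TRANSFAC
matrices are licence-restricted, so the package ships synthetic example
matrices spanning a realistic length/sharpness range (8, 10, 12 bp); the
simulator's uniform-background model understates real-promoter false-hit
rates; multiple probes per gene are treated as separate transcripts, not
collapsed.

## Problem sizes

The test suite's replicated experiments use 500 null replicates and 100
recovery replicates at the default study conditions (200 genes × 40
samples, 3 matrices, nine-combo grid); a single replicate of the full
pipeline takes ~0.3 s, the whole suite a few minutes, on one CPU.
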