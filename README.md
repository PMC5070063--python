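# tfactivity

Promoter-based inference of transcription-factor (TF) activity from
two-group gene-expression profiles.

Many questions in immunology and psychiatry-adjacent genomics ask not *which
genes* differ between two conditions but *which upstream transcription
control pathways* drive the difference — e.g. whether CREB/ATF, NF-κB,
glucocorticoid-receptor or interferon-responsive factors are more active in
patients' leukocytes than in controls. Per-gene tests are underpowered in
small clinical samples, but an activated TF leaves an aggregate footprint:
the genes it up-regulates are enriched for its binding motif in their
promoters. `tfactivity` implements that inference as a reusable pipeline
for analysts working with normalized expression matrices, promoter
sequences, and TRANSFAC-style position matrices.

## The method

1. **Differential expression screen.** Genes with a >15% difference in
   average expression between groups are split into up- and down-regulated
   sets: fold(g) = 2^(x̄_A(g) − x̄_B(g)) on log2-scale data, with up if
   fold > 1.15 and down if fold < 1/1.15 (strict inequalities). Nuisance
   covariates (age, sex, BMI, leukocyte subset fractions) can first be
   removed by per-gene OLS residualization. The down-regulated set serves as
   the reference so that every analyzed gene is expressible in the assayed
   cell pool.

2. **Promoter motif scanning.** Each promoter (TSS-relative window, stored
   span −1000..+200) is scanned on both strands with the
   information-weighted matrix-similarity score

   `mat_sim(x) = Σᵢ Iᵢ·pᵢ(xᵢ) / Σᵢ Iᵢ·maxᵦ pᵢᵦ`,  `Iᵢ = 2 + Σᵦ pᵢᵦ log₂ pᵢᵦ`,

   which equals 1.0 at the consensus. Hits are counted over a 3 × 3 grid of
   stringency (mat_sim ≥ 0.80, 0.90, 0.95) × promoter window (−300, −600,
   −1000 to +200 bp).

3. **Enrichment statistic.** For each TF matrix and each of the nine grid
   combinations, the prevalence ratio
   r_k = (mean hits per up-promoter) / (mean hits per down-promoter)
   is computed with a symmetric zero-count guard; log ratios are averaged
   across the grid (mean fold = exp(mean ln r_k)), and a two-tailed
   one-sample t-test (df = 8) tests the null of a 1.0-fold ratio, with
   Bonferroni control across the tested matrices (nine pathways ⇒
   individual P < 0.0056).

4. **qPCR confirmation.** Comparative-Ct quantification:
   ΔCt = Ct_target − Ct_reference per sample, ΔΔCt = mean ΔCt_case − mean
   ΔCt_control, relative fold = 2^−ΔΔCt.

A synthetic-data generator (`tfactivity.simulate`) produces random promoters
with planted motif instances at controlled prevalence, expression matrices
whose group effects are coupled to motif presence, covariates, and Ct
tables — so every stage is testable against known ground truth without any
external data.

## Worked example

Simulate a dataset in which one TF's motif is planted in 60% of up-destined
and 30% of down-destined promoters (true prevalence ratio 2.0), then run the
full screen → scan → enrich chain:

```python
from tfactivity import SimulationConfig, simulate_dataset, analyze, results_table

cfg = SimulationConfig(seed=1, planted_tf_effects={"SYN_ISRE_LIKE": (0.6, 0.3)})
promoters, expression, pwms, truth = simulate_dataset(cfg)
de, counts, results = analyze(expression, promoters, pwms,
                              case="case", reference="control")
print(de.summary())
print(results_table(results)[["matrix", "mean_fold", "se_fold", "p_value",
                              "bonferroni_significant"]].round(4).to_string(index=False))
```

prints

```
200 transcripts screened at >15%: 100 up, 100 down
       matrix  mean_fold  se_fold  p_value  bonferroni_significant
SYN_CREB_LIKE     2.0173   0.8532   0.1356                   False
SYN_NFKB_LIKE     0.9457   0.0751   0.5017                   False
SYN_ISRE_LIKE     2.1454   0.0615   0.0000                    True
```

The planted factor (`SYN_ISRE_LIKE`) is recovered with an estimated fold of
2.15 — close to the true 2.0 — and is the only matrix surviving Bonferroni
correction; the two unplanted matrices show only background-level ratios
whose dispersion across the grid (`se_fold`) is correspondingly wide.

The same flow is available from the shell:

```bash
tfactivity run --demo --seed 1 --out demo_run     # synthetic end-to-end run
tfactivity screen expr.tsv --groups groups.tsv --adjust --out de.tsv
tfactivity scan promoters.fasta matrices.transfac --out counts.tsv
tfactivity enrich counts.tsv de.tsv --out enrichment.tsv
tfactivity qpcr ct.tsv --target IFI44 --case case --control control
```

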