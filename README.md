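# stagetf

Inference of stage-dependent transcription-factor (TF) activity changes from
matched tumor multi-omics profiles. Given per-sample log2 mRNA expression,
copy-number and DNA-methylation matrices plus early/late stage labels, the
package explains each gene's expression as

```
y_ij = beta_cn_i * C_ij + beta_me_i * M_ij + sum_f beta_f * S_j * B_fi + eps_ij
```

where `S_j` indicates late-stage samples and `B_fi` is a binary TF-target
incidence (GMT gene sets, duplicate target sets merged). The per-TF
coefficients `beta_f` quantify target-set expression shifts between stages
after accounting for gene-specific copy-number and methylation dosage — a
post-transcriptional activity signal not visible in the TF's own mRNA.

The stacked regression has one row per (gene, sample) pair and an arrowhead
normal-equation structure: independent 2×2 per-gene blocks coupled only
through the shared TF columns. The OLS solver eliminates the gene blocks
analytically and solves a single `n_tfs × n_tfs` Schur-complement system, so
a genome-scale design (5,684 genes × 178 samples → 1,011,752 rows, 11,574
coefficients) fits in milliseconds without ever materialising the design
matrix. Ridge uses the same structure; lasso runs on the sparse design via
scikit-learn.

## Modules

| module            | responsibility |
|-------------------|----------------|
| `io_datasets`     | TSV matrix / clinical / GMT parsing, alignment, duplicate-TF merging, >min-TF gene filter |
| `synthetic`       | generative simulator with ground-truth record, expression permutation baseline |
| `diffexpr`        | pooled-t stage differential expression, BH FDR, FC/FDR filter |
| `correlation`     | per-gene Pearson profiles, positive/negative summaries, KS gene-set comparisons |
| `model`           | design construction, structured OLS / ridge / lasso, TF activity table, residual diagnostics |
| `evaluation`      | 10-fold CV on held-out patients *and* genes, TF-only and randomized baselines, stage-change correlation, target-shift KS test |
| `attribution`     | per-gene CNV / methylation / TF mechanism flags and Venn summary |
| `cli`             | `stagetf` command-line entry point and pipeline orchestration |

## CLI

```bash
stagetf simulate --seed 1 --outdir data/            # synthetic dataset + truth
stagetf de --dataset data/ --fc 2 --fdr 0.001 --out de.tsv
stagetf correlate --dataset data/ --layer cnv --alpha 0.01 --out corr.tsv
stagetf fit --dataset data/ --method ols --out fit/ # coefficients + TF activity
stagetf crossval --dataset data/ --k 10 --seed 42 --out cv.json
stagetf dissect --dataset data/ --out attribution.tsv
stagetf run-all --seed 1 --outdir run/              # full pipeline end to end
```

Datasets are directories holding `expression.tsv`, `cnv.tsv`,
`methylation.tsv` (genes × samples, first column `gene_id`), `clinical.tsv`
(`sample_id`, `stage` ∈ {I, IV}) and `tf_targets.gmt`. Configuration files
are plain `key = value` text; defaults follow the analysis protocol
(FC > 2, DE FDR < 0.001, correlation α 0.01, TF FDR < 0.001, TF effect
size > 0.5, genes with > 5 binding TFs, 10 folds).

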