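# factorialseq

`factorialseq` is a reusable pipeline for the integrative analysis of a 2×2
factorial genomics experiment in the intestinal epithelium: germ-free (GF)
vs microbiota-colonized (CV) animals, each sampled unfed or two hours after
a single high-fat meal (HFM). It jointly analyses gene-level RNA-seq counts
and window-level chromatin counts (an H3K27ac-style activation mark, or
transcription-factor binding such as HNF4A) to separate purely microbial
responses, purely nutritional responses, and genes or regulatory regions
where the two signals interact.

It is written for computational biologists who have count matrices and peak
calls in hand (or who want a fully synthetic benchmark with known ground
truth) and want the factorial analysis — not read alignment or peak calling,
which stay upstream.

## The model

For feature *i* (gene, or 300-bp chromatin window) in sample *j*, counts are
negative binomial with variance μ + αμ² and mean

```
μ_ij = s_j · q_i · 2^( βm·x_j + βf·y_j + βi·x_j·y_j )
```

where `s_j` is a median-of-ratios size factor, `q_i` a base abundance,
`x_j, y_j ∈ {0,1}` indicate microbes and meal, and the coefficients are
log2 fold changes. `βi` is the interaction log2 fold change — the log2 ratio
of (CV+HFM/CV)/(GF+HFM/GF): positive when the meal response is stronger in
colonized animals. Per feature the pipeline reports:

- the four pairwise Wald contrasts CV/GF, CV+HFM/GF+HFM, GF+HFM/GF,
  CV+HFM/CV (BH-adjusted per contrast, significant at padj < 0.05), and
- the interaction likelihood-ratio test (full vs additive model, χ², 1 df),
  with lenient interaction calls at p < 0.05 & baseMean > 10 for genes and
  p < 0.01 & baseMean > 15 for chromatin windows.

Downstream, significant features split by direction into 8 directional
significance groups (4 contrasts × up/down). Chromatin windows (300 bp,
200 bp step, tiled over merged peaks) are joined back to their parent peaks
(a peak is significant when any window is; min-p window represents it).
Peaks responsive to both microbes and meal are classified **red**
(CV+HFM/CV-up ∧ CV+HFM/GF+HFM-up: meal-induced only with microbes) or
**blue** (GF+HFM/GF-up ∧ CV+HFM/GF+HFM-down: meal-induced only germ-free).
The package also classifies regions by cell-type accessibility (stem-cell
vs enterocyte repertoires), links peaks to nearest genes and counts binding
sites per gene, runs PWM motif enrichment of each directional group against
its reciprocal-direction background (ZOOPS counting, hypergeometric tail),
and computes PCA and one-factor PERMANOVA of the sample distance matrix.

A first-class synthetic-data module generates the whole input universe —
genomes, genes, peaks, factorial NB counts with unbalanced replication
(RNA 4/4/4/4; chromatin 2/5/2/5), binding-site clusters, accessibility
labels, motif-planted sequences — with the planted truth recorded for
recovery testing.

## Worked example

```
factorialseq run-all config.yaml
```

with `config.yaml`:

```yaml
out_dir: run
seed: 7
simulate:
  n_genes: 200
  n_peaks: 150
stats:
  n_perm: 999
```

prints (with `-v`) stage-level progress and writes ~40 result tables plus a
JSON manifest under `run/`. On this config the run reports, among others:

```
genes CV/GF: 35 standard-significant
peaks CV+HFM/GF+HFM: 57 significant
integration classes: {'none': 104, 'red': 18, 'other-dual': 15, 'blue': 13}
```

`run/results/peak_integration.tsv` assigns each peak its class; comparing
against `run/fixtures/truth_peaks.tsv` (the planted truth) shows every
strongly-expressed planted red/blue peak recovered correctly.
`run/results/permanova_rna.tsv` gives the factor separation of the samples,
e.g. microbes R² = 0.38, p = 0.001 — the permutation floor at 999
permutations.

The same stages are callable as a library (`factorialseq.run_differential`,
`factorialseq.simulate_annotation`, ...) or as individual subcommands
(`simulate`, `de`, `join`, `annotate`, `validate`).

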