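# tissuetau

Robust identification of tissue-specific genes from multi-tissue bulk
RNA-seq expression matrices (FPKM/TPM), for anyone who needs per-tissue
marker gene lists from atlas-style data: transcriptomicists comparing
tissue panels, and method developers benchmarking specificity scores.

## The method

Genes are first partitioned on raw expression: **null** (≤ 1.0 in every
tissue), **weak** (< 10 everywhere), and, via the tau specificity index
computed on log2(x+1)-transformed values,

$$\tau = \frac{\sum_{i=1}^{n}(1-\hat{x}_i)}{n-1}, \qquad
\hat{x}_i = \frac{x_i}{\max_{1\le j\le n} x_j},$$

**specific** (τ ≥ 0.85) versus **wide-spread** (τ < 0.85). Tau ranges
from 0 (uniform, housekeeping-like) to 1 (single-tissue), but by itself
can only point at one tissue — the argmax. The *extended tau* step
assigns each specific gene to every tissue within a statistically
significant interval below its maximum: two-cluster fuzzy c-means splits
each tissue's nonzero values into a low bulk and a high tail, the mean
upper-cluster fraction becomes a normal quantile
$z = \Phi^{-1}(1-\mathrm{ratio})$, and a gene with maximum expression
$x_{\max}$ and nonzero-expression standard deviation $\sigma$ is assigned
to all tissues with expression at least

$$\mathrm{dist}_{ss} = x_{\max} - \sigma \cdot z.$$

At z = 0 this reduces exactly to the classic single-tissue tau call;
the extended pair set is always a superset of it. The package also ships
per-dataset QC and cross-dataset comparison statistics (F-test,
Kolmogorov–Smirnov normality, correlation over shared genes, Venn
overlap, consensus support), a BTO-style child→parent tissue roll-up,
and a synthetic-data generator with planted gene classes.

## Worked example

```python
from tissuetau import ExtendedTau, SyntheticConfig, generate_dataset, score_recovery

matrix, truth = generate_dataset(SyntheticConfig(seed=1))   # 20,000 genes x 30 tissues
est = ExtendedTau().fit(matrix)
print(est.summary_)
score = score_recovery(est.assignments_, truth)
print(f"recall={score.recall:.3f} precision={score.precision:.3f}")
```

prints

```
{'n_genes': 20000, 'n_tissues': 30, 'n_null': 2000, 'n_weak': 3000,
 'n_wide_spread': 12000, 'n_specific': 3000, 'n_specific_genes': 3000,
 'n_pairs': 4382, 'ratio_opt': 0.007326666666666666, 'z_val': 2.440835364444195}
recall=0.996 precision=1.000
```

All 3,000 planted specific genes are found (τ ≥ 0.85) and the interval
step expands them to 4,382 gene–tissue pairs: on average 0.7 % of a
tissue's expressed genes sit in the upper fuzzy cluster, giving
z ≈ 2.44, so a gene is kept in any tissue within 2.44 standard
deviations of its maximum. A planted two-tissue gene looks like:

```
  gene_id    tissue  expression      tau    dist_ss      x_max      sigma  is_argmax
SYNG19000 tissue_17  492.673257 0.903387 228.893976 492.673257 108.069264       True
SYNG19000 tissue_19  346.778731 0.903387 228.893976 492.673257 108.069264      False
```

Classic tau would report only `tissue_17`; the second home tissue at
347 ≥ dist_ss ≈ 229 is recovered by the extension. 99.6 % of all planted
(gene, tissue) pairs are recovered and every reported pair is a planted
one.

The same pipeline runs from the shell:

```sh
tissuetau simulate --out matrix.tsv --truth truth.tsv --seed 1
tissuetau extended-tau matrix.tsv --out pairs.tsv --summary summary.tsv
tissuetau rollup pairs.tsv --map bto_map.tsv --out parent_pairs.tsv
```

`tissuetau categorize`, `compare` and `qc` cover categorization
summaries, multi-dataset Venn/consensus tables and per-tissue QC. Real
Expression Atlas baseline TSV exports (`Gene ID`, optional `Gene Name`,
one column per tissue) are read directly; supply a fixed
`--z-val` to replay a previously optimised dataset threshold.

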