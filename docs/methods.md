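# Methods

## Problem and model

Bulk RNA-seq atlases quantify each gene across tens of tissues in FPKM or
TPM. The tau specificity index summarises a gene's expression pattern in a
single score: with expression values `x_i` over `n >= 2` tissues,
log-transformed as `x_i <- log2(x_i + 1)` and max-normalised as
`x̂_i = x_i / max_j x_j`,

    tau = sum_i (1 - x̂_i) / (n - 1).

Tau is 0 for perfectly uniform (housekeeping-like) expression and 1 when a
single tissue carries all transformed expression. Genes are first
partitioned on raw values: **null** if every tissue is <= 1.0 FPKM/TPM,
else **weak** if every tissue is < 10 (tau is computed but ignored), else
**specific** if tau >= 0.85, else **wide-spread**. All cutoffs act on raw
values; the log transform exists only inside tau. The unit tag (FPKM vs
TPM) is carried as metadata — every cutoff treats the two identically.

Tau alone points at a single tissue (the argmax), yet genes can be
genuinely specific to two or three tissues — a digestive enzyme expressed
in both small intestine and duodenum, say. The extension assigns each
specific gene to every tissue whose raw expression lies within a
statistically significant interval below its maximum:

1. **Per-tissue clustering.** Within each tissue, the nonzero expression
   values of all genes are split into two fuzzy c-means clusters; the
   upper-cluster fraction `ratio = n_up / n_total` measures how much of
   the tissue's expressed transcriptome sits in the high cluster.
2. **Dataset threshold.** The per-tissue ratios collapse to one dataset
   ratio (arithmetic mean by default) which is converted to a standard
   normal quantile `z = Phi^-1(1 - ratio)`. A heavy-tailed dataset whose
   top expressers are few and far from the bulk yields a small ratio and
   a large z.
3. **Assignment.** For each specific gene, `sigma` is the sample (n-1)
   standard deviation of its strictly positive values,
   `dist_ss = x_max - sigma * z`, and the gene is assigned to every
   tissue with raw expression >= dist_ss. The argmax tissue is always
   included (relevant when z < 0 pushes dist_ss above the maximum), and
   ties at the maximum assign all tied tissues.

At `z = 0` the interval collapses to the maximum and the procedure
reduces exactly to the classic single-tissue tau assignment; raising z
can only add tissues, so the extended pair set is always a superset of
the original one — pair counts are non-decreasing in z.

Datasets are processed separately; no cross-dataset normalisation is
attempted. Cross-dataset agreement is assessed afterwards with the
`stats` module: variance-equality F-tests (larger variance in the
numerator, two-sided p), one-sample Kolmogorov–Smirnov normality checks,
Pearson correlation of per-gene mean expression over shared genes (the
tissue panels differ, so genes are the common axis), Venn-region overlap
counts of per-dataset specific-gene sets, and consensus calls supported
by at least `min_support` datasets.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `null_cutoff` | 1.0 FPKM/TPM | inclusive ceiling for null expression |
| `weak_cutoff` | 10 | strict ceiling for weak expression |
| `tau_cutoff` | 0.85 | specificity threshold on tau |
| `pseudocount` | 1.0 | added before log2; keeps zeros at zero |
| `threshold_method` | `mean` | collapse of per-tissue ratios (`median`, `linear-trend` available) |
| `z_val` | None | fixed z overriding optimisation (replays a published threshold) |
| `clustering_axis` | `tissue` | cluster within tissues (across genes); `gene` clusters across tissues |
| `fcm_m`, `fcm_tol`, `fcm_max_iter` | 2, 1e-6, 1000 | fuzzy c-means configuration |

The `linear-trend` method (least-squares fit of sorted ratios against
rank, evaluated at the mid-rank) is algebraically identical to the mean —
an LS line passes through the mean point — and is kept only as an
explicit, named strategy. The optimised ratio is clamped to
(1e-6, 1 - 1e-6) before the quantile conversion so a degenerate all-high
or all-low clustering cannot produce an infinite z.

## Numerical choices

* **Pseudocount.** Specific genes are near zero in most tissues and
  log2(0) is undefined; log2(x + 1) maps 0 to 0, is monotone, and leaves
  tau's [0, 1] range intact.
* **Fuzzy c-means.** Two clusters, fuzzifier m = 2, tolerance 1e-6 on the
  centers, at most 1000 iterations. Memberships are computed as
  `u_0 = 1 / (1 + (d_0/d_1)^2)`, which is overflow-safe at any distance
  scale; points coinciding with a center get full membership there. Two
  deterministic starts are run — centers at the 25th/75th percentiles and
  at the data extremes — and the solution with the lower fuzzy objective
  is kept. The second start matters: on heavy-tailed expression data the
  quartile start can converge to a local optimum that separates the weak
  bulk from the mid-range instead of isolating the highly expressed tail,
  which inverts the meaning of the upper-cluster ratio. Both starts are
  seed-free, so identical inputs give bit-identical results.
* **Degenerate inputs.** Tissues with fewer than two nonzero values, or
  all values identical, are flagged degenerate and excluded from
  threshold optimisation. A matrix with no specific genes yields an empty
  assignment with a warning. sigma is defined as 0 for genes with a
  single nonzero value, collapsing their interval to the maximum.
* **Boundaries.** Null is inclusive (<= 1.0), weak strict (< 10, so a
  value of exactly 10 is non-weak), tau inclusive (>= 0.85), and the
  assignment boundary inclusive (expression >= dist_ss). Sub-1.0 values
  enter tau unclamped.

## Synthetic data: what it emulates and what it does not

`generate_dataset` plants five gene classes — null (mean 0.3), weak (3),
housekeeping (50), and k-tissue-specific genes (500 in k uniformly chosen
home tissues, 0.5 elsewhere) — and multiplies every value by mean-one
log-normal noise with coefficient of variation 0.2. FPKM/TPM values are
positive and right-skewed, which multiplicative log-normal noise
reproduces while keeping class separation interpretable in CV units. The
default study is 20,000 genes x 30 tissues with 2,000 null, 3,000 weak,
12,000 housekeeping and 3,000 specific genes (2,000/600/400 for
k = 1/2/3), proportioned after the category structure typical of
multi-tissue atlases. All randomness flows through one seeded generator,
so a config reproduces its matrix exactly.

The generator makes no attempt to imitate gene-length or GC bias, batch
effects, correlated tissues (e.g. brain subregions), partial expression
gradients, or the empirical value distributions of any real atlas.
Passing recovery tests therefore demonstrates that the pipeline is
correct and self-consistent under its own model — clean planted patterns
with multiplicative noise — not that it attains any particular accuracy
on real tissue panels, where off-tissue leakage and tissue correlation
blur the class boundaries.

For the recovery checks run at test time, smaller replicates (hundreds of
genes, 12 tissues) use the same levels and noise; the full default
geometry is exercised once per run because the planted-pattern
recall/precision floor (0.95 for k <= 3) is a property of the full study
size.

## Known limitations

* The per-tissue upper-cluster ratio depends on the composition of the
  whole matrix: filtering the gene set changes the threshold, hence the
  assignments.
* The assignment is an interval rule, not a hypothesis test; no p-value
  is attached to a gene-tissue pair and none should be read into it.
* The classical K-S p-value is reported without the Lilliefors
  correction for estimated parameters, matching common practice; it is
  conservative.
* Only one-level child→parent tissue roll-up is supported — no ontology
  reasoning beyond the supplied table.
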