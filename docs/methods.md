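# Methods

`editbench` asks a design question about gene-edited iPSC RNA-seq studies:
when the same edit is introduced into several stock lines, how reliably do
standard differential-expression (DE) workflows detect and reproduce its
transcriptomic signature?  The package implements the statistical machinery
needed to answer that question on data with known ground truth: a count
generator, normalization, three DE engines, cross-line concordance metrics,
a spike-in/permutation benchmark, and per-gene variance partitioning.

## Count model and synthetic data

Counts are negative binomial (NB) with mean

```
mu[g, s] = L_s * b_g * 2^(line[g, line(s)] + batch[g] * 1[batch(s) = A]
                           + e_g * 1[status(s) = edited] + h[g, s])
```

and variance `mu + phi_g * mu^2`.  Components:

- `L_s` — library size, log-normal (default log-mean `log 6e7`, log-sd
  0.08, matching a 50–75 M read target).
- `b_g` — relative abundance: log-normal draws (sd 1.8 on the natural-log
  scale) normalized to sum to one, giving the heavy-tailed abundance
  distribution typical of transcriptomes.
- `phi_g` — gamma-distributed dispersion, shape 2.0 and scale 0.03 (median
  ≈ 0.05, typical for technical iPSC replicates).  An optional
  mean–dispersion trend inflates dispersions of low-abundance genes.
- `line[g, l]` — per-line per-gene log2 offsets, N(0, `sigma_line`),
  default 0.5: baseline differences between stock lines dominate editing
  effects, as multi-line experiments show.
- `batch[g]` — a sparse batch artifact: 10% of genes shifted by
  N(0, `sigma_batch` = 0.5) in batch-A samples only, emulating one culture
  round drifting from the other two.
- `e_g` — editing effects: an HPRT1-like gene at log2FC −3 (a premature
  stop codon subject to nonsense-mediated decay knocks the transcript down
  roughly eight-fold; the true magnitude is not precisely known, so it is
  configurable) plus 100 secondary effects with magnitudes uniform in
  [0.5, 2] and random sign.
- `h[g, s]` — optional heterogeneous-line mode: a random gene set shifted
  in a subset of one line's edited sublines, emulating subclone-selection
  artifacts in a heterogeneous parent culture.

The default design is 4 lines × (3 stock + 3 edited) = 24 samples, with
stock replicates cycling through batches A/B/C.  Every injected editing
effect is recorded in a truth table; line, batch and heterogeneity offsets
are deliberately *not* in the truth table — they are the nuisance structure
the analyses must overcome.

What the generator does **not** emulate: outlier samples, GC/length biases,
isoform switching, correlated gene modules (co-expression), or count
zero-inflation beyond NB sampling.  Passing tests therefore demonstrate
correctness of the machinery and qualitative behavior of the engines under
an idealized NB world, not performance guarantees on real libraries.

## Normalization

TMM factors follow the canonical construction: reference sample = the one
whose upper-quartile of library-scaled counts is closest to the mean
upper-quartile; per sample, gene-wise M-values (log2 ratios after library
scaling) are trimmed 30% per tail, A-values 5% per tail, and the surviving
M-values averaged with inverse asymptotic-variance (binomial) weights;
factors are rescaled to geometric mean 1.  The implementation agrees with
edgeR's `calcNormFactors` to ~1e-7 on a frozen fixture.  Log-CPM adds a
prior count (default 0.5) scaled per sample by effective library size.  The
expression filter (CPM ≥ 0.5 in ≥ smallest-group-size samples by default)
is permissive and logged, since the upstream studies do not state theirs.
PCA is the standard SVD of the samples × genes matrix with per-gene
centering and scaling; zero-variance genes are dropped with a warning when
scaling.

## DE engines

All engines share treatment-coded design matrices with a designated
coefficient of interest, report log2 fold change / p / Benjamini-Hochberg q
/ mean log-CPM, and treat `q < 0.05` as the significance rule.

**Dispersion estimation.**  The Cox–Reid adjusted profile likelihood of
each gene is evaluated on a 36-point log-spaced grid (1e-6 … 10) with
IRLS fits vectorized across genes; the common dispersion maximizes the
mean curve, and tagwise dispersions maximize `APL_g + prior_n * meanAPL`
with `prior_n = 10` pseudo-genes by default (no trend by default; a lowess
trend on abundance is optional).  Maxima are refined by quadratic
interpolation in log-dispersion.  Genes with constant counts land on the
grid's lower bound; all-zero genes inherit the common value.

**NB exact test.**  Counts are quantile-adjusted (mid-quantile NB→NB
mapping) to a common library size — the geometric mean of the two groups'
geometric-mean effective library sizes.  Conditional on each gene's total,
group sums are NB with size `n_k / phi`, and the two-sided p sums the
probabilities of all splits no more likely than the observed one
(minimum-likelihood rule; tail-doubling is available as `method=
"doubletail"`).  Enumeration is exact and vectorized over genes in blocks.

**NB GLM-LRT.**  Log-link NB GLMs with offsets `log(L_s * f_s)` are fitted
by batched IRLS with step-halving; the likelihood-ratio statistic between
the full and reduced design is referred to chi-square with 1 df.  Genes
that fail to converge are reported with `p = NaN` and excluded from the BH
denominator (a logged count), so non-convergence can never fabricate
significance.

**Precision-weighted moderated t.**  Per-gene linear models on log-CPM give
residual standard deviations whose square roots are smoothed against
average log-count by lowess (span 0.5); each observation's predicted
variance at its own fitted log-count becomes an inverse-variance weight.
The consensus within-block correlation is estimated per gene as a
hat-matrix-bias-corrected moment estimate of the within-block residual
correlation, variance-stabilized with atanh, pooled by a 15% trimmed mean,
and transformed back; the bias correction removes the O(p/n) negative
correlation that least-squares residuals of independent data carry.  The
blocked fit is generalized least squares under a compound-symmetric
within-block correlation.  Residual variances are shrunk toward a pooled
prior whose degrees of freedom are estimated by moment-matching the
log-variance distribution (trigamma inversion); when the variances show no
excess scatter beyond chi-square sampling noise the prior df is infinite
and the prior variance is the geometric mean of the sample variances — the
degenerate limit in which moderation leaves equal variances untouched.

**Multiple testing.**  BH step-up, stable under ties, NaN-aware (NaN p
excluded from `m`), cross-checked against statsmodels.

## Benchmark and evaluation

Null splits enumerate all unordered two-group partitions of a line's
samples (10 for six samples split 3+3; an ordered mode exists for
asymmetric scoring).  For each split and fold-change level, randomly chosen
genes (excluding all-zero genes, whose perturbation would be undetectable
by construction) are multiplied and rounded in one group, the engine is
rerun, and TP/FN/FP/TN are tallied; AUC is the rank-based probability that
a spiked gene outranks an unspiked one by `-log10 p` (ties count ½), equal
to the trapezoidal area under the empirical ROC at all distinct score
thresholds.  A combined mode spikes all levels at once (the
400-perturbation reading of 50 genes × 8 levels); the per-level mode keeps
false-positive counts comparable across levels.  The spiked gene *fraction*
matters: spiking more than ~1% of genes perturbs library composition enough
to make false positives rise with the level, so reduced-scale runs keep the
fraction near the canonical 50/26485 ≈ 0.2%.

Reference-based evaluation scores a single line's significant list against
the aggregate reference — the significant set of the joint, line-adjusted
analysis (GLM with line covariates or blocked moderated t; the exact test
cannot adjust for line and is rejected).  TP% is `100·tp/|reference|` and
FP% is `100·fp/total calls`, both rounded half-up to one decimal;
`tp + fp = total` holds exactly.

## Variance partitioning

For each gene, the random-effects model implies
`E[(y_i − y_j)^2]/2 = sigma_e^2 + sum_f sigma_f^2 · 1[f_i ≠ f_j]` for every
sample pair.  Regressing squared half-differences of all pairs on the
level-disagreement indicators by non-negative least squares gives
method-of-moments variance components for unbalanced crossed designs
without per-gene iteration; NNLS doubles as the truncation of negative
components at zero, and fractions (component / total) are non-negative and
sum to one by construction.  Aliased factors (identical disagreement
patterns) raise an error naming the pair.  A per-gene REML mixed model via
statsmodels is available as `method="reml"` for cross-checking; the default
is deliberately the simpler moment method, and no numerical agreement with
any specific mixed-model implementation is claimed.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced scale, chosen as the
smallest sizes at which the statistical properties are stable: 600–13000
genes, library sizes 1e5–3e5, 3v3 or 6v6 samples, 10 null splits, 25–50
spiked genes per level.  Null calibration uses 2000 genes at dispersion
0.05; fold-change recovery uses 250 affected genes at ±1 log2FC (6v6,
phi = 0.1); the engine-conservativeness comparison uses the generator's
default heterogeneous dispersions, since gene-to-gene dispersion spread is
precisely what separates the moderated t's heavier tails from the
shrunk-dispersion NB tests.  IRLS uses a 1e-10 ridge, eta clipped to
[−30, 35], and convergence at relative log-likelihood change 1e-8 with at
most 60 iterations; the exact test treats dispersions below 1e-8 as
Poisson and uses an exact binomial conditional law there.

## Known limitations

- The exact test enumerates every split of a gene's total; runtime grows
  linearly in the total count, so very deep libraries are slow (the GLM or
  moderated t are the right engines there).
- The duplicate-correlation analogue is a moment estimator, not the REML
  estimator of the reference implementations; agreement is qualitative
  (sign, ordering, approximate magnitude).
- Variance fractions are moment estimates; for strongly unbalanced designs
  the REML option is more efficient but much slower.
- No quasi-likelihood F-tests, robust dispersion outlier handling, or
  batch-correction transforms (batch is a modeled factor, not removed).
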