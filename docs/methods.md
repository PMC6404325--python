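# Methods

This note documents the models, parameter choices and numerical decisions
behind `xenodissect`, and what the synthetic cohorts do and do not emulate.

## Species partitioning

Unique alignment to a prefix-concatenated multi-species genome is emulated
with a canonical k-mer index over the two transcriptomes.  A k-mer is
*informative* when it occurs in exactly one organism; k-mers present in both
are marked shared and carry no evidence.  A read is assigned to an organism
when that organism alone has informative hits and it has at least
`min_informative` of them; informative evidence for two or more organisms
makes the read `ambiguous` (the analogue of discarding multi-mapping reads);
no informative hits leaves it `unmapped`.

- **k = 31** (flag): standard for species-level discrimination.  At 10%
  human–mouse coding divergence the chance that a 31-mer of an ortholog
  contains no diverged site is ≈ 0.9³¹ ≈ 0.04, so nearly every k-mer of
  every transcript is informative.
- **min_informative = 2** (flag): one matching k-mer can arise from a
  sequencing error creating a chance match; two suppress that failure mode
  at negligible sensitivity cost for ≥ 50-bp reads.
- **Canonical (strand-collapsed) k-mers**: the simulator does not model
  library strandedness, so matching is strand-agnostic.  Strand-aware
  counting is out of scope.
- Paired mates are classified independently; the fragment label is their
  agreement, with any disagreement between two organism labels set to
  ambiguous.  Re-sequenced runs of one sample are combined by the additive
  `PartitionResult.merge`.
- Gene attribution within the assigned organism follows the plurality of
  informative k-mer hits; ties leave the read counted at organism level
  only.  This is a stated stand-in — how a probabilistic quantifier
  resolves within-organism multi-mapping is a different (EM-based) problem.

Composition is reported over organism-assigned reads only; ambiguous and
unmapped reads, and any organism explicitly excluded (e.g. a viral
reference), never enter the denominator.

## Per-species quantification

TPM is computed within each species separately.  Writing `f_s` for the
human fraction of sample `s`, every human gene's expected count scales by
`f_s`, so the factor cancels in the within-species TPM ratio: expected
human TPM is invariant to the mouse content of the sample.  This is the
property that makes samples at 5% and 90% human comparable, and it is
asserted by simulation (paired cohorts differing only in composition; no
gene's mean TPM may shift beyond its Monte-Carlo noise envelope).

Numerical choices:

- **log2(TPM + 1)**: the pseudocount keeps zeros at zero, consistent with
  filtering genes whose log2 TPM is zero across all samples.
- **Upper-quantile normalization** operates on the log scale as an additive
  per-column shift; the 75th percentile is computed over genes *nonzero in
  that column*, and only nonzero entries are shifted, so absent genes stay
  absent.  The operation is idempotent.
- **DE prefilter**: a gene is kept when expression exceeds 0.5 in at least
  ⌈10% of samples⌉ and max/(min+1) exceeds 0.5.  The ratio clause as
  written is satisfied by almost any expressed gene; it is implemented
  literally with the threshold exposed as a flag rather than reinterpreted
  (a log-ratio or a >1.5 cutoff would be plausible intents).  The ε = 1 on
  the minimum guards division by zero.
- **Variable genes**: largest sample variance, ties broken by gene id so
  selections are platform-independent.
- **Ward clustering on 1 − Pearson r**: the Lance–Williams recurrence
  applied to correlation dissimilarities (the `ward.D2` convention);
  verified against a brute-force O(n³) agglomeration.
- **PCA**: genes centered and scaled to unit variance before decomposition
  (zero-variance genes dropped); component signs fixed by making the
  largest-magnitude loading positive.
- **Label-swap QC**: each sample's nearest expression neighbor is found by
  Pearson correlation; a sample whose neighbor belongs to another line is
  flagged.  A *suspected swap* is a pair of flagged samples whose labels
  cross (each one's neighbor line equals the other's label) — a swapped
  sample clusters with its true line, not with the other swapped sample.

## Composition-adjusted differential expression

Per gene, counts follow a negative-binomial GLM with log link and an offset
of the log size factor:

    log μ = log(sf) + β₀ + β₁·percent + Σ_c β_c·[condition = c]

with `percent` the sample's share of reads from the focal organism (0–100,
centered before fitting; coefficients reported unscaled on the log2 scale).
The covariate absorbs composition-dependent expression that within-species
normalization cannot remove — cross-species signal bleed and
purity-correlated programs — which otherwise confounds any contrast whose
groups differ in purity (metastases are systematically less human than
mammary tumors).  All conditions present are fit jointly with indicator
coding; pairwise contrasts are read off the fitted coefficients.  When
`percent` is exactly collinear with the condition coding (normal organs are
100% mouse), the *percent* column is dropped, never the tested term.

Components:

- **Size factors**: median-of-ratios over genes with a positive geometric
  mean, rescaled to geometric mean 1; library-size ratios as a warned
  fallback when no gene is nonzero everywhere.
- **Dispersion**: per-gene method of moments with floor 1e-8,
  `α = (s² − μ̄)/μ̄²`, where the variance is the df-corrected residual
  variance around the per-condition group means and the mean terms are the
  fitted means.  Conditioning on the group means matters: the marginal
  variance of a gene with a real 4-fold condition effect reads as α ≈ 0.5
  and destroys power.  There is deliberately no empirical-Bayes shrinkage
  across genes; calibration is achieved instead by the test's reference
  distribution (below) and verified by simulation.
- **Wald test**: `z = β/SE`, referred to a t distribution with the residual
  degrees of freedom (n − p).  With only ~10 residual df, the plug-in
  dispersion makes z heavier-tailed than normal; the t reference restores
  nominal behavior (measured type-I error 0.048–0.057 at nominal 0.05 over
  2000 null genes, 6+6 samples, dispersion 0.1), where a normal reference
  over-rejects (~0.075).
- **BH correction** is a 10-line step-up implementation, cross-checked in
  the tests against an independent implementation on random p-vectors.
- **Independent filtering**: a 20-point quantile scan of a baseMean
  threshold; among cutoffs whose BH rejection count is within one residual
  SD (about a lowess fit of rejections vs. cutoff) of the maximum, the
  smallest is used.  Maximizing rejections outright overshoots into
  well-powered genes whenever discoveries concentrate at high counts.
- **Outlier convention**: genes whose fold-change *sign* depends on a
  single sample are excluded from the correction — but only genes with a
  substantial effect (|log2FC| > log2 1.5), since a near-zero effect has no
  meaningful sign to cross.  Filtered and outlier genes carry an absent
  (NA) adjusted p-value; their raw statistics are still reported.
- **Recurrent genes**: fold threshold (default 2), minimum supporting lines
  and an optional per-line FDR < 0.05 requirement are all parameters;
  output is ordered by support then mean fold change.

GLM fitting itself (IRLS) is delegated to statsmodels'
`GLM(..., family=NegativeBinomial(alpha))`; everything around it —
normalization, dispersion, testing, filtering, recurrence — is implemented
here.

## Signature analyses

The single-sample enrichment score ranks a sample's genes by expression
(descending, ties broken by gene id) and accumulates

    ES(S) = Σ_i [ P_in(i) − P_out(i) ]

with `P_in` the cumulative in-set weight (rank weight `(N − position)^α`,
α = 0.25 by default) normalized to 1, and `P_out` the uniform step over
non-members.  The score depends on expression only through ranks, so it is
invariant to any strictly monotone per-sample transform — in particular to
species-mixture scaling — which is why it pairs naturally with per-species
log2 TPM.  With `normalize=True`, scores are divided by the matrix-wide
(max − min).  A set covering every gene scores 0 by convention; at α = 0
the score of a set and of its complement are exact negatives.

Cross-line ranking computes, per PDX line, mean ES in metastases minus mean
ES in mammary tumors, sums the differences over lines, and sorts
descending (ties by set name).  The sum rewards consistent activation
across lines but, being a plain sum, a large effect in one line can
outweigh small opposite effects elsewhere — this is a property of the
statistic, not a bug, and the per-line differences are always reported
alongside it.

Host-origin attribution maps candidate (human) signature genes into the
mouse namespace — by case-insensitive symbol equality by default, since
human and mouse symbols usually differ only in capitalization; an explicit
two-column map overrides this — then one-way ANOVA per gene between
metastasis-bearing and normal organ, retaining genes with p < 0.05 and the
correct direction.  Samples entering enrichment or host-side analyses are
pre-filtered to > 50% reads of the relevant organism (strict inequality).

## Triad analysis

For a triad (parental MGT, metastasis, MGT regrown from the metastasis),
fold changes FC₁ = met/MGT and FC₂ = regrown/MGT are computed on group-mean
linear TPM with pseudocount 1.  With cutoff t (default 2):
transient ⟺ FC₁ ≥ t ∧ FC₂ < t; selected ⟺ FC₁ ≥ t ∧ FC₂ ≥ t; mirrored
classes for FC₁ ≤ 1/t; else unchanged.  "Reverted to parental levels" is
operationalized as FC₂ < t, i.e. the regrown tumor is within the cutoff of
the parental level, because the cutoff rules are applied globally.  Fold
changes use expression levels rather than model-based statistics — the
classification describes expression patterns, not hypothesis tests; no
significance filter is applied on top of the cutoffs by default.

## The synthetic cohorts

Counts are gamma-Poisson: `μ_gs = base_g · effect_{g,cond(s)} ·
2^{slope_g(pct_s − p̄)} · fraction_s · libsize_s`, with per-gene relative
abundances `base_g` lognormal(σ = 1.2), planted fold-change tables per
condition, optional per-gene log2 slopes on the species percentage (the
composition confound), and Var = μ + αμ².  Reads are uniform substrings of
expression-weighted transcripts with recorded origins; references are
uniform-random sequences with ortholog pairs at a controlled divergence
(default 0.10 — high enough that 31-mers are informative, low enough to
exercise shared k-mers).

Preset conditions:

- `partition_demo`: 4 samples at human fractions 0.8/0.5/0.2/0.99,
  error-free 100-bp single-end reads, divergence 0.10.
- `de_demo`: one PDX line, 6 MGT (human fractions evenly spaced over
  0.72–0.91, the range typical of mammary tumors) vs 6 liver metastases
  (evenly spaced over 0.2–0.9: liver metastases span nearly the full range
  with a lower mean, so percent and condition are correlated but
  identifiable).  The spreads are realized deterministically because the
  composition spread is a fixed property of the cohort being emulated;
  i.i.d. draws at n = 6 occasionally produce a nearly separating design in
  which the composition-adjusted model is unidentifiable; 50
  genes planted at 4-fold; every null gene carries a composition slope
  ~N(0, 0.02 log2 per percentage point); NB dispersion 0.05, the realistic
  within-line value for replicate tumors of a clonal PDX line (calibration
  simulations use 0.1); 10⁶ counted reads per sample, a ~40× scale-down of
  a deep bulk library.
- `triad_demo`: 3 lines × 3 roles × 3 replicates; 30 transient + 30
  selected genes at 4-fold, disjoint; near-zero dispersion (and a large
  library, so Poisson noise is also negligible) in the noiseless variant,
  0.05 in the noisy one.
- `signature_demo`: 6 lines × (2 MGT + 2 metastases); one planted 30-gene
  metastasis program at 3-fold (a strong but ordinary pathway-level
  induction) among 100 size-matched decoy sets.

What the simulator does *not* emulate: isoform structure, GC/length bias,
positional coverage bias, realistic error profiles, library strandedness,
between-line baseline heterogeneity within a preset, and correlated gene
programs among null genes.  Passing tests therefore demonstrate the
*logic and calibration* of each stage under the stated noise model, not
robustness to every artifact of real libraries.  Single-end reads are the
default (partitioning is identical per mate); a paired mode exists.  An
optional third (viral) reference with zero expression is supported by the
composition machinery via the `exclude` argument.

## Problem sizes

Default verification scales: partition accuracy at 10⁵ reads/sample (4
samples), composition recovery at fractions {0.01, 0.1, 0.5, 0.9, 0.99} ×
10⁵ reads, TPM invariance over 100 paired replicates, DE calibration on
2000 genes at n = 6+6, signature ranking over 100 seeded repetitions, triad
recovery over 3 lines × 1000 genes.  These sizes make binomial/NB noise
envelopes tight enough for the assertions while keeping the whole suite in
a few minutes on one core.

## Known limitations

- Dispersion is estimated per gene with ~n degrees of freedom; at n < 4
  per group the t-referenced Wald test loses power quickly (no information
  sharing across genes by design).
- The k-mer partitioner indexes transcripts, not genomes: reads from
  unannotated or intronic regions of real data would be `unmapped` here.
- The within-organism gene-attribution plurality rule is a simplification;
  isoform-aware quantification is out of scope.
- `recurrent_genes` defaults to a twofold threshold; depending on context a
  1.5-fold threshold is equally defensible and is a parameter.
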