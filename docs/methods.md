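# Methods

## Model

The unit of analysis is a gene–drug pair (i, j) with Pearson correlation
r_ij between gene i's expression and drug j's AUC across the n aligned
samples.  The Fisher transform z_ij = atanh(r_ij)·√(n−3) is approximately
N(0, 1) under independence, which makes a two-groups mixture natural:

    z_ij ~ (1 − π_i)·N(0, 1) + π_i·N(0, 1 + ω²)

The alternative component is a symmetric variance inflation: only the
magnitude of an association enters the mixture, while its direction
(negative r = sensitivity marker, positive r = resistance marker) stays in
the association table.  The mixing probability is gene-level and driven by
the five standardised driver features:

    logit(π_i) = λ₀ + λ·m_i,   m_i = Σₖ v_k d_ik,  k ∈ {mutation, hubness,
                                      regulator, cnv, methylation}

so a gene's prior chance of carrying true drug associations is a learned
function of its disease-driver evidence.  v is unconstrained in sign —
methylation is expected to earn a negative weight — and the (v, λ) scale
indeterminacy is resolved by reporting v with unit Euclidean norm, folding
the magnitude into λ, which also enforces the λ ≥ 0 identifiability
convention.

### Fitting

EM with deterministic initialisation (v = 0, λ₀ = logit 0.01, ω² = 4):

- E-step: responsibilities γ_ij = P(pair true | z_ij) in closed form.
- M-step (logistic part): (λ₀, λ·v) maximise the expected complete-data
  log-likelihood, a weighted logistic regression of each gene's mean
  responsibility on its features (gene weight = its number of usable
  pairs).  Newton iterations with step halving guarantee the conditional
  objective never decreases; a 1e−8 ridge keeps the Hessian invertible
  when a feature column is constant (such columns are standardised to
  zero and flagged — their weight is unidentifiable).
- M-step (variance part): 1 + ω² is the responsibility-weighted second
  moment of z, floored at 1 + 1e−6.

Both conditional maximisations increase the observed-data log-likelihood
(ECM), so the trace is monotone; a decrease beyond 1e−8 raises an error
rather than being silently accepted.  Convergence: relative log-likelihood
change below 1e−6 (default), at most 500 iterations.  Reported standard
errors come from the inverse Hessian of the final logistic stage; they
are conditional on the responsibilities and therefore somewhat
optimistic — they rank the precision of the weights but are not full
EM-aware confidence intervals.

### Prioritisation

Genes are ranked by m_i (ties broken lexicographically by gene id).
Benjamini–Hochberg runs genome-wide over all p·q association p-values at
q = 0.1 first; the surviving pairs are then intersected with the top-N
genes.  N defaults to 500 and is a reporting choice, not a fitted
quantity.

## Association statistics

Pearson (or Spearman) correlation with t = r·√((n−2)/(1−r²)) and a
two-sided t p-value; with covariates, both sides are residualised on the
covariates (plus intercept) and the t test uses n−2−c degrees of freedom,
equivalent to testing the gene coefficient in a linear model of AUC on
expression plus covariates.  Perfect correlations report the smallest
positive float rather than zero.  Zero-variance genes or drugs yield NaN
entries that are excluded from the mixture with a logged count.

## Dose-response processing

Viability–concentration records are summarised by a four-parameter
logistic fit on log10 molar concentration, parameterised as (bottom,
span, log EC50, hill) with span ≥ 0 so bottom ≤ top by construction;
bounds are bottom ∈ [0,1], top ∈ [0,1.5], hill ∈ [0.1,10].  Replicates are
averaged before fitting; a non-convergent fit falls back to monotone
linear interpolation and is flagged.  The AUC is the trapezoidal mean of
the fitted viability clipped to [0,1] over the tested log-concentration
range, normalised by the range width so drugs with different ranges are
comparable; 1 means no effect, 0 complete kill.  The activity filter
keeps drugs whose minimum fitted viability is ≤ 0.5 in at least half the
samples (both thresholds configurable; filtering on fitted rather than
raw viability damps replicate noise).

## Hubness estimation

Expression hubness is a gene's degree in a co-expression network.  The
default estimator is lasso neighbourhood selection: each gene is
regressed on all others with a single shared penalty chosen by bisection
so the mean degree matches a target (default 5); an edge is kept when
either direction selects it.  A cheaper |r|-quantile thresholding
estimator is available and is preferable for genome-scale panels.
Constant-expression genes get degree 0 and are excluded from regressions.

## Evaluation statistics

- **Consistency rate**: for a method's total pair ordering, the first
  q·N pairs (N genes per drug on average) are intersected with the
  discovery-significant set (genome-wide BH, q = 0.1); a pair replicates
  if its validation p < 0.05 with the same association sign.  The rate is
  replicated/total, NaN when the budget holds no significant pair.
- **DCS**: per gene, a one-sided Fisher's exact p for the overlap of its
  associated drugs with each mechanism class (multi-class drugs count in
  each class; the one-sided p is the hypergeometric survival function,
  vectorised), and DCS = −log10 of the class minimum.  Significance comes
  from permuting the drugs' class assignments (each drug keeps its class
  count).  Reported per-gene p-values use add-one smoothing
  (1 + #{perm ≥ obs})/(B+1): never zero and conservative under the
  ties a discrete statistic produces.  For calibration displays (QQ
  plots) the result also carries a randomised-tie PIT that is exactly
  uniform under the null.  The global p compares the mean observed DCS
  with the permuted means.
- **Cluster enrichment**: drug AUC rows are standardised and clustered
  (average linkage, Euclidean); every internal dendrogram node of size
  2..q−1 is tested for one-sided Fisher enrichment of each multi-drug
  class at p ≤ 0.06, a class counting once if any node is enriched.
- **Class-specific markers**: per class, genes with Fisher class p <
  0.05 in the patient pair set and at least one association to a drug of
  that class conserved in the second (cell-line) pair set, ranked by
  score, top 3 kept.
- **Prediction**: per drug, ridge regression (penalty by efficient
  leave-one-out CV) on the top-scoring genes among those with training
  association p < 0.05 (fallback: smallest training p), default 10 genes
  per drug; with all genes it reduces exactly to plain ridge.  Baselines:
  per-drug elastic net (mixing 0.5, 5-fold CV) and a multi-task elastic
  net sharing support across drugs.  Split-half and leave-one-out
  harnesses score per-drug Spearman ρ; methods are compared by a
  one-sided exact Wilcoxon signed-rank test over drugs (ties dropped).

## Synthetic screens

The generator produces data from the structure the model assumes, at a
default desk scale of p = 1000 genes, q = 53 drugs, n = 30 discovery
samples, 12 mechanism classes (30% of drugs carrying a second,
annotation-only label), and validation replicates of 14 samples at
attenuation 0.8 (cell-line-like) and 12 samples at attenuation 0.4
(refractory-patient-like).

- **Driver features**: sparse mutation frequencies (15% of genes,
  Beta(1.5, 8)), overdispersed neighbour counts consistent with planted
  hub blocks (one 10-gene block per 50 genes, within-block correlation
  0.5), 15% regulators, Gaussian CNV and methylation.  The true score is
  m = D_std·v_true with default v_true ∝ (0.3, 0.8, 0.35, 0.15, −0.35)
  — hubness-dominant with negative methylation — λ₀ = logit(0.02) and
  λ = 2, giving a ~5% overall true-pair rate.
- **Markers**: gene i marks class c with probability π_i independently
  per class (so the marginal follows the logit exactly); drugs inherit
  their primary class's markers.  Each gene carries one association
  direction.
- **Marker modules**: a class's markers share a latent expression factor
  (variance share 0.5 per single-class marker, growing with the number of
  marked classes up to 0.9), and the class factors share a common
  sensitivity axis (25% of module variance).  This is what makes marker
  potential learnable at screen scale: a drug's response has unit
  variance, so dozens of *independent* markers could only reach
  correlations of order 1/√k, whereas co-expressed markers each correlate
  strongly with the shared response.  With these defaults the Fisher
  z-scores of true pairs have variance close to the configured
  1 + ω² (ω² = 4).
- **Response**: AUC_j = Φ(standardised linear combination of the drug's
  marker expressions + batch + noise), with the marker share 0.55 of the
  response variance.
- **Batch confounding**: each data set draws its own batch factor, loads
  it on a fresh random 10% of genes (share 0.55) and on every drug's
  response (share 0.35).  This produces strong, significant,
  *irreproducible* associations on feature-random genes — the failure
  mode prior-guided prioritisation exists to avoid.  Because the
  confounded subset is redrawn per data set, these associations never
  replicate.
- **Validation replicates** multiply marker effects by the attenuation
  factor, keep the noise law, and redraw the batch.

### What the generator does and does not emulate

It reproduces the statistical shape of a small screen — correlated gene
modules, class-shared markers, a general-sensitivity axis, batch-driven
false associations, attenuated validation — but not platform-specific
artefacts (probe effects, normalisation residue, count noise), dose-level
measurement structure (the AUC is generated directly on the probit
scale), or biologically curated feature correlations.  Passing tests
therefore demonstrate that the estimator recovers the generative
structure and that the evaluation statistics behave as designed, not that
the method will perform identically on any particular real screen.

A known property of the prescribed prior (λ = 2 on a roughly unit-scale
score) is that the very top-scoring genes saturate π ≈ 1 and mark nearly
every class; since a unit-variance gene cannot correlate strongly with
dozens of weakly-correlated drugs, their per-pair associations are
diffuse, and the replication advantage of the score-guided ordering
appears from roughly the top 1–2% of genes onward rather than at the very
first handful.  Replication comparisons are therefore evaluated at N = 20
(top 2% of a 1000-gene screen).

## Numerical choices

- Population-variance standardisation of features; constant columns map
  to zeros with a warning.
- Sample alignment restricts to the sorted intersection of sample ids, so
  results are invariant to input column order; fewer than 3 shared
  samples is an error.
- Missing matrix cells ("", NA, NaN) are mean-imputed per row; rows more
  than 20% missing are dropped and logged.
- Permutation tests, CV folds and the elastic-net path are all seeded;
  identical seeds give identical results.
- Score ranking and all pair orderings break ties deterministically
  (lexicographic ids), so repeated runs are identical.

## Limitations

- The exact likelihood behind the published method is not public; the
  two-groups covariate-dependent mixture implemented here is a concrete,
  defensible instantiation of its described behaviour (joint learning of
  feature weights and their impact on observed associations), versioned
  so an alternative likelihood can be substituted without touching
  prioritisation or evaluation.
- Standard errors are conditional on responsibilities (no Louis
  correction).
- The multi-task prediction baseline is a shared-support elastic net,
  not a Bayesian multi-task kernel method.
- Per-gene DCS p-values are conservative under ties; use the randomised
  PIT for calibration plots.
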