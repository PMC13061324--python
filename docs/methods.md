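# Methods

## Model

Counts `y_{g,n}` for gene g in sample n are modelled as negative binomial,
`y ~ NB(mu, alpha)` with `Var = mu + alpha*mu^2`, and a log-link GLM mean

```
mu_{g,n} = s_n * (CN_{g,n}/2) * exp(X_n . beta_g)
```

`s_n` is the median-of-ratios size factor (reference: genes with positive
counts in every sample; ratios to the per-gene geometric mean across
samples — note this estimator is invariant to a global rescaling of all
counts, and a pseudo-count fallback reference is available when no gene is
everywhere-positive). `CN/2` is the absolute copy number relative to the
diploid state; normal samples carry CN = 2 by definition. The *naive* mode
drops the CN term (equivalently CN ≡ 2); the *aware* mode includes it as a
fixed multiplicative offset, so any dosage-proportional expression change is
absorbed by the offset and `beta_condition` captures only the residual
(regulatory) effect.

Coefficients are fit on the natural-log scale and reported as
log₂FC = β/ln 2. CN values below `cn_floor = 0.1` are floored before forming
CN/2, because the offset is −∞ at a homozygous deletion; the floor is
config-exposed.

## Fitting

1. **Initial fit.** IRLS with a fixed dispersion of 0.1 gives per-gene
   fitted means. A fixed (rather than moment-based) initial value keeps the
   whole pipeline exactly equivariant under CN-offset shifts — rescaling a
   gene's tumor CN by k changes its aware log₂FC by exactly −log₂k — and any
   reasonable starting value is forgotten after the alternation below.
2. **Gene-wise dispersion.** Two alternations of (dispersion | coefficients).
   The dispersion maximises the Cox–Reid-adjusted log-likelihood
   `ll(alpha) − 0.5 log det(X' W X)`; the adjustment compensates for the
   downward bias from plugging in estimated coefficients (without it the
   Wald test is measurably liberal). Maximisation is by bisection on the
   score in log-dispersion over [1e-8, max(30, n)]; 40 bisections give
   ~1e-10 precision in log space.
3. **Trend.** `alpha(mu) = a0 + a1/mu` fit by iteratively reweighted least
   squares with gamma weights (1/pred²), excluding bound-hitting genes and
   ratio outliers; the trend covariate is the mean of size-factor-normalised
   counts (depth-normalised only, so the trend is a property of expression
   level, not of CN). A trimmed-median constant trend is the fallback when
   the parametric fit degenerates.
4. **MAP dispersion.** Normal prior on log-dispersion centred at the trend;
   prior variance = max(MAD²-based spread of log residuals − trigamma((n−f)/2),
   0.25). Gene-wise estimates more than 2 SD above the trend are dispersion
   outliers and are *not* shrunk (shrinking them understates variance).
5. **Coefficients and Wald test.** Final IRLS with MAP dispersions (ridge
   1e-6 on the normal equations, tolerance 1e-8, 100 iterations max;
   non-converged genes are flagged and their p-values dropped). Standard
   errors come from the inverse Fisher information; the Wald statistic
   `z = c'beta / se(c'beta)` is tested against the standard normal. By
   default the test uses the unpenalised MLE coefficients — the standard
   Wald construction needs the unpenalised SE — while the *reported* log₂FC
   and the effect-size gate use the shrunken estimate; `wald_on="map"`
   switches the test to the shrunken coefficients for sensitivity analyses.
6. **log₂FC shrinkage.** MAP estimate of the condition coefficient under a
   Cauchy prior (Laplace-approximation style), by damped Newton ascent of
   the penalised likelihood jointly over all coefficients, started at the
   MLE with monotone backtracking. The prior scale is adaptive: a
   method-of-moments estimate of the signal spread,
   `S² = max(mean(clip(b²) − se²), 0.05²)` over the condition MLEs (b²
   clipped at its 99th percentile). This reproduces the qualitative
   behaviour of published heavy-tailed shrinkage estimators — negligible
   shrinkage for well-informed genes, strong pull to zero for noisy
   low-information ones — without claiming bit-compatibility with any
   particular implementation.

## Stage-wise testing

Per gene, the CN-naive and CN-aware null hypotheses define a global null
(neither model finds DE). Screening uses the two-hypothesis Simes p-value
`pS = min(2*min(pN,pA), max(pN,pA))` and a single BH pass at level α over
all genes (genes with both fits failed are excluded from the family; a gene
with one failed fit is carried by its surviving model with the missing p
treated as 1). Screened genes enter Holm confirmation of the two component
hypotheses at level `t = alpha * |R| / G`, the BH threshold implied by the
screening rejections (the convention of the stage-wise testing literature;
`t = alpha` is available as a config option since the original level is not
printed anywhere). The comparator mode applies BH to each model
independently, which does not control the joint error rate and produces
more discordant (DSG/DCG-pattern) calls on correlated p-values.

A gene is DE under a model when its confirmed bit holds **and** its shrunken
|log₂FC| strictly exceeds 1 (strict inequalities as printed in the class
definitions; gating happens after confirmation, switchable). The
(naive, aware) bits map (1,0)→DSG, (1,1)→DIG, (0,1)→DCG, (0,0)→non-DEG; the
direction annotation uses the naive log₂FC for DSGs (their signal *is* the
dosage effect) and the aware log₂FC otherwise.

## Simulator

The generator emulates a matched tumor–normal bulk RNA-seq cohort:

- baseline mean `mu0 ~ LogNormal(meanlog 5, sdlog 1.5)` (median ≈ 150
  counts, long right tail — a realistic expression distribution without
  fitting to any external cohort);
- dispersion `alpha = (0.05 + 5/mu0) * LogNormal(0, 0.3)` — asymptotic
  dispersion 0.05 with the usual 1/μ inflation at low counts;
- class mechanisms: non-DEG (tumor mean μ₀, CN 2); DIG
  (μ₀·2^β, β ~ ±Uniform(1.2, 3), CN 2); DSG (per-sample μ₀·CN/2, β = 0);
  DCG (CN altered, mean buffered: μ₀·(CN/2)^(1−buffering), full buffering
  by default so the aware model's implied regulation is −log₂(CN/2));
- CN alterations: 80% gains / 20% losses. Strong signal = gains CN ∈ {4,5},
  losses CN 1, in all tumor samples. Weak signal = smaller-magnitude gains
  CN ∈ {3,4} (losses CN 1): a CN-4 gain implies a dosage log₂FC of exactly
  1.0 and a CN-3 gain 0.58, so weak-signal dosage effects straddle the
  |log₂FC| > 1 calling threshold and detection is genuinely reduced rather
  than impossible. (A per-sample penetrance mixture is available via
  `weak_altered_fraction`; note that with CN ≤ 5 any penetrance below ~100%
  caps the implied dosage effect below the calling threshold.);
- class counts follow the configured proportions exactly (largest-remainder
  rounding); library depth varies as LogNormal(0, 0.15) so size-factor
  estimation is genuinely exercised; all randomness flows from one
  `numpy` Generator, and replicate grids derive independent streams by
  `SeedSequence` spawning.

The CN-noise injector perturbs exactly `round(fraction * entries)` matrix
cells, chosen without replacement, with additive noise from
{−2,−1,0,+1,+2} weighted 5/30/30/30/5% (moderate CN-calling errors dominate
extreme ones), floored at CN 0.

**What the simulator does not model:** subclonal CN mixtures and intra-tumor
heterogeneity, nonlinear dosage–response (saturation at high ploidy),
correlated genes, GC/length biases, and outlier samples. Passing benchmarks
therefore demonstrate that the machinery recovers the model's own generative
structure under realistic count noise — not performance on any real cohort.

## Benchmarks

DE detection is scored with DIGs as true positives and DSGs/non-DEGs as
true negatives (DCGs are by construction invisible to a CN-naive analysis
and are scored separately in the classification task); metrics are
precision, recall, F1 and MCC, with NaN for undefined ratios. Effect-size
accuracy is the MSE and squared Pearson correlation between estimated and
true (regulatory) log₂FC over all scored genes. The classification
benchmark reports one-vs-one DCG-vs-DSG and DCG-vs-DIG counts (prediction
positive = classified DCG, restricted to genes whose truth is one of the
two classes) plus one-vs-rest metrics per class. The robustness suite
compares a clean run against runs on a noise-injected CN matrix: per-class
Jaccard overlap of memberships, squared Pearson correlation of
clean-vs-noisy aware log₂FC, and squared Spearman correlation of
clean-vs-noisy adjusted-p rankings, computed over the union of clean/noisy
members of each class with fit-failed genes dropped pairwise.

Problem sizes: the default grids use 5000-gene datasets at n = 10, 20, 40,
60 per condition with 5 replicates (2000 genes and 3 replicates for the
robustness grid) — large enough that replicate means are stable to a few
percent while the whole grid runs in minutes on one core.

## Numerical and design notes

- FDR calibration was checked on mixed simulations with a 15% non-null
  fraction. At much higher DE fractions (e.g. the 50%-DE benchmark mix)
  median-of-ratios normalisation itself acquires a small composition bias —
  asymmetric DE shifts the median ratio — which inflates the error rate of
  *any* ratio-normalised pipeline; this is a known limitation of the
  normalisation, not of the testing scheme.
- The expression filter (mean count < 10) is evaluated in normal tissue by
  default (`sample_set` switches to tumor or all samples).
- CN-state annotation: mean-CN bins neutral (1.7, 2.5], gain (2.5, 3.5],
  amplification (> 3.5); a gene with CN ≤ 1 in ≥ 25% of tumor samples is
  *loss* regardless of its mean, since recurrent deletions can hide behind
  a near-diploid average.
- No independent filtering, Cook's-distance outlier replacement, or LRT:
  the tested surface is the single-contrast Wald workflow described above.
- Degenerate inputs: all-zero genes are excluded from fitting and reported
  with NaN statistics; zero standard errors yield missing p-values; genes
  missing a p-value in both models are excluded from the BH family.
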