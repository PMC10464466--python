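# Methods notes

This note documents the statistical procedures, the numerical choices, the
synthetic-data design, and the known limitations of `sensescale`. Nothing
below reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Harmonization (itembank)

Items are keyed by *homolog group*: analogous questions appearing on more
than one instrument collapse into a single harmonized column. SP1/SSP1
score frequency in the direction opposite to the other instruments, so
their responses are reflected x → K+1−x (an involution) before merging;
after harmonization 5 always means "more frequent behavior". When a subject
answered more than one instrument's version of a homolog, the retained
response follows a configurable instrument-precedence order whose default
is newest-version-first (SEQ-3.0 ≻ SEQ-2.1 ≻ SP2 ≻ SSP2 ≻ SP1 ≻ SSP1).
There is no published rule for this reconciliation, so it is a
configuration option rather than an assertion; equal-precedence conflicts
raise an error. The category count K is fixed per item bank (default 5)
rather than inferred from data, so empty categories remain representable.
Missing responses are NaN; blank strings and user-configured codes map to
missing.

## Graded response models (grm)

*Model.* Probit cumulative-link GRM: P(Y_i > k | θ) = Φ(a_i'θ − b_ik) with
strictly increasing thresholds. Factors have unit variance and are mutually
orthogonal (bifactor convention); each item has a general slope and at most
one specific slope. Logit-metric parameters are accepted and converted with
D = 1.702. Probit is the internal link because the standardization
λ = a/√(1 + Σa²) then reproduces the linear factor-analytic structure
exactly, making the bifactor index formulas algebraically consistent with
the generating model.

*Estimation.* Marginal maximum likelihood by EM. The E-step evaluates each
subject's posterior on a Gauss–Hermite grid (21 nodes per dimension by
default). For bifactor structures the likelihood uses dimension reduction:
conditional on the general trait, item blocks belonging to different
specific factors are independent, so each block integrates over a Q×Q
(general × specific) grid instead of the full (1+S)-dimensional cube; the
equivalence with naive multidimensional quadrature is oracle-tested to
1e-4. The M-step refits each item by weighted ordinal probit regression of
the expected grid counts, with analytic gradients and thresholds
parameterized as (b₁, log-increments) to preserve ordering. EM stops when
the marginal log-likelihood improves by less than 1e-5 (pipeline stages use
1e-4; test-suite replicate fits use 1e-3 with an iteration cap — the fit
statistics are insensitive to the final EM digits) or after 500 cycles; the
log-likelihood is asserted non-decreasing every iteration. Unidimensional
scales require ≥ 3 items; a specific factor listed with a single item is
demoted to a general-only loading (a one-item factor is unidentified).
Observed-empty categories are collapsed into the adjacent category with a
recorded remap; items with fewer than two observed categories are rejected.
Factor signs are identified by reflecting each factor to a non-negative
loading sum.

*Scoring.* EAP means and posterior SDs come from the same quadrature
posterior (specific traits use the joint block posterior marginalized over
the general grid). Marginal reliability is ρ_xx = Var(EAP)/(Var(EAP) +
mean posterior variance). Subjects with no modeled responses receive the
prior (0, 1) and a flag.

*Plausible values.* M draws per subject (default M = 10) from the discrete
quadrature posterior with uniform jitter of half the local node spacing — a
simple, reproducible approximation to continuous posterior sampling rather
than MCMC. For secondary analyses the posterior can be conditioned on the
covariate under analysis through a latent regression θ ~ N(Xγ, σ²) whose
(γ, σ²) are estimated by EM on the grid. This conditioning matters:
unconditional draws are shrunken toward the population prior, which
attenuates a PV-on-covariate regression by roughly the score reliability;
conditioned draws keep it unbiased. The pipeline therefore draws a separate
conditioned PV set for each construct × correlate model.

## Limited-information fit (fitstats)

SRMR is the root-mean-square difference between sample polychoric
correlations and the model-implied ΛΛᵀ over off-diagonal pairs;
unestimable pairs are excluded and logged. The global chi-square is a
pooled bivariate-margin statistic: for every jointly observed item pair,
the Pearson X² between observed joint category proportions and the
model-implied joint probabilities (items in the same specific-factor block
are integrated over their joint grid), with cells pooled to a minimum
expected count of 1 and degrees of freedom reduced by the number of free
item parameters. RMSEA = √max(0, (X² − df)/(df·(N−1))) with N the mean
pairwise sample size; TLI compares X²/df against an independence baseline
(observed univariate margins, zero loadings) and is reported untruncated
(values above 1 occur for well-fitting models). This statistic is a
deliberate approximation to published C2-type statistics — pairwise
statistics are positively dependent, so it is not exactly chi-square
distributed — and its contract is calibration of the adequacy gates
(near-zero RMSEA and TLI ≈ 1 under a correct model at realistic n, clear
degradation under misspecification), which the test suite checks over
simulation replicates. The gates themselves are pure threshold functions;
the SRMR cut tightens from 0.05 to 0.033 for 3-item composites, and gate
comparisons treat unavailable statistics (df ≤ 0) as skipped rather than
failed.

## Structure exploration (structure)

*Polychoric correlations* use two-step ML: thresholds from inverse-normal
cumulative margins, then a bounded 1-D likelihood maximization of the
bivariate-normal contingency table (rectangle probabilities by CDF
inclusion–exclusion). Pairs with fewer than 30 joint observations (default)
or degenerate margins are reported missing. A Pearson fallback is
available.

*ICLUST-style refinement.* Agglomerative merging of the cluster pair
maximizing the worst-split reliability β = 4·cov(A,B)/var(A+B) of the
merged composite, with a branch stopping when a merge of two multi-item
clusters lowers both α and β below their subclusters' values (singletons
may always join; weak items are caught afterwards). After clustering, items
correlating < 0.30 (default) with their cluster composite, and items left
as singletons, are removed; the procedure repeats until no removals (a
stable solution). Ties break by sorted item id, making the routine
deterministic. The exact removal criteria used with the original data are
not published; the contract here is recovery of planted block structure,
not replication of specific item lists.

*EGA.* Graphical-lasso precision estimation on the (eigenvalue-repaired,
if needed) polychoric matrix over a 100-point log-spaced penalty grid with
EBIC (γ = 0.5) selection, partial correlations from the selected precision,
and deterministic walktrap community detection on absolute edge weights.
With strong specific loadings (≥ 0.4) and n ≥ 1000 the communities recover
the generating subscales (adjusted Rand ≥ 0.9 in the test harness); items
with very weak specific loadings can migrate between communities, which
mirrors how single indicators behave in real data.

*wTO.* wTO_ij = (Σ_u |w_iu w_ju| + |w_ij|)/(min(k_i,k_j) + 1 − |w_ij|) with
k the absolute node strength; oracle-tested against a brute-force double
loop.

## Random-effects IDA (ida)

One construct × correlate at a time: y standardized overall, x standardized
(continuous) or 0/1 (binary), random intercept + slope per study with a
correlated 2×2 covariance. The study-level effects are integrated out
analytically (matrix determinant lemma / Woodbury on per-study sufficient
statistics), leaving six parameters (β₀, β₁, σ, τ₀, τ₁, ρ) sampled with the
affine-invariant ensemble sampler (32 walkers, differential-evolution
moves, 1000 burn-in + 4000 kept steps thinned by 5; the run is extended up
to twice when split-R̂ exceeds 1.01). Scale parameters are sampled on their
natural positive scale — the log transform produces a long soft tail when a
variance component is near zero and mixes poorly. Priors (the original
specification is unavailable, so these are the package's weakly-informative
defaults): β ~ N(0,1), σ ~ half-t(3, 0, 1), τ ~ half-t(3, 0, 0.5),
ρ ~ LKJ(2). The model is refit once per plausible value and posterior draws
are concatenated — exact Bayesian combining over imputations, simpler than
Rubin's rules, and it propagates latent-score uncertainty into the effect
posterior (pooled posteriors are never narrower than single-PV posteriors).

Evidence: P_ROPE is the posterior mass inside the interval null
(r ∈ [−0.1, 0.1], d ∈ [−0.2, 0.2]); BF_ROPE is the ratio of posterior to
prior odds of lying outside the ROPE, with prior odds from Monte-Carlo
draws of the β₁ prior and a one-draw continuity floor when a side is empty.
Classes: log BF > 2.3 / > 1.1 strong/moderate non-null, < −2.3 / < −1.1
strong/moderate null, else inconclusive. Heterogeneity: τ₁² (posterior
median of the random-slope variance; τ is also reported to avoid SD/variance
ambiguity), ICC = (τ₀² + τ₁²Var(x))/(τ₀² + τ₁²Var(x) + σ²),
I² = τ₁²/(τ₁² + s̃²) with s̃² the harmonic-mean typical within-study
sampling variance of the slope, and a 95% prediction interval from
β₁ + b₁,new, b₁,new ~ N(0, τ₁²) per draw. Models with fewer than 100
complete cases (default) are skipped with a recorded reason; a single study
is rejected (random effects unidentified). The effect estimate is the raw
standardized slope — values outside [−1, 1] are possible and not clipped.

## Synthetic data (synth)

The generator is the exact generative counterpart of the bifactor GRM:
orthogonal standard-normal traits, latent response y_i = λ_G θ_G + λ_s θ_s
+ e_i with uniqueness variance 1 − h², categories by counting thresholds
below y_i. Default thresholds are symmetric (−1.2…1.2), giving
non-degenerate 5-category margins. Correlates: continuous
c = β_j θ + N(0, 1 − β_j²), so the within-study standardized association
equals β_j = effect + N(0, τ²) by construction (clipped to ±0.99); binary
correlates are drawn from a latent threshold model matched to the requested
Cohen's d and prevalence. Study sizes, administered item subsets (planned
missingness by instrument), effects and τ come from the multi-site design;
per-study random substreams are spawned from one master seed, so adding a
study never perturbs earlier studies.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: informative (MNAR) missingness, differential item
functioning across studies or instruments, non-normal trait distributions,
cross-loading items, and study-level mean differences in the traits
themselves (only effect-size heterogeneity is simulated).

## Problem sizes used in validation

Worked-example index checks are exact-arithmetic and instantaneous.
Parameter recovery fits the 12-item, 3-specific bifactor structure at
n = 3000 (standardized-loading RMSE ≤ 0.05). Fit-gate calibration uses 20
replicates of n = 2000 refit with a capped EM; the IDA checks use 12
studies of n_j = 100 with M = 10 plausible values for the non-null case and
10 single-PV replicates for the null case, scored with the
generating-parameter model. These sizes were chosen as the smallest designs
at which the respective claims are stable across seeds.

## Known limitations

- The omega family uses the linear-composite (sum-score) formula on
  standardized loadings. Categorical-omega variants computed from
  polychoric-implied covariances of the observed items give slightly higher
  ω_T for long scales (the 23-item hyperreactivity scale differs by ≈ 0.03);
  the ECV family and h² are formula-independent.
- The pooled bivariate X² is an approximation; its absolute value is not
  comparable across software, only the gate verdicts and model orderings
  are.
- Plausible values come from a discrete-grid posterior with jitter, not
  MCMC; with 21 nodes the grid granularity is ~0.35 SD, which the jitter
  smooths but does not remove for extreme scores.
- EGA penalty selection refits the graphical lasso over a full grid per
  call; on large item pools this dominates runtime.
- The IDA sampler targets a 6-parameter marginal posterior; it does not
  produce posteriors for individual study effects b_j (not needed for the
  reported summaries).
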