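# Methods

## Model

`jointprobit` fits a Bayesian multivariate probit joint species distribution
model (JSDM) to a site-by-taxon presence/absence matrix **Y** (n rows, J
taxa) and a shared design matrix **X** (n rows, K covariates):

    y_ij = 1(z_ij > 0),        z_i ~ MVN(B' x_i, R)

Each column of the coefficient matrix **B** is one taxon's abiotic niche
model — an ordinary probit regression on its selected environmental
covariates plus forced survey-design terms (round and area dummies, fixed
effects).  **R** is a J×J correlation matrix on the latent residuals: the
co-occurrence structure left over once the environmental responses are
accounted for, and the model's proxy for biotic interaction.  Four variants
are supported:

| variant            | covariates              | R          |
|--------------------|-------------------------|------------|
| `null`             | intercept + forced only | identity   |
| `community_only`   | intercept + forced only | estimated  |
| `environment_only` | per-taxon selections    | identity   |
| `full`             | per-taxon selections    | estimated  |

Structural zeros in **B** encode per-taxon covariate subsets, so a single
shared **X** serves every variant.

## Sampler

Fitting uses the classic latent-variable (Albert–Chib) Gibbs scheme.  One
sweep is

1. **z | B, R, y** — element-wise univariate truncated normals.  Taxa are
   updated in index order within the sweep (the order does not affect the
   stationary distribution; fixing it makes runs reproducible).  `z = 0` is
   counted as absence — a measure-zero tie, fixed for determinism.
2. **B | z, R** — one conjugate multivariate-normal draw of all free
   coefficients jointly (a seemingly-unrelated-regressions update; per-taxon
   cross-Gram blocks are cached so the per-iteration cost is one Cholesky).
3. **R | z, B** — a parameter-expanded step, skipped for identity-constrained
   variants.  The chain state keeps an *unrestricted* covariance Σ; given
   residuals E = z − XB it draws Σ ~ InverseWishart(J + 1 + n, I + EᵀE) via
   a Bartlett factorisation (which also yields Σ⁻¹ for the next latent
   sweep).  Stored draws are normalised back to the identified scale:
   R = cov2cor(Σ) and each taxon's coefficients divided by √Σ_jj.  This is
   the standard non-identified expanded sampler for multivariate probit
   models; the InverseWishart(J+1, I) prior on Σ induces a marginally
   uniform prior on every off-diagonal correlation.

### Priors

The coefficient prior is independent Normal(0, 10²) per free coefficient
(applied on the expanded scale; with a prior this weak the induced prior on
the identified coefficients is equally diffuse).  The correlation prior is
the marginally-uniform one induced by the parameter expansion above.  Both
are weakly informative defaults chosen for reproducibility; they are not a
reconstruction of any particular published analysis.

### Chains, seeding, convergence

Defaults: 2 chains × 30,000 iterations, 10,000 burn-in, thinning 10.  The
seed is required explicitly; a single `SeedSequence` is spawned per chain so
chains are independent yet the whole fit is bit-reproducible.  Split-chain
potential-scale-reduction (R̂) is computed for every free coefficient and
correlation; values above 1.1 raise a `ConvergenceWarning`.  Taxa observed
everywhere or nowhere raise a quasi-separation warning but the fit proceeds
— the proper prior regularises the intercept.

### Truncated-normal draws

Latent updates use the inverse-CDF method on `scipy.special.ndtr/ndtri`
with the argument clipped to [1e-15, 1−1e-15].  With standardised covariates
and effect sizes of realistic magnitude the truncation bounds stay far from
the extreme tails where this loses accuracy.

## Covariate selection

Per taxon, forward stepwise selection by maximum-likelihood probit fits
(statsmodels): start from intercept + forced terms, add the candidate with
the largest AIC decrease, stop when none lowers AIC.  Any strictly positive
decrease accepts a step (no Δ ≥ 2 rule).  Ties within 1e-9 go to the
earliest candidate in the supplied ordering, so selection is deterministic.
Candidates causing perfect separation (common with rare taxa and binary
vegetation indicators) are skipped for that step with a logged warning
rather than aborting the taxon.

## Likelihood, deviance and DIC

The likelihood of one site's occurrence pattern is a multivariate-normal
orthant probability.  With R = I it is the exact product of univariate Φ
terms; otherwise it is estimated with the GHK sequential importance sampler
(default 5,000 draws, antithetic uniform pairs, seeded, uniforms shared
across sites so repeated evaluations are comparable).  Site probabilities
are floored at 1e-300 before logs, with a warning.

Per-taxon deviance under a correlated model is defined *conditionally*:
−2 Σ_i log p(y_ij | y_i,−j), evaluated as the ratio of the joint orthant
probability to the one with taxon j marginalised out.  This lets the
correlation matrix inform per-taxon predictions (so "additional deviance
explained by community interactions" is a meaningful per-taxon quantity) and
reduces exactly to the marginal probit deviance when R = I.  The
community-level proportion explained is the ratio of summed deviances, not
the mean of ratios, which weights taxa by information content.

DIC = 2·D̄ − D(θ̄) with the *integrated* (GHK) likelihood: D̄ averages the
deviance over retained draws (optionally an evenly spaced subset when GHK
evaluation dominates runtime — the subset size is reported wherever used);
D(θ̄) plugs in the element-wise posterior mean of B and the posterior mean
of R projected to the nearest correlation matrix (eigenvalue floor 1e-6,
rescale to unit diagonal — the mean of correlation matrices need not be
one).  Conditioning DIC on the latent variables instead would change pD;
the integrated version is implemented.  Differences greater than 5 are
treated as appreciable when models are ranked.

## Posterior summaries

* **Effect sizes**: continuous covariates are standardised (mean 0, sample
  sd 1, n−1 denominator), so coefficients are per-1-sd effects; 0/1
  indicator effects are reported on their own scale and never mixed with the
  continuous ones.  Point estimate is the MAP — the mode of a Gaussian KDE
  (Silverman bandwidth) on a 512-point grid over the draw range;
  uncertainty is the central 95% quantile interval (linear interpolation
  between order statistics).
* **Bayesian p-value** of a correlation: the posterior fraction of draws
  that are zero or of opposite sign to the posterior mean (0.5 when the
  mean is exactly zero).  Edge case: when the posterior mean and median
  straddle zero this fraction can marginally exceed 0.5; the definition is
  kept as stated.
* **Correlation network**: an edge for every unordered taxon pair with
  Bayesian p-value below the threshold (default 0.05); edge weight is the
  posterior-mean correlation, sign recorded.
* **Co-occurrence dendrogram**: dissimilarity 1 − Pearson (phi) between
  occurrence columns (0 identical, 1 independent, 2 complementary),
  average-linkage (UPGMA) agglomerative clustering — the linkage is
  configurable since "hierarchical clustering" alone does not pin it down.
  Exported as Newick with branch lengths from merge heights.

## Spatial diagnostics

Raw residuals are observed occurrence minus the posterior-mean *marginal*
probability of presence, mean over draws of Φ(x_i·β_j) (not conditional on
the other taxa; the marginal is the simplest reading of "mean probability of
presence" and the choice is configurable).  Residuals are split by
round × area and each (split, taxon) series is screened with Moran's I —
inverse-distance weights with zero diagonal by default (k-nearest-neighbour
binary weights available), two-sided p-value from the normal approximation
under the randomisation null.  Series with p < 0.05 get a spline
correlogram: Moran-type distance-bin correlations, a cubic smoothing spline
through bin midpoints, and percentile confidence bands from resampling
sites with replacement (seeded).  Bins with fewer than two pairs are
dropped with a warning, and the reported band is widened where necessary to
contain the point-estimate curve.  "Coherent" spatial autocorrelation is
operationalised as ≥ 3 consecutive grid points whose 95% bands exclude
zero — a declared automation of what is otherwise a visual judgement.

## Synthetic data

The generator emulates a repeated-measures larval dipping survey and is the
test-bed for every other module: 167 dip sites in 3 survey areas visited
over 4 rounds (668 rows), 4 continuous water-chemistry covariates (depth,
temperature, oxidation-reduction potential, salinity) built from a shared
site-level factor plus visit noise and then standardised, 9 binary
vegetation indicators fixed per site with prevalences in [0.05, 0.5], and
planar coordinates uniform in area rectangles up to 1700 m across.
Occurrences come from the model's own generative process (latent MVN rows
thresholded at zero), so fits are exercised inside the model class.

The study-scale fixture has 16 taxa: 4 "mosquitoes" (pairwise residual
correlations +0.2 to +0.45), 2 "predators" (shrimp, fish) each planted with
negative correlations (−0.2 to −0.5) against two mosquito taxa, and 10
background taxa with weak correlations; the target matrix is projected to
the nearest valid correlation matrix (eigenvalue floor 0.05), and the
*projected* matrix is recorded as the truth.  Per-taxon environmental
effects use 2–4 randomly chosen covariates with magnitudes 0.4–1.5 on the
standardised scale (a detectability floor so planted covariates genuinely
drive occurrence) and intercepts in (−1, 0) so taxa are present at fewer
than half the sites.  Round and area effects (±0.4) are included so the
forced-term machinery is exercised.  The generator does **not** emulate
observation error, imperfect detection, abundance, or spatially structured
residuals — so passing tests say nothing about robustness to those
features of real survey data.

## Problem sizes used in the test experiments

The statistical acceptance experiments run at desk scale, chosen once:

* recovery: 100 datasets of 200 rows × 6 taxa, 2 chains × 5,000 iterations;
* DIC ordering: 100 replicates each of (n=500, 3 taxa, identity variants)
  and (n=250, 2 taxa, planted ρ=0.7, GHK 300 draws, 80-draw DIC subset);
* stepwise: 100 replicates at n=1,000 with a planted 1.5-sd covariate;
* Moran calibration: 500 null replicates at n=40.

A note on accuracy at these sizes: with 200 binary rows and realistic
covariate effects the marginal posterior sd of an off-diagonal residual
correlation is ≈ 0.13–0.16, so the mean absolute error of the
posterior-mean estimate sits in the same range even though the posterior is
well calibrated (interval coverage ≈ 92–95%) and the sampler is consistent
(MAE ≈ 0.04 at n=2,000).  Residual-correlation point estimates at a few
hundred sites should be read with their credible intervals, not alone.

## Known limitations

* Probit link only; no logit variant.
* Presence/absence only; no abundance models.
* No phylogenetic or spatially correlated random effects — spatial
  structure is diagnosed, not modelled.
* GHK likelihood estimates are Monte-Carlo; DIC values carry simulation
  error controlled by the draw count (fixed seeds make them reproducible).
* The DIC draw-subset and the correlogram's automated coherence rule are
  pragmatic operationalisations; both are parameterised and documented.
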