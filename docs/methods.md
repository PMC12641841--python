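# Methods

`expomix` implements a censoring-aware analysis chain for multi-pollutant
biomarker panels: a low-rank + sparse matrix decomposition that treats
values below the limit of detection (LOD) as interval information, latent
co-exposure structure extraction, person-level anomaly classification, the
Fatty Liver Index, and a Bayesian kernel machine regression of liver
markers on the exposure mixture. This note records the models, the
numerical choices, and what the synthetic studies do and do not establish.

## Data model and preprocessing

An exposure panel is a participants × analytes concentration matrix with,
per analyte, a strictly positive LOD, a detection flag matrix, a missing
mask, a chemical class (metal, PFAS, phthalate, PAH) and units. *Censored*
(measured, below LOD) and *missing* (never measured) are distinct states
end to end. Censored cells carry a NaN sentinel until `substitute_lod`
explicitly writes LOD/√2, the standard survey convention; no operation
imputes silently.

Detection frequency is detects / non-missing per analyte, and the
retention filter keeps analytes with frequency ≥ 0.5 — the boundary is
inclusive (exactly 50 of 100 is retained). Columns are scaled to unit
standard deviation **without centering**: mean-centering would create
negative entries, which is incompatible with the non-negativity constraint
on the low-rank component. LODs are divided by the same factors so the
censoring intervals stay consistent. An optional `log1p` pre-transform
exists (off by default) because whether concentrations should be
log-transformed before decomposition is a modelling choice the data owner
must make, not a default we guess.

## Low-rank + sparse decomposition under censoring

The scaled matrix X is modelled as X = L + S with L ≥ 0 low-rank
(population co-exposure patterns) and S sparse (individual spikes). The
fitted objective is

    ‖L‖* + λ‖S‖₁ + (μ/2) Σᵢⱼ fᵢⱼ(L + S)

where fᵢⱼ is (·−Xᵢⱼ)² on detected cells, the squared distance of (L+S)ᵢⱼ
to the interval [0, LODⱼ] on censored cells, and 0 on missing cells.
Censoring is therefore an interval constraint: any reconstruction below
the detection limit is equally consistent with a non-detect.

Two paths are available:

* **Nuclear-norm path** (`rank=None`): the convex objective above.
* **Rank-constrained path** (`rank=r`): the nuclear penalty is replaced by
  the hard constraint rank(L) ≤ r. On block-structured, strictly
  non-negative panels — which are highly coherent in the matrix-recovery
  sense — the convex penalty's minimizer provably trades a visible share
  of L into S at any fit weight, while the rank-constrained path recovers
  clean low-rank structure essentially exactly. Since the target rank is
  an explicit tuning parameter of the method, the rank path is the default
  in the pipeline (`rank=3`).

**Solver.** Alternating proximal steps with step 1/μ: a singular-value
step for L (soft-threshold or hard rank-r truncation) followed by
projection onto the non-negative orthant, then an entrywise
soft-threshold for S. The non-negativity projection makes the L-prox
inexact, so the L-step backtracks (halving the step, ultimately keeping
the previous iterate) whenever it would increase the objective — the
recorded objective trace is non-increasing by construction. Iteration
stops when the relative change of (L, S) falls below `tol` (default 1e-6)
or at `max_iter` (default 10 000); non-convergence returns a result with
`converged=False` plus a warning, never silently.

**Initialization.** The solver warm-starts from the rank-r (or
singular-value-thresholded) projection of the LOD/√2-substituted matrix,
and the rank path then runs a threshold-continuation phase: the S
threshold decays geometrically from the largest residual to its final
value λ/μ. Without this phase the tiny final threshold lets S absorb
transient misfit on detected cells, freezing the (non-convex) iteration at
poor stationary points; with it, S locks onto genuine spikes first. The
objective trace reported covers the monotone descent phase that follows.

**Defaults.** λ = 1/√max(n, p), the standard robust-PCA weight. μ =
10·√max(n, p): per-iteration singular-value shrinkage is 1/μ, so this
keeps the low-rank bias of the nuclear path small at desk scales, while
the S-threshold λ/μ stays far below spike magnitudes. Both are starting
points for the grid search, not conclusions.

**Model selection.** The grid search scores each (λ, μ, r) by the
detected-cells-only reconstruction loss. Because that loss is evaluated on
the same cells the model fits, it cannot penalize overfitting by itself;
a holdout mode therefore masks a seeded random 10% of detected cells
before fitting and scores only those. Both losses are reported; ties break
toward the smallest rank, then λ, then μ (parsimony, and determinism).

## Latent structure

SVD operates on the same SD-scaled (uncentered) matrix the decomposition
uses, keeping the latent space consistent with it. Sign convention: each
loading column's largest-magnitude entry is made positive, making results
fully deterministic. Variance explained is σₖ²/Σσ² over all singular
values of the input. Spearman correlations use pairwise-complete
observations with ties mid-ranked; pairs with fewer than 3 complete
observations are NaN, never silently zero. The raw-vs-denoised comparison
reports mean within-block and between-block |ρ| per chemical class.

## Anomaly classification

Residuals are X_scaled − L. Each column of S is divided by the standard
deviation of its residual column (plain SD by default; a 1.4826·MAD robust
option exists because spike cells inflate the plain SD — the default
follows the simpler convention). High/Low thresholds are the 95th/5th
empirical percentiles (linear-interpolation quantile convention) of the
entire rescaled matrix pooled across participants and chemicals; a cell is
High strictly above the upper threshold, Low strictly below the lower, and
Sparse otherwise. Missing cells are excluded from the quantile computation
and labelled Missing, not Sparse: "Sparse" is a statement about a value,
which a missing cell does not have. The classification is invariant under
any strictly increasing transform of the whole matrix.

A second, censoring-aware three-tier classifier labels below-LOD cells
Sparse, detected values at or below the analyte's detected-cell median Low
(boundary: at-median is Low), and the rest High. Both classifiers are kept
as distinct operations; the percentile classifier is the pipeline default.

## Fatty Liver Index

FLI = 100·exp(A)/(1+exp(A)) with

    A = 0.953·ln(TG) + 0.139·BMI + 0.718·ln(GGT) + 0.053·waist − 15.745

(TG mg/dL, BMI kg/m², GGT U/L, waist cm, natural logarithms, the original
Bedogni 2006 constants). Bands: ≥60 high probability of steatosis, <30
low, [30, 60) indeterminate. The index is strictly increasing in each
input and bounded in (0, 100); inputs must be strictly positive.

## Kernel machine regression

Y = h(X) + Zβ + ε with ε ~ N(0, σ²) and a Gaussian-process prior
h ~ GP(0, σ²τ·K), where

    K(xᵢ, xⱼ) = exp(−Σₘ γₘ (xᵢₘ − xⱼₘ)²/ρ)

with a single smoothness scale ρ and binary inclusion indicators
γₘ ~ Bernoulli(π), π = 0.5. Exposures are standardized to unit SD before
fitting; quantile-based summaries are computed on the original scale and
mapped through the stored scaling (quantiles commute with a monotone map).

**Sampling.** h is marginalized analytically — Y ~ N(Zβ, σ²(I + τK)) —
so the chain updates: β (conjugate Gaussian, prior N(0, 10⁴I)), σ²
(conjugate inverse-gamma, prior IG(0.001, 0.001)), a random half of the
γₘ per iteration by single-flip Metropolis, and log ρ, log τ by bounded
random walks (ρ ∈ [0.1, 1000], τ ∈ [0.01, 100], proposal SD 0.5). ρ is
initialized at the median pairwise squared distance. The whole posterior
is reproducible from one seed; per-block acceptance rates are reported.
Desk-scale defaults are 2 000 iterations with 1 000 burn-in at n ≤ 600;
larger n needs longer runs or fewer exposures (each likelihood evaluation
is one n×n Cholesky).

**Effect summaries.** Predictions of h use the GP conditional mean and
covariance per (thinned, ≤200) posterior draw, with one joint h sample
drawn per retained draw; estimates are posterior means and 95% equal-tail
credible intervals of the resulting contrast samples. The summaries are:
single-exposure interquartile contrasts (25th→75th percentile, others
fixed at a chosen quantile), exposure–response curves relative to a
reference quantile plus an interaction contrast (the curve at high vs low
background quantiles — zero under additivity), bivariate surfaces
(exposure a varied with exposure b pinned at its 25th/50th/75th
percentile, all else at medians; conditioning a variable on itself
degenerates to the univariate curve), and the overall mixture effect (all
exposures jointly at quantile q vs all at the median; the q = 0.5 contrast
is exactly zero by construction). PIPs are post-burn-in means of γ.

## Synthetic studies: what they emulate and what they do not

The generator produces L = U·Vᵀ from folded-normal factors with a
per-class boost on one factor column (block co-exposure by chemical
class), additive positive spikes of magnitude `spike_scale` × column SD at
uniformly random cells (a signed option exists for solver stress tests),
Gaussian matrix noise, LODs placed at configured empirical quantiles of
each column (so censoring proportions are controlled by construction),
uniform missingness, and outcomes h(X_active) + Zβ + ε for linear,
quadratic, sigmoidal, or pairwise-product h acting on z-scored true
exposures. One `noise_sd` drives both the exposure measurement noise and
the outcome noise; the defaults (noise_sd = 1, h amplitude 4, two active
exposures) put Var(h)/Var(ε) near 1–2, a clearly detectable but not
trivial signal. Covariates are age ~ U(20, 80), sex and smoking Bernoulli,
BMI ~ N(28, 5) truncated at 15; FLI inputs are log-normal TG and GGT with
waist coupled to BMI, wide enough that the index spans both clinical
cutoffs. One global seed feeds a named sub-stream per stage, so any stage
regenerates independently and bitwise-reproducibly.

What passing these studies does **not** show: real biomonitoring panels
have skewed, unit-heterogeneous concentrations, structured (non-uniform)
missingness, correlated assay batches, and survey design weights — none of
which the generator models. Recovery at the simulated signal-to-noise
says nothing about power at weaker real-world effect sizes, and the
percentile anomaly thresholds inherit the simulator's exchangeability
across participants.

## Problem sizes

The standard verification runs use 200×30 panels (decomposition), n = 150
to 300 with 8–10 exposures and 500–5 000 MCMC iterations (kernel
regression). These sizes give stable Monte-Carlo behaviour for the
properties checked while keeping a full verification run in the
tens-of-minutes range on one core; they are the package's reference
conditions, and larger studies scale by the noted per-iteration costs.

## Known limitations

* The rank-constrained path is non-convex; the continuation/warm-start
  scheme finds good optima in the tested regimes but carries no global
  guarantee.
* The kernel regression uses one global ρ; exposure-specific smoothness
  (ARD) and hierarchical group selection are out of scope.
* No creatinine adjustment, survey weights, or multi-cycle harmonization.
* XPT ingestion reads NHANES-style laboratory files but unit harmonization
  across files requires an explicit unit map; nothing converts silently.
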