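# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the known limits of what the test suite
demonstrates.

## Edge-influence statistics

MEI is computed from arithmetic means of the per-trap values at one edge
distance class and in the interior reference pool. The interior reference
is always the *logged-forest* interior traps (≥ 170 m from a road); primary
forest is reported alongside but never enters MEI, because the statistic is
meant to isolate the road effect within the logged landscape. An all-zero
pool makes the statistic undefined and raises an error rather than silently
returning 0.

RTEI permutes the pooled values without replacement, keeping the original
group sizes — a permutation test, not a bootstrap. The test is two-sided on
|MEI| because the statistic is signed and both enrichment and depression at
edges are of interest. The p-value carries the standard +1 correction, so
its floor is `1/(n_rand + 1)` and it can never be exactly 0. Each distance
class is tested separately at α = 0.05 with no multiple-testing adjustment
by default (an optional Holm flag exists); DEI is then the contiguous run
of significant distances starting at 0 m. Because of the +1 correction and
the discreteness of the permutation distribution the test is mildly
conservative: calibrated null rejection rates sit a little below the
nominal 0.05 (typically 0.04–0.05 at 999 permutations).

## Gradient models

Counts are fitted with an NB2 GLM (log link, `Var = μ + μ²/θ`) by joint
maximum likelihood via statsmodels; Gaussian responses (vegetation) use
OLS. When the dispersion MLE runs to the `θ → ∞` boundary (underdispersed
or noiseless data) the fit falls back to the Poisson GLM, which is the
correct limiting model there, and `θ` is reported as infinity.

The breakpoint ψ is estimated by maximising the profile likelihood over a
candidate grid between the 2nd and penultimate distinct distances. Grid
search was chosen over iterative linearisation because the design has few
distinct distances, the profile can be multi-modal, and a grid is
deterministic and trivially reproducible. The default resolution is 1 m;
the recovery simulations use a 10 m grid, which is an order of magnitude
finer than the sampling-noise scatter of the estimator at these sample
sizes (bootstrap SE ≈ 15 m). Candidate fits are warm-started from the
previous candidate's parameters. For Gaussian fits the profile uses
−(n/2)·log(SSR/n), which ranks candidates identically to the exact
likelihood and stays finite on noiseless data.

`ψ_se` comes from a seeded parametric bootstrap (default 200 resamples)
because no closed-form SE is reliable for a grid-profiled breakpoint at
these sample sizes. AIC counts the dispersion parameter and, for the
piecewise model, the breakpoint itself (k = 5 vs 3); ties in model
selection go to the single-slope model. The Wald t for the distance effect
is reported from the linear term of whichever model is selected; the
pre-break parameterisation means this is the gradient near the edge.

## Community composition

Rows (distance classes or traps — both supported, since either pooling is
defensible) are standardised to proportions, compared with Bray–Curtis, and
ordinated by non-metric MDS (SMACOF with monotone regression, best of 8
seeded restarts, Kruskal stress-1). Ties in the monotone regression follow
the weak (primary) treatment.

The multivariate edge-vs-interior test sums per-species NB
likelihood-ratio statistics for the two-level habitat factor. Under the log
link the group-mean MLEs are the sample means, so only the dispersion needs
a 1-D profile per species; it is profiled on a fixed log-θ grid, and the
same grid is used for the observed and bootstrap statistics so the
comparison is exchangeable. The null distribution is built by resampling
whole trap rows of randomized probability-integral-transform residuals
under the null fit and inverting them through the null quantile function —
resampling rows (not cells) preserves the between-species correlation
within traps, which is what makes the sum-of-LR statistic honest. This
procedure was designed to preserve the tested contrast and its error
control; it is this package's own construction, and the per-species LR sum
is not numerically comparable to other multivariate-GLM software statistics
(score/Wald variants), so no published statistic value is treated as a
reference.

## Vegetation mixed models

Predictors are standardized to mean 0, sample SD 1, so coefficients are per
SD of the raw variable and invariant to affine rescaling. The NB GLMM has a
single intercept-only random effect per plot; its marginal likelihood is
maximised under a Laplace approximation. The inner problem (posterior mode
of each plot effect) is a 1-D Newton iteration vectorised across plots; the
outer optimisation is L-BFGS-B over (β, log θ, log σ). With one grouping
factor and an intercept-only effect, Laplace is accurate: fixed effects
agree with R's glmmTMB to < 0.02 on the log scale in the cross-check test.
A fit whose random SD runs to the boundary is returned as valid with a flag
(it then equals the plain NB GLM). Wald SEs come from the finite-difference
Hessian of the marginal likelihood.

Moran's I uses inverse-Euclidean-distance, row-standardised weights with a
zero diagonal (k-nearest-neighbour weights are available), the most common
default for irregular point data. The Monte-Carlo test permutes residuals
over the fixed coordinates and is two-sided around E[I] = −1/(n − 1). In
the pipeline the test runs on plot-level mean Pearson residuals at plot
mid-point coordinates, since plots — not traps — are the independent
spatial units.

## Synthetic data-generating model

The generator reproduces the reference sampling design exactly: 24 edge
plots × 6 trap distances {0, 6, 12, 25, 50, 100} m (144 traps), 58
interior traps on 14 transects between 170 and 550 m (twelve 4-trap and two
5-trap transects), and 60 primary-forest traps on 12 five-trap transects.
Within an edge plot, traps are staggered on alternating sides of the
perpendicular line with 50 m lateral offsets, which guarantees the ≥ 50 m
within-plot spacing for any distance schedule.

Counts follow `NB(μ, θ)` with
`log μ = β0_s + u_plot + β1_g·min(d, ψ) + β2_g·max(d − ψ, 0)`:
`β1_g` is the pre-breakpoint gradient of functional group g, `β2_g` the
absolute gradient beyond ψ (0 = flat). Defaults are chosen to mirror the
reference community: 74 species on a log-series rank-abundance curve scaled
so an interior trap expects ≈ 129 individuals; ψ = 130 m; `β1 = +0.012`/m
for every functional group except small diurnal rollers (0, the
edge-insensitive group) and `β2 = 0`; θ = 1.5; plot random intercepts
log-normal with SD 0.3 (log-normal because it is conjugate with the log
link downstream); primary forest sits `exp(0.13)` above the interior
baseline, matching the observed primary-vs-interior abundance ratio. With
these values the edge-to-interior abundance ratio at 0 m is ≈ 0.2 and the
mean over 0–100 m ≈ 0.35, close to the reference edge/interior contrast.

Traits: large species are 12–30 mm long, small 3–11 mm, width 0.45–0.65 of
length; dry mass follows `0.0003·size^1.35` g (size in mm²) with 10%
log-normal noise, giving ≈ 1 g large and ≈ 0.03 g small beetles; 30% of
masses are withheld to exercise the allometric extrapolation. Vegetation:
eight measures move linearly from an edge value to an interior plateau over
[0, 34] m (successional vegetation declining, tree measures increasing)
with Gaussian noise proportional to the plateau.

What the generator does *not* emulate: species turnover mechanisms (counts
are independent NB draws given the mean surface, so compositional change
arises only through group-specific gradients), temporal structure across
sampling years, trap-level micro-habitat covariance beyond the shared
distance trend, and any road-network geometry. Passing tests therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to real-data pathologies such as zero-inflation or spatially
autocorrelated abundance.

## Problem sizes and numerical conventions

Simulation-based checks use: 1,000 null replicates × 999 permutations for
RTEI calibration; 100 replicates for breakpoint recovery (240 counts each,
10 m grid) and for GLMM coefficient recovery (24 plots × 7 traps);
scaled-down replicate counts with Monte-Carlo-matched acceptance bands for
the secondary composition-test calibrations. Permutation counts in example
runs default to the analysis-grade values (10,000 for RTEI, 1,000
elsewhere). All stochastic stages take explicit seeds; the pipeline derives
per-stage seeds from one master seed via `numpy.random.SeedSequence`, and
fixed seeds give bit-identical outputs.

Degenerate inputs are handled explicitly: identical pooled values give
RTEI p = 1 with a warning; all-zero composition rows and species are
dropped with warnings; coincident coordinates are an error for
inverse-distance Moran weights; constant predictors are an error naming the
variable.

## Known limitations

- The breakpoint SE is bootstrap-based and can be optimistic when the
  profile is flat near the boundary of the candidate grid.
- The Laplace approximation can bias variance components slightly downward
  with very small plots (< 5 observations); adaptive quadrature is not
  implemented.
- The multivariate composition test conditions on the observed species set;
  very rare species (fitted θ at the grid edge) contribute little signal
  but are not special-cased.
- Landscape accounting treats road length as a scalar input; no GIS
  processing is done, and the published reference-table audit reports the
  five internally inconsistent printed rows rather than correcting them
  (the pattern suggests a column row-shift in the source; richness is also
  not additive, so a weighted mean of means need not apply to it).
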