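# roadedge

Edge-effect statistics for ecological communities along linear
infrastructure (logging roads, tracks, pipelines), built around the study
design used for dung-beetle surveys along unpaved logging roads in
selectively logged tropical forest: plots of baited pitfall traps at fixed
distances from the road edge, deeper interior transects in the logged
forest, and reference transects in primary forest.

The package is aimed at community ecologists who want to quantify **how
strongly** and **how far** a road edge alters a biotic or structural
variable, and what that implies at the landscape scale.

## What it computes

**Magnitude of edge influence (MEI).** For a variable with mean `e` at one
distance class from the edge and mean `i` in interior habitat,

```
MEI = (e − i) / (e + i)
```

which is 0 when the edge equals the interior and bounded in [−1, 1] for
non-negative variables. Significance comes from the **randomization test of
edge influence (RTEI)**: the pooled edge + interior per-trap values are
permuted (group sizes fixed, 10,000 randomizations by default) to build a
null MEI distribution, with the two-sided p-value
`(1 + #{|MEI_rand| ≥ |MEI_obs|}) / (n_rand + 1)`. The **distance of edge
influence (DEI)** is the contiguous range of distances over which MEI stays
significant.

**Piecewise distance gradients.** Counts are regressed on distance with a
negative-binomial GLM (log link, variance `μ + μ²/θ`), and a two-segment
model with basis `{d, (d − ψ)₊}` estimates a breakpoint ψ by
profile-likelihood grid search, with a parametric-bootstrap SE and AIC
comparison against the single-slope model (the piecewise model is charged
two extra parameters, the slope change and ψ itself).

**Community composition.** Proportion standardisation, Bray–Curtis
dissimilarity, non-metric multidimensional scaling (Kruskal stress-1), and
a model-based multivariate test of the edge (≤ 100 m) vs interior (≥ 170 m)
contrast: per-species NB likelihood-ratio statistics are summed and
referenced to a null distribution built by trap-level resampling of
randomized probability-integral-transform residuals.

**Vegetation mixed models.** NB GLMMs of community metrics on eight
standardized vegetation predictors with a plot random intercept
(Laplace-approximate marginal likelihood), plus a Monte-Carlo permutation
test of Moran's I on the residuals.

**Landscape accounting.** Road-edge area = road length × edge-effect limit
× 2; landscape metrics as area-weighted means `w·edge + (1 − w)·interior`;
percent declines against interior logged and primary forest; and a
consistency audit of the published reference table.

A seeded synthetic-data generator reproduces the full study design (24
edge plots × 6 distances {0, 6, 12, 25, 50, 100} m = 144 traps, 58 interior
traps on 14 transects at 170–550 m, 60 primary-forest traps) so every stage
is testable end to end.

## Worked example

```python
from roadedge import (
    StudyDesign, CommunityModel, generate_design, generate_counts,
    generate_traits, extrapolate_mass, trap_metrics, fit_piecewise,
    select_model, road_edge_area, combined_metric, percent_decline,
)
from roadedge.edge_influence import edge_influence_profile

locs = generate_design(StudyDesign(), seed=1)
model = CommunityModel(seed=2)                      # breakpoint at 130 m
samples = generate_counts(locs, model)
traits, r2 = extrapolate_mass(generate_traits(model, seed=3))
metrics = trap_metrics(samples, traits)

results, dei = edge_influence_profile(metrics, "abundance",
                                      n_rand=10_000, seed=4)
for r in results:
    print(f"{r.distance_m:>5.0f} m  MEI = {r.mei:+.3f}  p = {r.p_value:.4f}")
```

prints

```
    0 m  MEI = -0.628  p = 0.0001
    6 m  MEI = -0.624  p = 0.0001
   12 m  MEI = -0.550  p = 0.0001
   25 m  MEI = -0.502  p = 0.0001
   50 m  MEI = -0.426  p = 0.0001
  100 m  MEI = -0.178  p = 0.0006
```

so abundance is depressed at every sampled distance (DEI = [0, 100] m, the
full tested range), most strongly at the road itself. The breakpoint fit on
the same data:

```python
sub = metrics[metrics["habitat"].isin(["road_edge", "interior"])]
fit = fit_piecewise(sub["abundance"].astype(int), sub["distance_m"],
                    grid_step=5.0, se_boot=100, seed=5)
label, delta = select_model(fit.linear_fit, fit)
# breakpoint = 131 +/- 14 m, model = piecewise, dAIC = 90.4
```

recovers the generator's true 130 m gradient change, and the piecewise
model beats the single slope by ~90 AIC units. Landscape accounting:

```python
road_edge_area(2403.0, 0.170)          # 817.0 km^2 of edge-affected forest
combined_metric(129.3, 48.6, w_edge=0.09)   # 122.0 beetles per trap
percent_decline(129.3, 122.0)          # 5.65 % decline vs interior forest
```

i.e. with road-edge forest making up 9% of the logged landscape, mean trap
abundance falls about 5.7% below what timber removal alone would suggest.

There is also a CLI (`roadedge simulate | metrics | mei | piecewise |
composition | glmm | landscape | report`); `roadedge report --seed 0` runs
every stage on a fresh synthetic dataset and writes one CSV per stage.

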