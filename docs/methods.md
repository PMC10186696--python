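# Methods

This note records the statistical models implemented in `dieloverlap`, the
defaults and why they were chosen, the numerical details that affect
results, and what the synthetic data generator does and does not emulate.

## Circular treatment of time of day

Observation clock times t (hours) are mapped to angles θ = 2πt/24 and all
densities are periodic on [0, 2π). Clock time, not solar time, defines the
circle: observations are analysed as recorded, with no sunrise/sunset
anchoring and no timezone arithmetic. Timestamps contribute only their
time-of-day component.

### von Mises kernel density estimate

The default estimator places a von Mises kernel at each observation,

    f̂(θ) = (1/n) Σᵢ exp{ν cos(θ − θᵢ)} / (2π I₀(ν)),

with kernel concentration ν set by the plug-in rule for a von Mises
reference density,

    ν = [ 3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²) ]^{2/5},

where κ̂ inverts the mean resultant length R̄ through Fisher's
approximations (κ̂ capped at 500 so degenerate samples remain usable; a
sample whose resultant vanishes, e.g. two exactly antipodal point masses,
raises an estimation error because κ̂ is unidentifiable). A user
multiplier `bandwidth_adjust` divides ν, so values above 1 smooth more and
the curve's maximum can only decrease — the orientation is chosen so that
"larger adjust = smoother", and is therefore *opposite* to R's `overlap`
package, whose `adjust` multiplies the concentration. For multimodal data
the von Mises reference makes κ̂ small and the rule oversmooths somewhat;
this is the standard behaviour of the plug-in prescription in the
activity-overlap literature and is accepted here for comparability.

Kernels are evaluated in the stable form exp{ν(cos d − 1)}/(2π I₀(ν)e^{−ν})
with exponentially scaled Bessel functions, so large ν neither overflows
nor loses the mode. Curves are evaluated on an m-point equispaced grid
(default m = 512) and renormalised by the periodic trapezoid rule, which
for equispaced periodic data reduces to h·Σvalues; the residual quadrature
error is far below statistical error at these sample sizes.

### Nonnegative trigonometric-sum density

The parametric alternative is the squared trigonometric polynomial

    f(θ) = |Σ_{k=0}^{M} c_k e^{ikθ}|²,   Σ_k |c_k|² = 1/(2π),

which is nonnegative and integrates to one for any complex coefficient
vector. Orders M = 0..4 are fitted by maximum likelihood (L-BFGS on the
unconstrained real/imaginary parts, normalisation inside the likelihood;
initialisation takes the inverse FFT of √(clipped empirical Fourier
density) plus two seeded perturbed restarts) and the order minimising
AIC = 2·NLL + 2·(2M) is returned — the norm and the global phase of c are
not identified, leaving 2M free parameters. Order 0 is the uniform
density, so flat data select a flat fit; note AIC retains the usual ~14%
chance per order of admitting a small spurious ripple at any n. Before
fitting, the sample is rotated so its circular mean is at zero and the
fitted curve rotated back; since the circular mean is exactly equivariant,
this makes the whole estimator exactly equivariant under rotation of the
data rather than equivariant only up to optimiser tolerance.

## Coefficient of overlapping

Δ(f, g) = ∫ min(f, g) over the circle, computed by the periodic trapezoid
rule on the shared grid and clipped to [0, 1]. Two sample-based estimators
are provided, following standard usage:

* `grid`: integrate the minimum of the two fitted curves;
* `at_points` (the "Dhat4" form): ½[ mean_i min(1, ĝ(xᵢ)/f̂(xᵢ)) +
  mean_j min(1, f̂(yⱼ)/ĝ(yⱼ)) ] over the pooled observations.

`auto` uses `at_points` once both samples have ≥ 75 observations, `grid`
below that — the conventional switch point. Densities at the observation
points are obtained by periodic linear interpolation of the fitted
512-point curves rather than re-summing kernels at every point; the
interpolation error (~10⁻⁴) is orders of magnitude below the statistical
error and keeps large resampling studies fast.

### Smoothed bootstrap and confidence intervals

Each bootstrap replicate redraws n₁ and n₂ angles from the two *fitted*
density curves by inverse-CDF sampling (cumulative trapezoid over the
closed circle, linear interpolation between nodes) and re-estimates Δ from
scratch, including re-estimation of the kernel concentrations. A raw
(data-resampling) bootstrap is available via `smoothed=False`.

Kernel smoothing biases Δ̂, and resampling from the fitted curves applies
the same bias a second time: in simulation at n = 200/side the replicate
mean exceeds Δ̂ by almost exactly the amount Δ̂ exceeds the true Δ. Raw
percentile intervals of the replicates therefore undercover badly (≈70%
observed for a nominal 95%). The default interval is consequently the
bias-corrected basic interval

    [2Δ̂ − q₀.₉₇₅, 2Δ̂ − q₀.₀₂₅] ∩ [0, 1],

whose first-order effect is to re-centre the interval at Δ̂ minus the
estimated smoothing bias; measured coverage at n = 200/side, 200
replicates is ≈ 91–96%. `ci_method="percentile"` returns the uncorrected
replicate quantiles, which by construction bracket the replicate
distribution (and its median) but inherit the double bias.

### Comparing two overlaps

`compare_overlaps` runs a two-sided Mann–Whitney rank-sum test on the two
replicate sets and reports the U statistic of the first argument (0 when
its replicates all fall below the second's), the asymptotic tie-corrected
p-value, and the orientation-proof effect size U/(n₁n₂). Interpreting a
rank-sum statistic over bootstrap replicates treats the replicates as the
sampling distributions to be compared; with 1000-vs-1000 independent
replicate sets its type-I error is calibrated (measured ≈ 5% at α = 0.05).
When replicate sets are built from overlapping data the test is
approximate — the package uses it, as the source analyses do, as a
descriptive separation measure.

## Pearson-system thermal preference

`fit_pearson` matches the first four sample moments (variance as m₂, skew
m₃/m₂^1.5, kurtosis m₄/m₂², plain moment estimators). Every Pearson family
solves, for the centred variable y,

    f′/f = −(y + a) / (b₀ + b₁y + b₂y²),

with a = b₁ = √μ₂·γ₁(β₂+3)/D, b₀ = μ₂(4β₂−3β₁)/D, b₂ = (2β₂−3β₁−6)/D and
D = 10β₂ − 12β₁ − 18. The root structure of the denominator selects the
family: real roots straddling the mean give the four-parameter beta
(type I), complex roots type IV (normalised numerically by quadrature),
real roots on one side the beta-prime (type VI); boundaries are the gamma
(III), scaled Student t (VII), symmetric beta (II), inverse gamma (V) and
the normal limit. Families are realised through the corresponding
scipy.stats distributions where one exists (with reflection for
negative-skew III/V/VI).

Because the classification statistics (γ̂₁, the type III criterion
2β₂−3β₁−6, …) are estimated, an absolute boundary tolerance would almost
never fire on data: sampling noise is O(n^{−1/2}). Boundary families are
therefore selected whenever the statistic is within 3 standard errors of
the boundary, with the SE taken as the larger of a 20-block subsampled
estimate (balanced blocks through a fixed internal permutation, so the fit
is deterministic and order-invariant) and the normal-theory asymptotic SE,
floored at 10⁻⁶ and capped so strongly skewed or kurtotic samples can
never collapse. The consequence is deliberate: interior types (I, IV, VI)
match all four moments essentially exactly (verified to ~10⁻¹⁴ relative by
quadrature), while a collapsed boundary family matches as many moments as
it has parameters — the gamma reproduces mean, variance and skewness and
implies a kurtosis within sampling noise of the observed one. Inputs with
kurtosis ≤ skewness² + 1 (outside the realisable region), zero variance,
or n < 4 raise estimation errors.

`activity_probability` divides the fitted density by its maximum on the
requested temperature grid, so the curve peaks at exactly 1; a grid that
misses the support entirely is an error, and temperatures outside the
tabulated grid map to probability 0 so cold nights or extreme heat never
acquire spurious edge weight.

## Operative temperature and potential activity

`aggregate_to` pools logger records into 288 half-open 5-minute
time-of-day bins [5i, 5(i+1)) by arithmetic mean across all loggers, all
days present, and the selected micro-environments; empty bins are flagged
missing. By default all four micro-environments (exposed soil, shade,
rock, burrow) are pooled, since the accessible thermal landscape is
site-dependent; any subset can be selected.

`potential_activity` weights each bin by the activity probability at its
mean operative temperature (missing bins get weight 0) and draws `n_out`
bin midpoints with replacement proportionally to the weights; an optional
flag jitters draws uniformly within the bin. All weights zero — the
thermal environment never touches the preferred range — raises a
thermal-mismatch error. In the pipeline `n_out` defaults to the number of
observed prey records at the site, so observed-vs-potential overlaps
compare equal-information samples.

## Pipeline

Per site, the pipeline estimates the predator and observed-prey kernel
densities, builds the potential-activity sample from the pooled T_b fit
and the T_o series, computes Δ with a smoothed-bootstrap CI for
observed-vs-potential, predator-vs-observed and predator-vs-potential, and
compares the last two with the rank-sum test. Raptor observation times are
pooled across species before density estimation. One seed drives the run;
per-site and per-bootstrap streams are spawned from it, and results.json
embeds the full configuration, so every number is reproducible from the
logged config and seed. Write→read→write of every CSV dialect is
byte-identical (canonical formatting: ISO 8601 seconds, fixed decimal
places).

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 38 prey
and 98 predator observation records per site; prey times from a
two-component von Mises mixture (07:30 and 18:30, κ = 4, weights
0.65/0.35 — a morning-dominant bimodal day), predator times from a single
broad von Mises at 13:00 (κ = 2); T_b from a shifted gamma (shape 9,
scale 1, shift 20 → mean 29 °C, mode 28 °C) clamped to the 20–40 °C
gradient; and per-logger 5-min operative temperatures following a cosine
diel curve with micro-environment-specific amplitude (exposed soil
12–45 °C > shade > rock > burrow 16–24 °C) plus Gaussian noise, two
loggers per micro-environment, one day. A capture-record generator
produces 319 individuals in 14 populations with male/female SVL around
244/301 mm and injury odds rising with length, higher in females, with a
negative length×sex interaction.

One seed sequence per scenario is split into independent child streams for
observations, body temperatures and loggers, so changing the logger count
never perturbs observation times and identical (config, seed) pairs are
bit-identical. Not emulated: multi-day weather, spatial structure,
predator–prey encounters, behavioural hysteresis in emergence/retreat, and
any dependence of observation probability on observer effort. Passing
tests on these data demonstrate the estimators' statistical properties
under the assumed structure; they cannot validate field-data artefacts
such as detection bias or rounded observation times.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script use: 12
closed-form von Mises pairs against 10⁵-point quadrature (agreement
~10⁻⁵); Δ recovery with n = 5000/side over 100 seeds; CI coverage with
n = 200/side, 200 replicates, 200 seeds; Pearson gamma recovery at
n = 10⁵; thermal-uniformity checks at n_out = 5000 over 100 seeds; and
rank-sum calibration over 400 (tests) / 1600 (script) null pairs. Grid
size 512 and the 75-observation estimator switch are package-wide
defaults. Ties and duplicate times are allowed everywhere; densities are
clipped at 10⁻³⁰⁰ in ratio estimators to avoid division by zero.

## Known limitations

* The plug-in bandwidth assumes a von Mises reference; strongly bimodal
  samples are oversmoothed, which inflates Δ̂ slightly — the bias-corrected
  interval compensates on average but cannot remove estimator bias from
  the point estimate itself.
* The rank-sum comparison of bootstrap replicate sets is descriptive when
  the two results share data (e.g. the same predator sample), as its null
  distribution ignores that dependence.
* Pearson boundary collapse is a statistical decision at ~3 SE; samples
  genuinely near a boundary may be assigned the adjacent interior type (or
  vice versa) with the corresponding small change in implied kurtosis.
* The potential-activity construction treats thermal suitability as the
  only constraint: no energetic, hydric or predation terms, no hysteresis,
  and a single pooled thermal landscape per run.
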