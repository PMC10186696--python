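# dieloverlap

Temporal niche analysis for ectotherm predator–prey systems: do prey shift
their daily activity away from the hours their predators hunt, even when
those hours are thermally the best ones?

The package was built around a concrete study system — a small montane
viper hunted by diurnal raptors — but every piece is generic: it takes
time-stamped observation records of two species, laboratory body-temperature
preferences, and operative-temperature logger series, and quantifies how
much of the thermally available activity window the prey actually uses.

## What it computes

**Circular activity densities.** Time of day is a circular random variable
(24 h ≙ 2π rad). Activity patterns are estimated either by a von Mises
kernel density estimate, with the kernel concentration ν chosen by the
plug-in rule ν = [3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²)]^{2/5} from the sample's
estimated concentration κ̂, or by a maximum-likelihood nonnegative
trigonometric-sum density f(θ) = |Σₖ cₖ e^{ikθ}|² with the order selected
by AIC.

**Coefficient of overlapping.** For two activity densities f and g,

    Δ = ∫ min{f(θ), g(θ)} dθ ∈ [0, 1],

the shared area under the two curves (0 = activity at disjoint times,
1 = identical timing). Sample-based estimation uses the grid estimator or
the at-points ("Dhat4") estimator, switching to the latter when both
samples have ≥ 75 observations. Confidence intervals come from a smoothed
bootstrap (replicates are redrawn from the fitted densities and Δ is
re-estimated from scratch); the default 95% interval is the bias-corrected
basic interval [2Δ̂ − q₀.₉₇₅, 2Δ̂ − q₀.₀₂₅]. Two overlap results are
compared by a two-sided rank-sum (Mann–Whitney) test on their bootstrap
replicate sets.

**Thermally potential activity.** The body-temperature preference T_b is
fitted with a Pearson-system distribution selected and parameterised by
matching the sample's variance, skewness and kurtosis. The fitted density,
rescaled to a maximum of 1, is an *activity probability* as a function of
temperature. Operative temperatures T_o are pooled into 288 five-minute
time-of-day bins, and times are resampled with each bin weighted by the
activity probability at its mean T_o. The resulting "potential" activity
distribution is what the animal could do on thermal grounds alone;
comparing it with observed activity (via Δ) exposes behavioural shifts.

**Survey summaries.** Injury prevalence, per-population survey effort, and
the rank-sum comparison of body size between sexes.

## Worked example

`examples/full_pipeline.py` simulates a two-site campaign (38 prey and 98
predator observations per site, gamma-shaped T_b preference with mode
28 °C, four logger micro-environments) and runs the full analysis:

```
thermal preference family: III

tymfi (38 prey, 98 predator obs):
  Delta observed_vs_potential  = 0.564 [0.388, 0.619]
  Delta predator_vs_observed   = 0.531 [0.419, 0.597]
  Delta predator_vs_potential  = 0.802 [0.696, 0.924]
  shift test (predator overlap, observed vs potential): W = 844, p = 0.00e+00
```

Read: the prey's *potential* activity (thermal suitability alone) overlaps
the midday predator activity strongly (Δ = 0.80), but its *observed*
activity much less (Δ = 0.53), and the rank-sum test on the bootstrap
replicates confirms the difference — the bimodal observed pattern avoids
the thermally optimal midday window that predators use. The other
examples (`simulate_scenario.py`, `estimate_densities.py`,
`overlap_with_ci.py`, `potential_activity_curve.py`,
`injury_summaries.py`) each exercise one capability and print annotated
numbers.

The same analysis runs from the shell on CSV inputs:

```
dieloverlap simulate --seed 3 --sites tymfi,lakmos --out data/
dieloverlap pipeline data/observations.csv data/tb.csv data/to.csv \
    --seed 1 --out results/
```

CSV schemas and the CLI subcommands (`simulate`, `density`, `overlap`,
`potential`, `pipeline`, `injuries`) are documented in `dieloverlap --help`;
exit code 2 flags input errors, 3 estimation errors.

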