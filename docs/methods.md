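# Methods

This note documents the model, the statistics, the numerical choices, and
the limits of what the package's tests demonstrate.

## The metacommunity model

Dynamics are discrete-time. One step consists of dispersal followed by local
growth.

**Dispersal.** Emigrants of species `s` from patch `p` are drawn
`E ~ Binomial(round(N), d)` and capped at `N` (rounding can otherwise draw
one more emigrant than the stock holds, e.g. `N = 0.6` rounds to one trial).
Under global dispersal every other patch receives the equal fractional share
`E/(P−1)`; under local dispersal patches form an `L×L` torus (`P = L²`,
row-major) and emigrants split equally among the four von-Neumann
neighbours. Both operators conserve per-species metacommunity totals to
floating-point exactness, a property asserted step-by-step in the tests.

**Growth.** Post-dispersal abundances update as

    N' = N · exp( r_s (1 − N/K_s − Σ_{j≠s} β_sj N_j/K_j)
                  + σ_e,s µ_e[p,t] + σ_d,s µ_d / √max(N, 1) )

Competition divides the competitor's abundance by the *competitor's*
carrying capacity (`β_sj = α_sj K_j / K_s` relative to classic
Lotka–Volterra α's), so carrying capacities and competitive effects are
controlled independently. `µ_d` is i.i.d. standard normal per species,
patch, and step.

The `1/√N` demographic-noise scaling is the first-order normal approximation
of individual-level birth–death variability. That approximation is derived
for populations counted in whole individuals; below one individual it
diverges (a population of 0.02 individuals would receive noise with sd
`7 σ_d`, producing spontaneous order-of-magnitude jumps). Because fractional
immigrant shares routinely create such populations, the divisor is floored
at one individual: `√max(N, 1)`. This bounds the per-step demographic noise
at `σ_d` without affecting populations of a whole individual or more.

**Extinction.** After each growth step, local populations below
`extinction_threshold` are set to zero. The default is 0.5 — round-to-nearest
zero individuals. The threshold is the model's only route to local
extinction, hence to richness fluctuation; it is deliberately exposed as a
parameter. Sensitivity (700-run ensembles, thresholds 0.25 / 0.5 / 1.0):
mean richness synchrony is nearly unchanged (0.34 / 0.32 / 0.33), while the
R² of the stability-on-synchrony regression moves 0.25 / 0.19 / 0.19 and the
parameter-driver regression R² moves 39% / 33% / 31%. Conclusions that hinge
on exact R² magnitudes should be read with this sensitivity in mind.

**Climate.** `c[t+1] = a·c[t] + b·φ[t]`, `c[0] = 0`, `φ ~ N(0,1)`,
`b = √(1−a²)` so that the stationary variance is 1 for every `a ∈ [0, 0.75]`
— autocorrelation is varied without varying the magnitude of environmental
fluctuation. Patch-level conditions are `µ_e[p,t] ~ Normal(c[t], h)`:
`h = 0` is a pure shared (Moran) driver, larger `h` decorrelates patches.

**Parameter distributions** (one draw per simulation; `sample_params`):

| parameter | meaning | distribution |
|---|---|---|
| S | species-pool size | uniform integers 15–55 |
| P | patches | uniform integers 9–49 (perfect squares 9–49 in local mode) |
| h | patch heterogeneity (sd) | U(0, 0.5) |
| a | climate autocorrelation | U(0, 0.75) |
| env_sd | sd of species' environmental responses | U(0.05, 0.5) |
| σ_e,s | per-species environmental response | Normal(0, env_sd) |
| σ_d,s | demographic susceptibility | U(0, 0.75) |
| r_avg | growth-rate half-spread | U(0, 0.25) |
| r_s | intrinsic growth rate | U(0.5−r_avg, 0.5+r_avg) |
| β_max | competition ceiling | U(0, 0.5) |
| β_sj | competition coefficients | U(0, β_max), zero diagonal |
| d | dispersal probability (shared) | U(0, 0.2) |
| K_s | carrying capacity | lognormal(logmean 3, logsd 1) |

`b` is derived from `a`, never drawn, and cannot be overridden directly.
Simulations start at `N = K` everywhere and run 100 steps; the first 50 are
burn-in and all statistics use the last 50, so analysis series have lengths
comparable to multi-decade field records.

**Randomness.** Each noise source (parameter draws, climate, patch
environment, dispersal, demographic noise) has its own generator keyed as
`default_rng([k, seed])` with a distinct small prefix `k`, so any component
can be reproduced in isolation and one integer seed pins the entire
simulation bit-for-bit.

## Richness synchrony

Per patch, the richness series is linearly detrended (OLS on the time index)
and its residuals are scaled to unit sample sd; the Spearman correlation is
computed for all patch pairs (midranks for ties) and the lower-triangle mean
is the synchrony value. Detrending/standardization is retained even though
rank correlation is invariant to increasing affine maps — it matters if a
user swaps in Pearson correlation.

Numerical choices:

- A series whose OLS residual sd is below `1e-9` of its scale (constant or
  perfectly linear richness) carries no rank information; pairs containing
  such a series are dropped from the mean and reported, not imputed as zero
  correlation.
- Standardized residuals are rounded to 9 decimals before ranking so that
  analytically tied residuals — common for integer richness series — are not
  broken by order-`1e-16` solver noise. The pairwise matrix then equals a
  brute-force midrank→Pearson computation to `1e-12`.

## The surrogate null test

AAFT surrogates are built per patch independently: rank-remap the series
onto a sorted Gaussian sample, randomize Fourier phases (conjugate symmetry
kept; DC and, for even lengths, Nyquist bins stay real), inverse transform,
and rank-remap back onto the original sorted values. Each surrogate patch
series is an exact permutation of the original (marginals preserved as
multisets), its autocorrelation is approximately preserved (lag-1 within
about ±0.15 for series of 30+ steps), and all cross-patch phase alignment is
destroyed — so the surrogate distribution of mean synchrony embodies "no
spatial synchrony beyond chance". Constant series are returned unchanged.

The p-value uses the add-one convention `(1 + #{surrogate ≥ observed}) /
(1 + n_surrogates)` so it is never exactly zero; the `significant` flag uses
the raw count (observed strictly exceeds 95% of surrogates). With 1,000
surrogates (the default) the test's type-I error at nominal 0.05 is within
binomial sampling error on independent-noise inputs; a warning is emitted
below 100 surrogates, where the p-value's resolution degrades.

Phases are randomized independently per patch: a common phase shift would
preserve cross-patch alignment and could not represent the no-synchrony
null.

## Community metrics and stability

All metrics accept an abundance cube or a long-format table.

- **Occupancy filter:** species present in fewer than 5% (configurable
  0–10%) of patch-by-time cells are removed before community-structure
  metrics, minimizing the influence of observation-error-like rarity. In the
  ensemble pipeline the filter is applied to the structure metrics only;
  richness synchrony and stability use the full cube (on simulations the two
  readings give near-identical synchrony, r ≈ 0.99).
- **Richness:** mean of `R[p,t]` over patches and steps.
- **Evenness:** Evar (default; `1 − (2/π)·arctan(var(ln n))`, population
  variance over the species present) per patch-time cell, averaged over
  cells with ≥2 species; Pielou's `J = H/ln S` available by flag. The
  ensemble records which was used.
- **Beta diversity:** mean pairwise Jaccard *similarity* of patch species
  lists pooled over all years (post-filter). The Baselga partition splits
  the corresponding Jaccard dissimilarity into a species-replacement
  (turnover) component `2·min(b,c)/(a+2·min(b,c))` and a
  richness-difference (nestedness-resultant) remainder; pairwise means are
  reported by default, the multiple-site form is available, and the two
  components sum to the total within `1e-12`.
- **Turnover:** per patch and consecutive census pair,
  `(gains + losses)/(species observed at either census)`, averaged within
  then across patches; both-empty pairs are skipped and logged.
- **Stability:** `−sd/mean` (sample sd, ddof 1) of the per-step
  metacommunity total abundance. Scale-invariant and ≤ 0; `−CV` rather than
  `1/CV` keeps the ensemble distribution from extreme skew.

## Ensemble experiments

`run_ensemble` simulates `n` independently parameterized metacommunities
(default 2,500 — the full study size; per-run seeds are integers below 2³¹
drawn from the master seed) and records parameters, synchrony, metrics, and
stability per run. Runs whose richness never varies anywhere are flagged
`degenerate` with missing synchrony and retained; regressions use listwise
deletion with reported counts (3–4% of runs at default settings).

Regressions are OLS on z-scored predictors (statsmodels), so coefficients
are effect sizes in response units per predictor-sd:

- *drivers*: synchrony on env_sd, a, P, h, r_avg, β_max, d;
- *structure*: synchrony on mean richness, evenness, Jaccard beta
  diversity, turnover rate;
- *stability*: stability on synchrony and, separately, on mean richness,
  plus a generic one-predictor sweep across all candidate metrics.

At the defaults, ensemble replicates consistently show: environmental
forcing strength (env_sd) is the strongest positive driver of richness
synchrony with climate autocorrelation (a) next; patch heterogeneity has
essentially no effect; dispersal's effect is positive; emergent mean
richness relates negatively and turnover positively to synchrony; and
synchrony predicts stability (negative slope) better than richness does.
These sign and ordering patterns, not the exact R² values, are the robust
output: the R² magnitudes move with the extinction threshold (above) and
with the continuous-abundance adaptation of the dynamics.

## What the synthetic data do and do not show

The fixture generator (`make_fixture`) produces long-format tables with the
dimensions, zero inflation, and spatial extents of multi-decade grassland
(≤ ~1.5 km, 6–30 plots) and coastal marine (up to ~75 km, 6–34 sites)
community surveys, by running the simulator with profile-tuned parameters
and subsampling. Fixtures therefore carry *realistic synchrony structure*,
which pure random tables would not. They do not emulate observation error,
taxonomic aggregation, missing censuses, or irregular sampling intervals —
passing pipeline tests on fixtures demonstrates mechanical correctness on
field-shaped data, not robustness to field-data pathologies (series are
regular and complete by construction).

## Known limitations

- Abundances are continuous; binomial emigration operates on rounded counts
  and immigration distributes exact fractional shares. A fully
  individual-based variant would change small-population behaviour.
- The extinction threshold is an explicit model ingredient, not an estimated
  quantity; R²-level results depend on it (see sensitivity above).
- Dispersal is distance-free (global or nearest-neighbour only); no
  distance-decay kernels, no species interactions beyond pairwise
  Lotka–Volterra competition, no age/stage structure.
- The surrogate test conditions on each patch's marginal and spectrum; it
  does not test against nulls that preserve cross-patch dependence of other
  variables.
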