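# richsync

Spatial synchrony of species richness in metacommunities: a stochastic
metacommunity simulator, the richness-synchrony statistic with a
surrogate-data significance test, community-structure and stability metrics,
and ensemble regression experiments linking synchrony to its drivers and to
ecosystem stability.

## Who this is for

Community ecologists studying spatiotemporal dynamics: the package asks
whether *species richness* — not just population abundance — fluctuates in
step across the patches of a metacommunity, what drives that synchrony
(Moran effects, dispersal, community structure), and what it implies for the
temporal stability of aggregate biomass. Everything runs on simulated or
generated data; the analysis functions equally accept long-format community
time-series tables (`patch, time, species, abundance`) from field surveys.

## The model and the statistic

**Dynamics.** `S` species inhabit `P` patches. Each discrete time step
applies binomial dispersal (global equal redistribution or nearest-neighbour
on a wrap-around lattice), then local growth:

    N[s,p,t+1] = N[s,p,t+d] * exp( r_s (1 − N[s,p,t+d]/K_s − Σ_{j≠s} β_sj N[j,p,t+d]/K_j)
                                   + σ_e,s µ_e[p,t] + σ_d,s µ_d[s,p,t] / √N[s,p,t+d] )

a discrete-time Lotka–Volterra competition model with environmental forcing
and demographically scaled noise. The regional climate is an AR(1) process
`c[t+1] = a·c[t] + b·φ[t]` with `b = √(1−a²)` (unit stationary variance for
any autocorrelation `a`); patch conditions are `µ_e[p,t] ~ Normal(c[t], h)`.
Populations falling below an extinction threshold (default: half an
individual) go locally extinct, which is what makes richness fluctuate.
Parameters are drawn per simulation from fixed sampling distributions
(`richsync.sample_params`).

**Statistic.** Per patch, the richness series `R[p,t]` is linearly detrended
and variance-standardized; the mean of the lower triangle of the pairwise
Spearman correlation matrix is the metacommunity's *richness synchrony*.
Significance is tested against amplitude-adjusted Fourier transform (AAFT)
surrogates, which keep each patch's values and approximate autocorrelation
but randomize cross-patch phase relationships.

**Stability.** Ecosystem stability is `−1 ×` the coefficient of variation of
metacommunity total abundance over time (larger = more stable).

## Worked example

```python
import richsync as rs

params = rs.sample_params(seed=1, overrides={"a": 0.6})
cube = rs.run_simulation(params)            # 100 steps, 50-step burn-in
R = rs.richness_series(cube)                # patch x time species counts
result = rs.surrogate_test(R, n_surrogates=1000, seed=1)
print(f"richness synchrony = {result.mean_synchrony:.3f}, "
      f"p = {result.p_value:.4f} ({result.n_pairs_used} patch pairs)")
print(f"stability = {rs.stability(cube):.3f}")
```

prints

```
richness synchrony = 0.852, p = 0.0010 (990 patch pairs)
stability = -0.297
```

— this metacommunity (36 species, 45 patches, strongly autocorrelated
climate) has strongly synchronous richness fluctuations: the observed mean
pairwise correlation of 0.85 exceeds all 1,000 phase-randomized surrogates,
and the aggregate abundance varies with a CV of about 30% over the analysis
window.

The same pipeline from the shell:

```sh
richsync simulate --seed 1 --out sim.csv --overrides a=0.6
richsync surrogate-test --in sim.csv --n 1000 --seed 1
richsync ensemble --n 2500 --seed 1 --out ensemble.csv
richsync analyze --ensemble ensemble.csv --which drivers
```

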