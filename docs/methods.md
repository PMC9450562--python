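# Methods

This note documents the models implemented in `reverb`, the assumptions
they make, the tunable parameters that matter, and the numerical choices
behind the fits. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## The branching-process model

Population activity is modelled as a driven branching process: the number
of active units obeys

    ⟨A_{t+1} | A_t⟩ = m·A_t + h,

where `m` (the branching parameter) is the mean number of next-bin events
caused by one current event and `h` is the mean rate of external drive per
bin. `m = 0` is temporally uncorrelated (asynchronous/Poisson) activity,
`m = 1` the critical point, and `m` just below 1 the reverberating regime
with long autocorrelation time `τ = −Δt/ln m`.

The model only fixes the conditional mean, so the simulator needs an
offspring law. We use Poisson: `A_{t+1} ~ Poisson(m·A_t) + Poisson(h)`
(drawn as one `Poisson(m·A_t + h)` variate, which is distributionally
identical). Poisson offspring give closed-form stationary moments — mean
`h/(1−m)` for `m < 1` — that the tests verify directly. Simulations start
at the rounded stationary mean and discard a burn-in (default 1000 bins,
configurable), so the recorded series is stationary by construction.

**Defaults.** `dt = 4 ms`, the timescale of neural activity used when a
simulation stands in for spiking data. Drives in tests and experiments are
set so stationary activity is O(10) events per fine bin, comparable to a
~200-neuron population firing at ~1 Hz.

## The lattice network

The spatial simulator places units on a periodic 2-D square lattice
(`n_units` a perfect square), each connected to its four nearest
neighbours. Every spike transmits to each neighbour independently with
probability `p_transmit` in the next bin; every unit receives independent
Poisson drive `h_unit` per bin. The implied branching ratio is
`4·p_transmit`, and the population total matches the pure branching process
with `m = 4·p_transmit` (verified to 5% in tests). Per-unit counts are
event tallies and can exceed 1 per bin — branching-process bookkeeping, not
a refractory neuron model. There is no refractoriness, no inhibition and no
heterogeneity: every unit is statistically equivalent, which is exactly
what makes the lattice useful for isolating the effect of *measurement*
(which units you record, and how time is binned) from network structure.

The inner loop is compiled with numba; for long runs where only the
population activity is needed, `simulate_lattice_activity` records the
per-bin total with O(steps) memory instead of the full raster.

## Subsampling operators and surrogates

- **Binomial spike subsampling** keeps each spike independently with
  probability `q` — the idealised model of limited recording yield under
  which the MR estimator is provably consistent.
- **Systematic neuron subsampling** keeps a uniformly random subset of
  rows — what an imaging experiment actually does.
- **Temporal coarsening** by factor `n`: `sum` adds each block of `n` bins
  (what a slow indicator plus spike inference effectively measures); `skip`
  keeps the last bin of each block and discards the rest. The trailing
  incomplete block is dropped in both modes, so the two modes stay
  block-aligned and `sum` conserves total spike count up to that tail.
- **Time shuffling** permutes bins (per neuron, for rasters), conserving
  per-neuron totals exactly while destroying all temporal correlation: the
  Poisson null.

## The MR estimator

For each lag `k = 1..k_max`, `r_k` is the ordinary-least-squares slope of
`A_{t+k}` on `A_t` (intercept included). Under the branching model
`r_k = b·m^k`, with `b = 1` at full sampling and `b < 1` under subsampling;
`m` is read off the decay while `b` absorbs the bias.

**k_max default**: `min(⌈10·τ_guess/Δt⌉, ⌊n/10⌋)` with a floor of 20, where
`τ_guess` comes from a quick two-parameter fit over `k ≤ 50`. Ten
autocorrelation times of lags retain the full decay; the `n/10` cap bounds
the noise floor. When analysing a shuffled *surrogate* of a dataset, use
the original dataset's `k_max` (pass `k_max=` explicitly): a surrogate test
holds the analysis fixed and varies only the data.

**Exponential fits.** `r_k = b·m^k` (and the offset variant
`b·m^k + c`) are linear in `(b, c)` for fixed `m`, so the fit profiles the
linear coefficients out exactly and searches the single remaining parameter
`m ∈ (10⁻⁸, 1.05]` on a coarse grid refined by bounded Brent minimisation.
This is deterministic, cannot fail to converge, and resolves exact-model
inputs to ~1e-8; ties break to the smaller residual, then the smaller `m`.

**Stationarity/Poisson battery.** "Residual" is the sum of squared fit
residuals throughout.

- `H_offset`: the offset model halves the residual
  (`2·R²_offset < R²_exp`) — transient drive increase.
- `H_τ`: `|τ_exp − τ_offset| / min(τ_exp, τ_offset) > 2` — drive ramp. If
  either fitted `m` lies outside (0, 1), its τ is undefined and `H_τ` is
  set true (conservative rejection).
- `H_lin`: a straight line beats the exponential (`R²_lin < R²_exp`) —
  sudden state changes.
- `H_MR_invalid`: one-sided one-sample t-test of mean(`r_k`) > 0 with
  p ≥ 0.1 — the flat-line case produced by both critical and Poisson
  activity. The `k_max` slopes are treated as the sample; their mutual
  dependence is deliberately ignored, as the procedure prescribes.
- `H_poisson` (only when `H_MR_invalid` is positive): the linear slope `q_1`
  is consistent with zero (p ≥ 0.05) — confirms Poisson activity, `m = 0`.

Verdicts: any of the first three positive → `rejected_nonstationary`; both
of the last two → `accepted_poisson` (`m = 0`); only `H_MR_invalid` →
`invalid`; none → `accepted_clear`. The **paper acceptance policy**
additionally admits `invalid`-only datasets (as `accepted_flagged`),
because short stationary recordings trip those two tests by fluctuation
alone; the **strict policy** does not. An all-zero `r_k` vector is
short-circuited to `accepted_poisson`.

The battery has a real false-positive rate: on clean stationary `m = 0.9`
simulations of 10⁵ bins, `H_offset` fires on roughly a quarter of seeds,
because neighbouring `r_k` share most of their data and a coherent tail
fluctuation is exactly what a free offset absorbs. This is a property of
the screening procedure itself, not of the simulator; treat a single
rejection as grounds for inspection, not exclusion.

**Timescale conversion.** Estimates at bin width Δt follow
`m̂ = m_true^{Δt/ΔT} = φ^{Δt}`. `timescale_convert(m, n) = m^n` converts
across integer coarsening factors; `fit_phi` fits `φ` to (Δt, m̂) pairs by
no-intercept regression of `ln m̂` on Δt (exact when the data follow the
law), with outliers excluded by explicit index. τ is invariant to the bin
size, which is what makes it the preferred cross-dataset summary.

## Avalanche analysis

Avalanches are maximal runs of consecutive nonzero bins of the population
activity. Runs touching the first or last bin are extracted but flagged
`edge_truncated` (their true extent is censored) and excluded from
distribution fits by default. A series with no silent bins yields no
avalanches and a warning flag — the signature of too-coarse binning, not an
error.

**Distribution fits.** Discrete power-law MLE via the Hurwitz-zeta
likelihood, `xmin` chosen by KS-distance minimisation when not fixed (both
choices reported). The comparison against the discrete exponential
(`P(x) ∝ e^{−λx}` on `x ≥ xmin`, MLE `λ = ln(1 + 1/(x̄ − xmin))`) uses the
Vuong-style normalised log-likelihood ratio with a two-sided normal
p-value; "power law" is favored only when the ratio is positive **and**
p ≤ 0.1 (threshold configurable), mirroring how such comparisons are
reported. The inverse-CDF sampler used for validation inverts the exact
zeta survival function by vectorised bisection — no tail truncation.

**⟨S⟩(T).** Since the mean size given duration is not a distribution, `β`
is an OLS slope of `log⟨S⟩(T)` on `log T` over distinct durations.

**Shape collapse.** Avalanches shorter than 5 bins, and durations with
fewer than 3 avalanches, are excluded. Mean profiles per duration are
rescaled to the unit interval — a T-bin profile sits on `t/(T−1)`,
endpoints included — and linearly interpolated at 1000 points. For
candidate `γ`, profiles are scaled by `T^−γ`; the collapse error is the
mean over interpolation points of the across-duration variance divided by
the squared span (max − min over all scaled profiles and points). The
search is coarse-to-fine over `γ ∈ [0, 5]`: steps 0.1, then 0.01 within one
coarse step of the optimum, then 0.001. The error is invariant to global
profile rescaling, so `γ` is too. Note the `t/(T−1)` convention: synthetic
profiles built on any other grid will carry a small interpolation-induced
error floor at short durations.

## Population statistics

The recording is cut into windows (fixed seconds, default 2 s, or a
multiple of the dataset's own τ; widths floor to whole bins, trailing
partial window dropped). From per-window spike counts `n_i^p`:

- unbiased covariances `ĉ_ij` with the 1/(N−1) factor (validated against
  the brute-force definition exactly);
- `μ`, `σ`: mean and SD of the off-diagonal `ĉ_ij`; correlations exclude
  zero-variance neurons (flagged), covariances keep them;
- `Δ = σ / mean(ĉ_ii)`; because `σ` is estimated from finitely many
  windows, `Δ` is biased upward at small N — a jackknife-over-windows
  bias-reduced value is reported alongside, clearly labelled a surrogate
  for the full correction, not the canonical formula;
- PCA on the neuron-by-window matrix (per-neuron mean removal, no variance
  scaling, spectrum via SVD), explained-variance ratios `λ̃_k`,
  `N_eff = (Σ λ̃_k²)^−1`, and loadings for heterogeneity inspection;
- `λ_max = 1 − 1/(1 + N·Δ²)` with the *underlying network size* `N`
  (default 1500, a larval-zebrafish habenula scale), not the number of
  recorded neurons.

## Replication experiments and problem sizes

`spatial_subsampling_experiment` reproduces the measurement chain that
biases `m̂` under realistic conditions: lattice at the fine timescale →
record a random subset of units → temporal summation ×15 (4 ms → 60 ms) →
MR on nested further subsets. Defaults: 2,500 units, 250 measured, 10-minute
recordings (150,000 fine bins), 1 Hz per-unit rate, 20 seeds — sizes chosen
to mirror a typical single-plane imaging session. Two regimes matter:
`m_true = 0.985` (reverberating; `0.985¹⁵ = 0.7972` at 60 ms) and
`m_true = 0.9999` (near-critical; `0.9985` at 60 ms).

At these sizes the qualitative pattern is reproduced — the estimate is
stable between 125 and 250 measured units, degrades below ~100 (median drop
≈ 0.05 at 25 units), and the near-critical regime is far less sensitive.
The *magnitude* of the degradation, however, depends strongly on how small
a fraction of the network is measured (here 250 of 2,500 units, i.e. 10%;
a plane of a larger structure samples far less), so quantitative statements
about this bias only transfer between systems at matched sampling
fractions; the `n_units` argument exists precisely to explore that axis.

## What the synthetic data does and does not show

The generators emulate: branching statistics of population activity,
spatial propagation on a homogeneous graph, spike- and neuron-level
subsampling, temporal summation vs. skipping, and Poisson surrogates. They
do **not** emulate: calcium indicator dynamics or spike-inference errors
(inputs are assumed to be spike counts), cell-type heterogeneity, 
inhibition, refractoriness, or nonstationary drive from behaviour. Passing
tests therefore validate the *estimators and their stated invariances*, not
the claim that any particular biological recording satisfies the model's
assumptions — that is what the stationarity battery screens for on real
data.

## Known limitations

- The Poisson offspring law is an assumption; heavy-tailed offspring would
  change avalanche statistics at fixed `m`.
- The battery's t-test ignores dependence among the `r_k`; its thresholds
  (factor 2, p = 0.1, p = 0.05) are the procedure's conventions, exposed
  as configuration but not calibrated here.
- KS-based `xmin` selection can settle deep in the tail of a sample whose
  true cutoff is small; both `xmin` and the tail size are reported so this
  is visible.
- The jackknife on `Δ` reduces, but does not remove, the finite-window
  bias.
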