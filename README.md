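# reverb

Criticality diagnostics for neural population spike rasters: where does a
population's spontaneous activity sit on the **asynchronous – reverberating –
critical** spectrum?

`reverb` is aimed at systems neuroscientists who have a spike raster
(neurons × time bins of non-negative spike counts with a known bin width,
e.g. spikes inferred from calcium imaging) and want quantitative, 
subsampling-aware answers to three questions:

1. **Avalanche scaling.** Are there neuronal avalanches — runs of nonzero
   population activity between silent bins — whose size `S` and duration `T`
   distributions follow power laws `f(S) ~ S^-τ_S`, `f(T) ~ T^-α`, with
   `⟨S⟩(T) ~ T^β` and mean profiles that collapse as `s(t,T) ∝ T^γ F(t/T)`
   satisfying the crackling-noise relation `γ = β − 1`? Distribution fits use
   discrete maximum likelihood with a KS-minimising lower cutoff and a
   Vuong-style normalised likelihood-ratio test against the exponential.

2. **Branching parameter and autocorrelation time.** Modelling the population
   activity as a driven branching process `⟨A_{t+1}|A_t⟩ = m·A_t + h`, the
   multistep-regression (MR) estimator fits the lag-k regression slopes
   `r_k = b·m^k`. Because spatial subsampling only rescales the slopes by a
   constant `b`, the decay base `m` — and the autocorrelation time
   `τ = −Δt/ln m` — survive severe subsampling where the naive one-step slope
   fails. A battery of stationarity and Poisson tests (`H_offset`, `H_τ`,
   `H_lin`, `H_MR_invalid`, `H_poisson`) screens each dataset before an
   estimate is reported, and the conversion law `m̂ = φ^Δt` moves estimates
   between measurement timescales.

3. **Population covariance and dimensionality.** From windowed spike counts:
   the unbiased pairwise covariances `ĉ_ij`, the mean `μ` and width `σ` of
   their distribution, the normalised width `Δ = σ / mean(ĉ_ii)`, the
   PCA participation ratio `N_eff = (Σ_k λ̃_k²)^-1`, and the distance to the
   dynamically balanced critical point, `λ_max = 1 − 1/(1 + NΔ²)`.

A synthetic-data module provides ground truth for every stage: driven
branching processes, a periodic 4-neighbour lattice network, binomial spike
subsampling, systematic neuron subsampling, temporal summation/skipping, and
time-shuffled (Poisson) surrogates.

## Worked example

```python
import reverb
from reverb import mr

series = reverb.simulate_branching(
    reverb.BranchingConfig(m_true=0.9, h=1.0, steps=100_000, seed=12345)
)
result, report = mr.estimate_branching(series)
sub = reverb.subsample_spikes_binomial(series, q=0.1, seed=7)
subr, _ = mr.estimate_branching(sub)
```

Running `python examples/subsampling_invariance.py` prints:

```
full sampling : m_hat = 0.8997, r_1 = 0.9001
10% of spikes : m_hat = 0.9012, r_1 = 0.3259, bias coefficient b = 0.3642
subsampling rescales every slope r_k by the same constant b, so the decay base m survives; the naive r_1 estimate does not.
```

With the full data, the one-step slope and the MR fit agree (`m ≈ 0.9`,
a reverberating regime with `τ ≈ 38 ms` at 4 ms bins). After discarding 90%
of the spikes, the one-step slope collapses to 0.33 — it measures `b·m`, not
`m` — while the MR estimate is still 0.90. The other scripts in `examples/`
demonstrate avalanche scaling fits, the bin-size conversion law `m̂ = φ^Δt`,
and the covariance/dimensionality statistics, one capability per script.

A thin CLI mirrors the library for batch use:

```bash
reverb simulate --model branching --m 0.9 --h 1 --steps 50000 --seed 1 --out data/
reverb mr data/raster.csv            # MR estimate + stationarity battery
reverb avalanches data/raster.csv    # scaling fits
reverb popstats data/raster.csv      # covariance, N_eff, lambda_max
reverb report data/raster.csv        # full pipeline, JSON report
```

## Layout

- `src/reverb/raster.py` — raster/series types, I/O, temporal coarsening
- `src/reverb/simulate.py` — branching & lattice simulators, subsampling operators
- `src/reverb/avalanches.py` — avalanche extraction and scaling analyses
- `src/reverb/mr.py` — MR estimator, stationarity battery, timescale conversion
- `src/reverb/popstats.py` — covariance, participation ratio, λ_max
- `src/reverb/pipeline.py` — orchestration and replication experiments
- `src/reverb/cli.py` — thin command-line wrapper
- `docs/methods.md` — models, assumptions, numerical choices, limitations
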