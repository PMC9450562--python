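"""Why multistep regression: invariance to spike subsampling.

Keeps only 10% of the spikes of a m = 0.9 branching simulation (binomial
subsampling — what limited recording yield does to data) and shows that the
one-step regression slope collapses while the MR estimate does not.
"""

import reverb
from reverb import mr

series = reverb.simulate_branching(
    reverb.BranchingConfig(m_true=0.9, h=1.0, steps=100_000, seed=12345)
)
sub = reverb.subsample_spikes_binomial(series, q=0.1, seed=7)

full, _ = mr.estimate_branching(series)
subr, _ = mr.estimate_branching(sub)

print(f"full sampling : m_hat = {full.m_hat:.4f}, r_1 = {full.naive_r1:.4f}")
print(f"10% of spikes : m_hat = {subr.m_hat:.4f}, r_1 = {subr.naive_r1:.4f}, "
      f"bias coefficient b = {subr.b_hat:.4f}")
print("subsampling rescales every slope r_k by the same constant b, so the "
      "decay base m survives; the naive r_1 estimate does not.")
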