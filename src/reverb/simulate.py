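"""Synthetic spiking data: driven branching processes and lattice networks.

These generators provide ground-truth data for every stage of the analysis
pipeline.  The core model is a driven branching process for the population
activity :math:`A_t`,

.. math:: \\langle A_{t+1} \\mid A_t \\rangle = m A_t + h,

where ``m`` is the branching parameter (mean number of next-bin events
caused by one current event; ``m = 1`` is critical) and ``h`` the mean rate
of external drive per bin.  The offspring law is Poisson: the update draws
``A_{t+1} ~ Poisson(m * A_t) + Poisson(h)``, which has exactly the
conditional mean above and known stationary moments, making the generator
testable in closed form.

The lattice network realises the same dynamics spatially: units sit on a
periodic 2-D square lattice, each spiking unit transmits to each of its four
neighbours independently with probability ``p_transmit`` in the next bin,
and every unit receives independent Poisson drive.  The implied branching
ratio is ``4 * p_transmit``.  Per-unit counts are event tallies (they can
exceed 1 per bin), matching branching-process bookkeeping.

Subsampling operators emulate measurement limitations: binomial spike
subsampling (each spike kept with probability ``q``), systematic neuron
subsampling (a random subset of rows), and time-shuffled surrogates that
destroy temporal correlations while conserving per-neuron totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from numba import njit

from .raster import ActivitySeries, SpikeRaster

__all__ = [
    "BranchingConfig",
    "LatticeConfig",
    "simulate_branching",
    "simulate_lattice",
    "simulate_lattice_activity",
    "subsample_spikes_binomial",
    "subsample_neurons",
    "shuffle_time",
]

#: timescale of neural activity used as the default simulation bin (seconds)
DEFAULT_DT = 0.004


@dataclass
class BranchingConfig:
    """Parameters of a driven branching-process simulation.

    ``init`` defaults to the stationary mean ``h / (1 - m)`` (rounded) for
    subcritical processes.  ``burn_in`` bins are simulated and discarded
    before recording starts.
    """

    m_true: float
    h: float
    steps: int
    seed: int
    init: Optional[int] = None
    burn_in: int = 1000
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if not (0.0 <= self.m_true <= 1.05):
            raise ValueError("m_true must be in [0, 1.05]")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.steps < 100:
            raise ValueError("steps must be >= 100")
        if self.h == 0 and (self.m_true < 1 or self.resolved_init() == 0):
            raise ValueError("h = 0 guarantees extinction for this configuration")

    def resolved_init(self) -> int:
        if self.init is not None:
            return int(self.init)
        if self.m_true < 1:
            return int(round(self.h / (1.0 - self.m_true)))
        return max(1, int(round(self.h)))


@dataclass
class LatticeConfig:
    """Parameters of the periodic square-lattice network simulation.

    ``n_units`` must be a perfect square (the lattice side squared).  The
    implied branching ratio is ``4 * p_transmit``; ``h_unit`` is the Poisson
    drive rate per unit per bin.
    """

    n_units: int
    p_transmit: float
    h_unit: float
    steps: int
    seed: int
    degree: int = 4
    burn_in: int = 1000
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.degree != 4:
            raise ValueError("only 4-neighbour lattices are supported")
        side = int(round(math.sqrt(self.n_units)))
        if side * side != self.n_units:
            raise ValueError("n_units must be a perfect square")
        if self.n_units < 100:
            raise ValueError("n_units must be >= 100")
        m = self.degree * self.p_transmit
        if not (0.0 < m <= 1.05):
            raise ValueError("implied branching ratio 4*p_transmit must be in (0, 1.05]")
        if self.h_unit < 0:
            raise ValueError("h_unit must be >= 0")

    @property
    def side(self) -> int:
        return int(round(math.sqrt(self.n_units)))

    @property
    def m_implied(self) -> float:
        return self.degree * self.p_transmit

    def stationary_unit_mean(self) -> float:
        m = self.m_implied
        if m >= 1:
            return self.h_unit
        return self.h_unit / (1.0 - m)


def simulate_branching(config: BranchingConfig) -> ActivitySeries:
    """Simulate ``A_{t+1} ~ Poisson(m A_t) + Poisson(h)``.

    Returns the activity series after discarding ``config.burn_in`` bins.
    """
    rng = np.random.default_rng(config.seed)
    total = config.burn_in + config.steps
    out = _branching_loop(
        float(config.m_true), float(config.h), int(total), int(config.resolved_init()), rng
    )
    return ActivitySeries(values=out[config.burn_in :], dt=config.dt)


def _branching_loop(m: float, h: float, total: int, init: int, rng) -> np.ndarray:
    out = np.empty(total, dtype=np.int64)
    a = init
    for t in range(total):
        a = rng.poisson(m * a + h)
        out[t] = a
    return out


@njit(cache=True)
def _lattice_loop(side, p, h_total, steps, burn_in, seed, init, record_idx):  # pragma: no cover
    np.random.seed(seed)
    n = side * side
    a = init.copy()
    n_rec = record_idx.size
    out = np.zeros((n_rec, steps), dtype=np.int64)
    rec_pos = -np.ones(n, dtype=np.int64)
    for j in range(n_rec):
        rec_pos[record_idx[j]] = j
    total = np.zeros(steps, dtype=np.int64)
    nxt = np.zeros(n, dtype=np.int64)
    for t in range(steps + burn_in):
        for i in range(n):
            nxt[i] = 0
        # external drive: total Poisson, each event lands on a uniform unit
        n_drive = np.random.poisson(h_total)
        for _ in range(n_drive):
            nxt[np.random.randint(0, n)] += 1
        # transmission: each spike reaches each of 4 neighbours with prob p
        for i in range(n):
            ai = a[i]
            if ai == 0:
                continue
            r = i // side
            c = i - r * side
            up = ((r - 1) % side) * side + c
            down = ((r + 1) % side) * side + c
            left = r * side + (c - 1) % side
            right = r * side + (c + 1) % side
            for _ in range(ai):
                if np.random.random() < p:
                    nxt[up] += 1
                if np.random.random() < p:
                    nxt[down] += 1
                if np.random.random() < p:
                    nxt[left] += 1
                if np.random.random() < p:
                    nxt[right] += 1
        for i in range(n):
            a[i] = nxt[i]
        if t >= burn_in:
            s = 0
            for i in range(n):
                s += a[i]
                j = rec_pos[i]
                if j >= 0:
                    out[j, t - burn_in] = a[i]
            total[t - burn_in] = s
    return out, total


def simulate_lattice(
    config: LatticeConfig, record_units: Optional[np.ndarray] = None
) -> SpikeRaster:
    """Simulate the lattice network, returning a per-unit spike raster.

    ``record_units`` restricts the returned raster to the given unit indices
    (rows in index order); the full lattice is always simulated.  Initial
    activity is drawn Poisson at the stationary per-unit mean so that the
    burn-in starts near equilibrium.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    init = rng.poisson(config.stationary_unit_mean(), size=n).astype(np.int64)
    if record_units is None:
        record_idx = np.arange(n, dtype=np.int64)
    else:
        record_idx = np.asarray(record_units, dtype=np.int64)
        if record_idx.size == 0 or record_idx.min() < 0 or record_idx.max() >= n:
            raise ValueError("record_units out of range")
        record_idx = np.unique(record_idx)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    counts, _ = _lattice_loop(
        config.side,
        float(config.p_transmit),
        float(config.h_unit * n),
        int(config.steps),
        int(config.burn_in),
        kernel_seed,
        init,
        record_idx,
    )
    meta = {
        "model": "lattice",
        "m_implied": config.m_implied,
        "h_unit": config.h_unit,
        "seed": config.seed,
    }
    return SpikeRaster(counts=counts, dt=config.dt, meta=meta)


def simulate_lattice_activity(config: LatticeConfig) -> ActivitySeries:
    """Lattice simulation returning only the population activity A_t.

    Equivalent to summing the full raster over units ("full sampling") but
    with O(steps) memory, for long runs where the per-unit raster is not
    needed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    init = rng.poisson(config.stationary_unit_mean(), size=n).astype(np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    _, total = _lattice_loop(
        config.side,
        float(config.p_transmit),
        float(config.h_unit * n),
        int(config.steps),
        int(config.burn_in),
        kernel_seed,
        init,
        np.empty(0, dtype=np.int64),
    )
    return ActivitySeries(values=total, dt=config.dt)


def subsample_spikes_binomial(
    x: Union[SpikeRaster, ActivitySeries], q: float, seed: int
) -> Union[SpikeRaster, ActivitySeries]:
    """Keep each spike independently with probability ``q``.

    Each count ``c`` is replaced by a ``Binomial(c, q)`` draw; this is the
    spike-level spatial subsampling under which the MR estimator is
    provably consistent.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(x, SpikeRaster):
        return SpikeRaster(
            counts=rng.binomial(x.counts, q),
            dt=x.dt,
            neuron_ids=x.neuron_ids,
            meta=dict(x.meta),
        )
    if isinstance(x, ActivitySeries):
        return ActivitySeries(values=rng.binomial(x.values, q), dt=x.dt)
    raise TypeError("expected SpikeRaster or ActivitySeries")


def subsample_neurons(
    raster: SpikeRaster, keep: Union[int, float], seed: int
) -> SpikeRaster:
    """Keep a uniformly random subset of neurons (systematic subsampling).

    ``keep`` is a neuron count (int) or a fraction in (0, 1] (float).  Row
    order is preserved.
    """
    n = raster.n_neurons
    if isinstance(keep, float) and keep <= 1.0:
        n_keep = max(1, int(round(keep * n)))
    else:
        n_keep = int(keep)
    if not (1 <= n_keep <= n):
        raise ValueError(f"keep={keep} out of range for {n} neurons")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_keep, replace=False))
    ids = [raster.neuron_ids[i] for i in idx] if raster.neuron_ids is not None else None
    return SpikeRaster(counts=raster.counts[idx], dt=raster.dt, neuron_ids=ids, meta=dict(raster.meta))


def shuffle_time(
    x: Union[SpikeRaster, ActivitySeries], seed: int
) -> Union[SpikeRaster, ActivitySeries]:
    """Randomly permute time bins, destroying temporal structure.

    For a raster each neuron's bins are permuted independently; per-neuron
    spike totals are conserved exactly.  The result is the Poisson-activity
    surrogate used to null-test the MR battery.
    """
    rng = np.random.default_rng(seed)
    if isinstance(x, SpikeRaster):
        shuffled = np.empty_like(x.counts)
        for i in range(x.n_neurons):
            shuffled[i] = x.counts[i, rng.permutation(x.n_bins)]
        return SpikeRaster(counts=shuffled, dt=x.dt, neuron_ids=x.neuron_ids, meta=dict(x.meta))
    if isinstance(x, ActivitySeries):
        return ActivitySeries(values=x.values[rng.permutation(x.n_bins)], dt=x.dt)
    raise TypeError("expected SpikeRaster or ActivitySeries")
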