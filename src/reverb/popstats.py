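"""Spike-count covariance, dimensionality and distance to instability.

The recording is divided into ``N`` windows ("subsets"); ``n_i^p`` is the
total spike count of neuron ``i`` in window ``p``.  From the unbiased
pairwise covariances

.. math:: \\hat c_{ij} = \\frac{1}{N-1} \\sum_p (n_i^p - \\bar n_i)(n_j^p - \\bar n_j)

we report the mean ``mu`` and SD ``sigma`` of the off-diagonal
distribution, the normalised width ``Delta = sigma / mean(c_ii)``, the
PCA explained-variance ratios and the participation ratio

.. math:: N_\\mathrm{eff} = \\left(\\sum_k \\tilde\\lambda_k^2\\right)^{-1},

and the largest eigenvalue of the implied effective connectivity,

.. math:: \\lambda_\\max = 1 - \\frac{1}{1 + N\\Delta^2},

whose critical point is at 1 (the dynamically balanced critical state).
``N`` here is the underlying network size, not the number sampled; the
default of 1500 is the larval zebrafish habenula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "SpikeCountMatrix",
    "PopulationStats",
    "spike_count_matrix",
    "count_covariance_stats",
    "participation_ratio",
    "lambda_max",
    "population_stats",
]

DEFAULT_NETWORK_SIZE = 1500


@dataclass
class SpikeCountMatrix:
    """Neurons x windows matrix of per-window spike totals."""

    counts: np.ndarray  # (n_neurons, n_subsets)
    window_width: float  # seconds

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_subsets(self) -> int:
        return self.counts.shape[1]


@dataclass
class PopulationStats:
    cov: np.ndarray  # off-diagonal c_ij, i < j
    var: np.ndarray  # diagonal c_ii
    corr: np.ndarray  # off-diagonal correlations (zero-variance neurons excluded)
    zero_variance_neurons: np.ndarray
    mean_cov: float  # mu
    width_cov: float  # sigma
    mean_var: float  # mean c_ii
    Delta: float
    Delta_jackknife: Optional[float]  # bias-corrected surrogate, non-canonical
    evr: np.ndarray
    N_eff: float
    lambda_max: float
    loadings: np.ndarray  # (n_components, n_neurons)


def spike_count_matrix(
    raster: SpikeRaster,
    window: str = "fixed_seconds",
    width: float = 2.0,
    tau: Optional[float] = None,
) -> SpikeCountMatrix:
    """Aggregate a raster into per-window spike totals.

    ``window="fixed_seconds"`` uses windows of ``width`` seconds;
    ``window="tau_multiple"`` uses ``width * tau`` seconds, with ``tau`` the
    dataset's autocorrelation time.  Widths convert to a whole number of
    bins by flooring (at least 1); the trailing partial window is dropped.
    """
    if window == "fixed_seconds":
        width_s = float(width)
    elif window == "tau_multiple":
        if tau is None or tau <= 0:
            raise ValueError("tau_multiple mode needs a positive tau")
        width_s = float(width) * float(tau)
    else:
        raise ValueError(f"unknown window mode {window!r}")
    if width_s < raster.dt:
        raise ValueError("window width must be at least one bin")
    bins_per = max(1, int(width_s / raster.dt))
    n_windows = raster.n_bins // bins_per
    if n_windows < 2:
        raise ValueError("recording must span at least 2 windows")
    trimmed = raster.counts[:, : n_windows * bins_per]
    counts = trimmed.reshape(raster.n_neurons, n_windows, bins_per).sum(axis=2)
    return SpikeCountMatrix(counts=counts, window_width=bins_per * raster.dt)


def _unbiased_cov(counts: np.ndarray) -> np.ndarray:
    centred = counts - counts.mean(axis=1, keepdims=True)
    return centred @ centred.T / (counts.shape[1] - 1)


def _delta_from_cov(cov: np.ndarray) -> float:
    iu = np.triu_indices(cov.shape[0], k=1)
    off = cov[iu]
    mean_var = float(np.mean(np.diag(cov)))
    return float(np.std(off) / mean_var)


def count_covariance_stats(
    matrix: SpikeCountMatrix, jackknife: bool = True
) -> dict:
    """Pairwise covariance statistics of the spike-count matrix.

    Returns the off-diagonal covariances, their mean ``mu`` and SD
    ``sigma``, the mean single-neuron variance, the normalised width
    ``Delta = sigma / mean(c_ii)``, and the correlations (neurons with zero
    variance are excluded from correlations but kept in covariances).  A
    jackknife-over-windows bias estimate of ``Delta`` is reported alongside
    the naive value; it is a labelled surrogate for the full bias
    correction, not the canonical formula.
    """
    counts = matrix.counts.astype(np.float64)
    n_neurons, n_sub = counts.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subsets")
    cov = _unbiased_cov(counts)
    var = np.diag(cov).copy()
    iu = np.triu_indices(n_neurons, k=1)
    off = cov[iu]
    zero_var = np.flatnonzero(var == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        corr_mat = np.where(denom > 0, cov / denom, np.nan)
    corr = corr_mat[iu]
    corr = corr[np.isfinite(corr)]
    mean_var = float(var.mean())
    delta = _delta_from_cov(cov)
    delta_jack = None
    if jackknife and n_sub > 2:
        deltas = np.empty(n_sub)
        for p in range(n_sub):
            sub = np.delete(counts, p, axis=1)
            deltas[p] = _delta_from_cov(_unbiased_cov(sub))
        bias = (n_sub - 1) * (deltas.mean() - delta)
        delta_jack = float(delta - bias)
    return {
        "cov": off,
        "var": var,
        "corr": corr,
        "zero_variance_neurons": zero_var,
        "mean_cov": float(off.mean()),
        "width_cov": float(off.std()),
        "mean_var": mean_var,
        "Delta": delta,
        "Delta_jackknife": delta_jack,
    }


def participation_ratio(
    matrix: Union[SpikeCountMatrix, np.ndarray]
) -> Tuple[np.ndarray, float, np.ndarray]:
    """PCA explained-variance ratios, participation ratio, loadings.

    Neurons are the variables and windows the observations; counts are
    mean-centred per neuron but not variance-scaled.  Returns
    ``(evr, N_eff, loadings)`` with ``N_eff = 1 / sum(evr**2)``.
    """
    counts = matrix.counts if isinstance(matrix, SpikeCountMatrix) else np.asarray(matrix)
    counts = counts.astype(np.float64)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 neurons and 2 subsets")
    centred = counts - counts.mean(axis=1, keepdims=True)
    if not centred.any():
        raise ValueError("degenerate all-constant matrix")
    # SVD of the centred data gives the PCA spectrum directly
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    lam = s**2
    evr = lam / lam.sum()
    n_eff = float(1.0 / np.sum(evr**2))
    loadings = u.T  # (n_components, n_neurons)
    return evr, n_eff, loadings


def lambda_max(Delta: float, network_size: int = DEFAULT_NETWORK_SIZE) -> float:
    """Largest eigenvalue of the implied connectivity: 1 - 1/(1 + N Delta^2)."""
    if Delta < 0:
        raise ValueError("Delta must be >= 0")
    if network_size < 1:
        raise ValueError("network_size must be >= 1")
    return float(1.0 - 1.0 / (1.0 + network_size * Delta**2))


def population_stats(
    raster: SpikeRaster,
    window: str = "fixed_seconds",
    width: float = 2.0,
    tau: Optional[float] = None,
    network_size: int = DEFAULT_NETWORK_SIZE,
) -> PopulationStats:
    """Full population-statistics summary for one raster."""
    matrix = spike_count_matrix(raster, window=window, width=width, tau=tau)
    covstats = count_covariance_stats(matrix)
    evr, n_eff, loadings = participation_ratio(matrix)
    return PopulationStats(
        cov=covstats["cov"],
        var=covstats["var"],
        corr=covstats["corr"],
        zero_variance_neurons=covstats["zero_variance_neurons"],
        mean_cov=covstats["mean_cov"],
        width_cov=covstats["width_cov"],
        mean_var=covstats["mean_var"],
        Delta=covstats["Delta"],
        Delta_jackknife=covstats["Delta_jackknife"],
        evr=evr,
        N_eff=n_eff,
        lambda_max=lambda_max(covstats["Delta"], network_size),
        loadings=loadings,
    )
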