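"""Neuronal-avalanche extraction and scaling analysis.

An avalanche is a maximal run of consecutive time bins with nonzero
population activity, bounded by silent (zero) bins.  Its size ``S`` is the
total spike count over the run and its duration ``T`` the number of bins.
Criticality predicts power laws ``f(S) ~ S^-tau_S``, ``f(T) ~ T^-alpha``,
``<S>(T) ~ T^beta``, and mean temporal profiles that collapse onto a
universal shape under ``s(t,T) * T^-gamma``, with the crackling-noise
consistency relation ``gamma = beta - 1``.

Distribution fitting follows the standard discrete maximum-likelihood
approach: the power-law exponent maximises the zeta-function likelihood
above a lower cutoff ``xmin`` (chosen, when unset, by minimising the
Kolmogorov–Smirnov distance), and the power law is compared against a
discrete exponential via a Vuong-style normalised log-likelihood-ratio test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

from .raster import ActivitySeries

__all__ = [
    "AvalancheSet",
    "PowerLawFit",
    "ModelComparison",
    "extract_avalanches",
    "fit_power_law",
    "compare_power_law_exponential",
    "fit_size_given_duration",
    "shape_collapse",
    "crackling_residual",
    "sample_discrete_power_law",
]


@dataclass
class AvalancheSet:
    """Sizes, durations and per-avalanche temporal profiles.

    ``edge_truncated`` marks runs touching the first or last bin of the
    recording; these are censored (their true extent is unknown) and are
    excluded from distribution fits by default.  ``no_silent_bins`` is set
    when the series never goes quiet, so no avalanche can be delimited.
    """

    sizes: np.ndarray
    durations: np.ndarray
    profiles: List[np.ndarray]
    dt: float
    edge_truncated: np.ndarray
    no_silent_bins: bool = False

    def __len__(self) -> int:
        return self.sizes.size

    def interior(self) -> "AvalancheSet":
        """The subset not touching the recording edges."""
        keep = ~self.edge_truncated
        return AvalancheSet(
            sizes=self.sizes[keep],
            durations=self.durations[keep],
            profiles=[p for p, k in zip(self.profiles, keep) if k],
            dt=self.dt,
            edge_truncated=self.edge_truncated[keep],
            no_silent_bins=self.no_silent_bins,
        )


def extract_avalanches(series: ActivitySeries) -> AvalancheSet:
    """Split the activity series into avalanches at silent bins."""
    a = series.values
    n = a.size
    active = a > 0
    if not active.any():
        return AvalancheSet(
            sizes=np.empty(0, dtype=np.int64),
            durations=np.empty(0, dtype=np.int64),
            profiles=[], dt=series.dt,
            edge_truncated=np.empty(0, dtype=bool),
        )
    no_silent = bool(active.all())
    if no_silent:
        warnings.warn(
            "series has no silent bins; no avalanche can be delimited "
            "(time binning may be too coarse)", stacklevel=2,
        )
        return AvalancheSet(
            sizes=np.empty(0, dtype=np.int64),
            durations=np.empty(0, dtype=np.int64),
            profiles=[], dt=series.dt,
            edge_truncated=np.empty(0, dtype=bool),
            no_silent_bins=True,
        )
    padded = np.concatenate([[False], active, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    sizes, durations, profiles, edge = [], [], [], []
    for s, e in zip(starts, ends):
        prof = a[s:e].astype(np.int64)
        profiles.append(prof)
        sizes.append(int(prof.sum()))
        durations.append(e - s)
        edge.append(s == 0 or e == n)
    return AvalancheSet(
        sizes=np.asarray(sizes, dtype=np.int64),
        durations=np.asarray(durations, dtype=np.int64),
        profiles=profiles, dt=series.dt,
        edge_truncated=np.asarray(edge, dtype=bool),
    )


# --------------------------------------------------------------------------
# discrete power-law machinery


@dataclass
class PowerLawFit:
    exponent: float
    xmin: int
    loglik: float
    n_tail: int
    ks_distance: float
    xmin_selected: bool  # True when xmin was chosen by KS minimisation


@dataclass
class ModelComparison:
    lr_statistic: float  # normalised Vuong statistic
    lr_p: float
    favored: str  # "power_law" | "exponential" | "none"
    raw_loglik_ratio: float


def _powerlaw_loglik(values: np.ndarray, alpha: float, xmin: int) -> float:
    return float(-alpha * np.sum(np.log(values)) - values.size * math.log(special.zeta(alpha, xmin)))


def _fit_alpha(values: np.ndarray, xmin: int) -> float:
    """Discrete MLE of the power-law exponent above xmin."""
    log_sum = float(np.sum(np.log(values)))
    n = values.size

    def neg_ll(alpha: float) -> float:
        return alpha * log_sum + n * math.log(special.zeta(alpha, xmin))

    res = optimize.minimize_scalar(neg_ll, bounds=(1.0 + 1e-6, 8.0), method="bounded",
                                   options={"xatol": 1e-9})
    return float(res.x)


def _powerlaw_cdf(x: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    """P(X <= x) for the discrete power law on {xmin, xmin+1, ...}."""
    z0 = special.zeta(alpha, xmin)
    return 1.0 - special.zeta(alpha, np.asarray(x, dtype=np.float64) + 1.0) / z0


def _ks_distance(values: np.ndarray, alpha: float, xmin: int) -> float:
    tail = np.sort(values[values >= xmin])
    n = tail.size
    uniq, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / n
    model = _powerlaw_cdf(uniq, alpha, xmin)
    ecdf_lo = np.concatenate([[0.0], ecdf[:-1]])
    return float(np.max(np.maximum(np.abs(ecdf - model), np.abs(ecdf_lo - model))))


def fit_power_law(values: Sequence[int], xmin: Optional[int] = None) -> PowerLawFit:
    """Discrete power-law MLE, with KS-minimising xmin when unset."""
    values = np.asarray(values, dtype=np.int64)
    if values.size and values.min() < 1:
        raise ValueError("values must be positive integers")
    if np.unique(values).size < 2:
        raise ValueError("degenerate sample: all values identical")

    if xmin is not None:
        tail = values[values >= xmin]
        if tail.size < 10:
            raise ValueError("too few values above xmin (need >= 10)")
        alpha = _fit_alpha(tail, xmin)
        return PowerLawFit(
            exponent=alpha, xmin=int(xmin),
            loglik=_powerlaw_loglik(tail, alpha, xmin),
            n_tail=tail.size, ks_distance=_ks_distance(tail, alpha, xmin),
            xmin_selected=False,
        )

    candidates = np.unique(values)
    best: Optional[PowerLawFit] = None
    for xm in candidates:
        tail = values[values >= xm]
        if tail.size < 10 or np.unique(tail).size < 2:
            continue
        alpha = _fit_alpha(tail, int(xm))
        ks = _ks_distance(tail, alpha, int(xm))
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(
                exponent=alpha, xmin=int(xm),
                loglik=_powerlaw_loglik(tail, alpha, int(xm)),
                n_tail=tail.size, ks_distance=ks, xmin_selected=True,
            )
    if best is None:
        raise ValueError("too few values for any candidate xmin")
    return best


def _exponential_loglik_pointwise(values: np.ndarray, xmin: int) -> np.ndarray:
    """Pointwise log-likelihood of the discrete exponential above xmin.

    Model: P(x) = (1 - e^-lam) * e^{-lam (x - xmin)}, x = xmin, xmin+1, ...
    MLE: lam = ln(1 + 1/(mean(x) - xmin)).
    """
    mean_excess = float(values.mean()) - xmin
    if mean_excess <= 0:
        # all mass at xmin: degenerate limit, likelihood -> 0 per point
        return np.zeros(values.size)
    lam = math.log(1.0 + 1.0 / mean_excess)
    return math.log(1.0 - math.exp(-lam)) - lam * (values - xmin)


def compare_power_law_exponential(
    values: Sequence[int], xmin: Optional[int] = None, p_threshold: float = 0.1
) -> ModelComparison:
    """Vuong-style normalised log-likelihood-ratio test, power law vs exponential.

    ``favored`` is ``power_law`` only when the ratio is positive and the
    two-sided p-value is at or below ``p_threshold`` (default 0.1); the
    mirror-image rule favours the exponential; otherwise neither model is
    favored.
    """
    fit = fit_power_law(values, xmin=xmin)
    values = np.asarray(values, dtype=np.int64)
    tail = values[values >= fit.xmin]
    ll_pl = -fit.exponent * np.log(tail) - math.log(special.zeta(fit.exponent, fit.xmin))
    ll_exp = _exponential_loglik_pointwise(tail, fit.xmin)
    diff = ll_pl - ll_exp
    ratio = float(diff.sum())
    n = diff.size
    sd = float(diff.std())
    if sd == 0 or ratio == 0:
        return ModelComparison(lr_statistic=0.0, lr_p=1.0, favored="none",
                               raw_loglik_ratio=ratio)
    stat = ratio / (sd * math.sqrt(n))
    p = 2.0 * float(stats.norm.sf(abs(stat)))
    if ratio > 0 and p <= p_threshold:
        favored = "power_law"
    elif ratio < 0 and p <= p_threshold:
        favored = "exponential"
    else:
        favored = "none"
    return ModelComparison(lr_statistic=float(stat), lr_p=p, favored=favored,
                           raw_loglik_ratio=ratio)


def sample_discrete_power_law(
    alpha: float, n: int, xmin: int = 1, seed: int = 0
) -> np.ndarray:
    """Exact inverse-CDF sampler for the discrete power law p(x) ~ x^-alpha.

    Uses vectorised bisection on the zeta-function survival curve, so the
    sample follows the target distribution without tail truncation.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    z0 = special.zeta(alpha, xmin)
    # survival S(x) = P(X >= x) = zeta(alpha, x) / z0; find smallest x with
    # S(x+1) < u  <=>  CDF(x) >= 1-u
    lo = np.full(n, xmin, dtype=np.float64)
    hi = np.full(n, xmin + 1.0)
    while True:
        surv_hi = special.zeta(alpha, hi + 1.0) / z0
        grow = surv_hi >= u
        if not grow.any():
            break
        hi[grow] = hi[grow] * 2
    for _ in range(64):
        mid = np.floor((lo + hi) / 2)
        surv = special.zeta(alpha, mid + 1.0) / z0
        take_hi = surv >= u  # x must be > mid
        lo = np.where(take_hi, mid + 1, lo)
        hi = np.where(take_hi, hi, mid)
        if np.all(lo >= hi):
            break
    return lo.astype(np.int64)


# --------------------------------------------------------------------------
# <S>(T) scaling and shape collapse


def fit_size_given_duration(av: AvalancheSet, use_interior: bool = True) -> Tuple[float, float, float]:
    """OLS slope beta of log<S>(T) against log T over distinct durations.

    Returns (beta, intercept, r_squared).
    """
    sub = av.interior() if use_interior else av
    if len(sub) == 0:
        raise ValueError("no avalanches")
    durs = np.unique(sub.durations)
    if durs.size < 2:
        raise ValueError("need at least 2 distinct durations")
    mean_s = np.array([sub.sizes[sub.durations == d].mean() for d in durs])
    x = np.log(durs.astype(np.float64))
    y = np.log(mean_s)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _mean_profiles(
    av: AvalancheSet, min_duration: int, min_count: int
) -> Tuple[np.ndarray, List[np.ndarray]]:
    keep_durs = []
    means = []
    for d in np.unique(av.durations):
        if d < min_duration:
            continue
        group = [p for p, dd in zip(av.profiles, av.durations) if dd == d]
        if len(group) < min_count:
            continue
        keep_durs.append(int(d))
        means.append(np.mean(np.stack(group), axis=0))
    return np.asarray(keep_durs), means


def shape_collapse(
    av: AvalancheSet,
    min_duration: int = 5,
    min_count: int = 3,
    n_interp: int = 1000,
    gamma_range: Tuple[float, float] = (0.0, 5.0),
    use_interior: bool = True,
) -> Tuple[float, float, dict]:
    """Collapse mean avalanche profiles onto a universal shape.

    Procedure: drop avalanches shorter than ``min_duration`` bins and
    durations represented by fewer than ``min_count`` avalanches; average
    the profiles of each remaining duration; rescale each mean profile's
    time axis to [0, 1] (a T-bin profile sits on t/(T-1), endpoints
    included) and linearly interpolate at ``n_interp`` points; then search
    gamma so that profiles scaled by ``T**-gamma`` coincide.  The collapse
    error is the mean over interpolation points of the across-duration
    variance, divided by the squared span (max minus min over all scaled
    profiles and points).  The search is a coarse-to-fine grid over
    ``gamma_range``: steps of 0.1, then 0.01 around the optimum, then 0.001.

    Returns ``(gamma, collapse_error, details)`` where ``details`` carries
    the durations used and the interpolated mean profiles.
    """
    sub = av.interior() if use_interior else av
    durs, means = _mean_profiles(sub, min_duration, min_count)
    if durs.size < 2:
        raise ValueError("fewer than 2 distinct durations survive the exclusions")
    grid_x = np.linspace(0.0, 1.0, n_interp)
    interp = np.stack([
        np.interp(grid_x, np.linspace(0.0, 1.0, prof.size), prof) for prof in means
    ])  # (n_durations, n_interp)
    log_t = np.log(durs.astype(np.float64))

    def error(gamma: float) -> float:
        scaled = interp * np.exp(-gamma * log_t)[:, None]
        span = float(scaled.max() - scaled.min())
        if span == 0:
            return 0.0
        var = scaled.var(axis=0, ddof=0)
        return float(var.mean() / span**2)

    lo, hi = gamma_range
    best = None
    for step in (0.1, 0.01, 0.001):
        gammas = np.arange(lo, hi + step / 2, step)
        errs = [error(g) for g in gammas]
        i = int(np.argmin(errs))
        best = (float(gammas[i]), float(errs[i]))
        lo = max(gamma_range[0], gammas[i] - step)
        hi = min(gamma_range[1], gammas[i] + step)
    gamma, err = best
    details = {"durations": durs, "profiles": interp, "grid_x": grid_x}
    return gamma, err, details


def crackling_residual(beta: float, gamma: float) -> float:
    """Departure from the crackling-noise relation: gamma - (beta - 1)."""
    if not (math.isfinite(beta) and math.isfinite(gamma)):
        raise ValueError("beta and gamma must be finite")
    return float(gamma - (beta - 1.0))
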