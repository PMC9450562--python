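"""Spike-raster data model and I/O.

The universal input of the package is a :class:`SpikeRaster`: a matrix of
non-negative integer spike counts (rows = neurons, columns = time bins) with
a known bin width ``dt`` in seconds.  Population-level analyses operate on
the :class:`ActivitySeries` obtained by summing the raster across neurons.

Rasters are stored on disk either as delimited text (comma, tab or
whitespace separated; ``#``-prefixed header lines carry metadata such as
``dt``) or as NumPy ``.npy`` dense matrices.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "SpikeRaster",
    "ActivitySeries",
    "load_raster",
    "write_raster",
    "population_activity",
    "temporal_coarsen",
    "firing_rate_stats",
    "FiringRateStats",
]

_INT_TOL = 1e-9


def _as_count_array(values, ndim: int) -> np.ndarray:
    """Coerce to a non-negative integer array, rejecting bad entries.

    Floating-point entries within 1e-9 of an integer are rounded; anything
    further away, and any negative value, is rejected.
    """
    arr = np.asarray(values)
    if arr.ndim != ndim:
        raise ValueError(f"expected a {ndim}-D array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty array")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric entries")
    if np.issubdtype(arr.dtype, np.integer):
        # fast path: no float copy for large simulated rasters
        if arr.min() < 0:
            raise ValueError("negative count")
        return arr.astype(np.int64, copy=False)
    arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite entries")
    rounded = np.rint(arr)
    if np.max(np.abs(arr - rounded)) > _INT_TOL:
        raise ValueError("non-integer spike counts")
    if np.any(rounded < 0):
        raise ValueError("negative count")
    return rounded.astype(np.int64)


@dataclass
class SpikeRaster:
    """Per-neuron, per-bin spike counts.

    Parameters
    ----------
    counts
        Integer matrix, rows = neurons, columns = time bins; entries >= 0.
    dt
        Bin width in seconds (> 0).
    neuron_ids
        Optional unique labels, one per row.
    meta
        Free-form provenance record (source file, seed, ...).
    """

    counts: np.ndarray
    dt: float
    neuron_ids: Optional[Sequence[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = _as_count_array(self.counts, 2)
        if not (float(self.dt) > 0):
            raise ValueError("dt must be > 0")
        self.dt = float(self.dt)
        if self.counts.shape[1] < 2:
            raise ValueError("raster needs at least 2 time bins")
        if self.neuron_ids is not None:
            ids = list(self.neuron_ids)
            if len(ids) != self.counts.shape[0]:
                raise ValueError("neuron_ids length must match row count")
            if len(set(ids)) != len(ids):
                raise ValueError("neuron_ids must be unique")
            self.neuron_ids = ids

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_bins * self.dt


@dataclass
class ActivitySeries:
    """Population-summed activity :math:`A_t` per time bin."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = _as_count_array(self.values, 1)
        if not (float(self.dt) > 0):
            raise ValueError("dt must be > 0")
        self.dt = float(self.dt)
        if self.values.size < 2:
            raise ValueError("series needs at least 2 bins")

    @property
    def n_bins(self) -> int:
        return self.values.size


def _sniff_delimiter(path: str) -> Optional[str]:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if "," in line:
                return ","
            if "\t" in line:
                return "\t"
            return None  # whitespace
    return None


def _read_header_meta(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def load_raster(
    path: Union[str, os.PathLike],
    format: str = "delimited",
    dt: Optional[float] = None,
    transpose: bool = False,
    neuron_ids: Optional[Sequence[str]] = None,
) -> SpikeRaster:
    """Read a spike raster from disk.

    ``format="delimited"`` reads comma/tab/whitespace separated text
    (delimiter auto-sniffed); ``format="dense"`` reads a NumPy ``.npy``
    matrix.  Rows are neurons unless ``transpose`` is set.  If ``dt`` is not
    given, a ``# dt: <seconds>`` header line in the delimited file is used.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta = {"source": path}
    if format == "delimited":
        header = _read_header_meta(path)
        if dt is None and "dt" in header:
            dt = float(header["dt"])
        arr = np.loadtxt(path, delimiter=_sniff_delimiter(path), comments="#", ndmin=2)
    elif format == "dense":
        arr = np.load(path, allow_pickle=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    if dt is None:
        raise ValueError("dt not given and not found in file header")
    if transpose:
        arr = arr.T
    return SpikeRaster(counts=arr, dt=dt, neuron_ids=neuron_ids, meta=meta)


def write_raster(raster: SpikeRaster, path: Union[str, os.PathLike], delimiter: str = ",") -> None:
    """Write a raster as delimited text with a ``# dt:`` metadata header."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write(f"# dt: {raster.dt!r}\n")
        if raster.neuron_ids is not None:
            fh.write(f"# neuron_ids: {json.dumps(list(raster.neuron_ids))}\n")
        np.savetxt(fh, raster.counts, fmt="%d", delimiter=delimiter)


def population_activity(raster: SpikeRaster) -> ActivitySeries:
    """Sum spike counts across neurons, giving the population activity A_t."""
    return ActivitySeries(values=raster.counts.sum(axis=0), dt=raster.dt)


def _coarsen_values(values: np.ndarray, factor: int, mode: str, axis: int) -> np.ndarray:
    n = values.shape[axis]
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > n:
        raise ValueError("factor exceeds series length")
    n_blocks = n // factor
    sl = [slice(None)] * values.ndim
    sl[axis] = slice(0, n_blocks * factor)
    trimmed = values[tuple(sl)]
    if mode == "skip":
        sl[axis] = slice(factor - 1, None, factor)
        return trimmed[tuple(sl)]
    if mode == "sum":
        new_shape = list(trimmed.shape)
        new_shape[axis : axis + 1] = [n_blocks, factor]
        return trimmed.reshape(new_shape).sum(axis=axis + 1)
    raise ValueError(f"unknown mode {mode!r}")


def temporal_coarsen(
    x: Union[SpikeRaster, ActivitySeries], factor: int, mode: str = "sum"
) -> Union[SpikeRaster, ActivitySeries]:
    """Coarse-grain time by ``factor`` consecutive bins.

    ``mode="sum"`` sums each block of ``factor`` bins (temporal summation,
    what slow calcium indicators effectively do); ``mode="skip"`` keeps the
    last bin of each block and discards the rest (temporal subsampling).
    The trailing incomplete block is dropped and ``dt`` is multiplied by
    ``factor``.
    """
    factor = int(factor)
    if isinstance(x, SpikeRaster):
        vals = _coarsen_values(x.counts, factor, mode, axis=1)
        return SpikeRaster(counts=vals, dt=x.dt * factor, neuron_ids=x.neuron_ids, meta=dict(x.meta))
    if isinstance(x, ActivitySeries):
        vals = _coarsen_values(x.values, factor, mode, axis=0)
        return ActivitySeries(values=vals, dt=x.dt * factor)
    raise TypeError("expected SpikeRaster or ActivitySeries")


@dataclass
class FiringRateStats:
    """Per-neuron firing rates (spikes/s) with population mean and SD."""

    rates: np.ndarray
    mean: float
    sd: float


def firing_rate_stats(raster: SpikeRaster) -> FiringRateStats:
    """Per-neuron average firing rate and its population mean/SD."""
    rates = raster.counts.sum(axis=1) / (raster.n_bins * raster.dt)
    return FiringRateStats(rates=rates, mean=float(np.mean(rates)), sd=float(np.std(rates)))
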