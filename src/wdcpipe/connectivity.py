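"""Voxelwise weighted degree centrality (wDC) from z-scored BOLD time series.

For a voxel time series ``a`` and all other in-mask voxel series ``b_i``,

    wDC(a) = sum_i S_C(a, b_i) * 1[S_C(a, b_i) > threshold]

where ``S_C`` is the cosine similarity ``a.b / (|a| |b|)``.  On z-scored
(mean 0, sd 1) series the cosine similarity equals Pearson's correlation
coefficient, so wDC is the thresholded row sum of the voxelwise correlation
matrix, self-connections excluded.  Sub-threshold similarities contribute
zero (they are removed, not clipped): the graph is weighted, not binarized,
and the default threshold 0.25 is strict and one-sided, discarding weak and
negative correlations as likely noise.

The similarity matrix is never materialised in full: it is processed in
column blocks so memory stays bounded while the result is numerically
identical to the full-matrix formula.  All standard deviations here are
sample sds (ddof=1); cosine similarity is invariant to that choice, map
z-scores are not, so the convention is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, DegenerateMapError, DegenerateSeriesError
from .image_io import MaskVolume, VoxelGrid, write_volume

log = logging.getLogger(__name__)

WDC_THRESHOLD = 0.25
DEFAULT_CHUNK = 1024


@dataclass
class WdcMap:
    """Per-voxel wDC values over an analysis mask.

    ``values[j]`` belongs to the j-th in-mask voxel in the mask's fixed
    linear order.  Before standardization values are in arbitrary
    summed-similarity units; after, unitless z-scores.
    """

    mask: MaskVolume
    values: np.ndarray
    standardized: bool
    threshold: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size != self.mask.n_voxels:
            raise DegenerateInputError(
                f"{vals.size} values for a {self.mask.n_voxels}-voxel mask"
            )
        self.values = vals


def zscore_timeseries(ts: np.ndarray, strict: bool = True) -> np.ndarray:
    """Standardize each column of a T x N matrix to mean 0, sample sd 1.

    In strict mode (default) a zero-variance column raises
    :class:`DegenerateSeriesError` naming the offending voxel column; in
    permissive mode such columns are left as zeros (callers should have
    dropped them from the mask already).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise DegenerateInputError("time series must be T x N")
    t = ts.shape[0]
    if t < 3:
        raise DegenerateInputError(f"need T >= 3 time points, got {t}")
    mean = ts.mean(axis=0)
    sd = ts.std(axis=0, ddof=1)
    zero = sd <= 0
    if np.any(zero):
        if strict:
            raise DegenerateSeriesError(
                f"zero-variance time series at voxel column(s) {np.flatnonzero(zero).tolist()}"
            )
        log.warning("%d zero-variance columns set to 0", int(zero.sum()))
        sd = np.where(zero, 1.0, sd)
    return (ts - mean) / sd


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two time-series vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DegenerateInputError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateSeriesError("cosine similarity of a zero vector is undefined")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def compute_wdc(
    ts: np.ndarray,
    mask: MaskVolume | None = None,
    threshold: float = WDC_THRESHOLD,
    chunk_size: int = DEFAULT_CHUNK,
) -> WdcMap | np.ndarray:
    """Weighted degree centrality of every voxel column of a z-scored matrix.

    Parameters
    ----------
    ts : T x N matrix of z-scored series (N >= 2).
    mask : analysis mask whose linear order matches the columns; when given,
        a :class:`WdcMap` is returned, otherwise the raw length-N vector.
    threshold : similarity cutoff; pairs with S_C <= threshold contribute 0.
        Set below -1 to disable thresholding.
    chunk_size : number of columns per similarity block; the result is
        chunk-size invariant.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise DegenerateInputError("time series must be T x N")
    n = ts.shape[1]
    if n < 2:
        raise DegenerateInputError("need at least 2 voxels to define wDC")
    if mask is not None and mask.n_voxels != n:
        raise DegenerateInputError("mask voxel count does not match time-series columns")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    norms = np.linalg.norm(ts, axis=0)
    if np.any(norms == 0):
        raise DegenerateSeriesError(
            f"zero-norm series at column(s) {np.flatnonzero(norms == 0).tolist()}"
        )
    unit = ts / norms
    wdc = np.empty(n)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = unit[:, start:stop].T @ unit  # (stop-start) x N similarities
        np.clip(block, -1.0, 1.0, out=block)
        rows = np.arange(stop - start)
        block[rows, start + rows] = 0.0  # self-connections excluded
        wdc[start:stop] = np.where(block > threshold, block, 0.0).sum(axis=1)
    if mask is None:
        return wdc
    return WdcMap(mask=mask, values=wdc, standardized=False, threshold=threshold)


def zscore_map(wdc_map: WdcMap) -> WdcMap:
    """Standardize a wDC map to mean 0, sample sd 1 across in-mask voxels."""
    vals = wdc_map.values
    if vals.size < 2:
        raise DegenerateMapError("need at least 2 voxels to standardize a map")
    sd = float(np.std(vals, ddof=1))
    if sd <= 0:
        raise DegenerateMapError("wDC map has zero spread; cannot standardize")
    z = (vals - vals.mean()) / sd
    return replace(wdc_map, values=z, standardized=True)


def write_wdc_map(path: str | Path, wdc_map: WdcMap) -> None:
    """Scatter a wDC map back onto its 3D grid (out-of-mask voxels NaN) and
    write it as NIfTI-1 with a plain-text sidecar (threshold, N)."""
    grid: VoxelGrid = wdc_map.mask.grid
    vol = np.full(grid.n_voxels, np.nan)
    vol[wdc_map.mask.linear_indices()] = wdc_map.values
    write_volume(path, grid, vol.reshape(grid.shape, order="F"))
    sidecar = Path(path).with_suffix("").with_suffix("")  # strip .nii / .nii.gz
    sidecar = sidecar.parent / (sidecar.name + "_wdc.txt")
    sidecar.write_text(
        f"threshold\t{wdc_map.threshold}\n"
        f"n_voxels\t{wdc_map.mask.n_voxels}\n"
        f"standardized\t{wdc_map.standardized}\n"
    )
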