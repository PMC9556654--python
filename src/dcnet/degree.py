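"""Voxel-wise binarized degree centrality (DC).

For every in-mask voxel the Pearson correlation with every other in-mask
voxel is computed, binarized at ``r > threshold_r`` (strict; negative
correlations are discarded, not folded in by absolute value), and the
suprathreshold connections counted.  The count map is z-scored within
the mask and optionally smoothed.

The correlation matrix over a whole-brain gray-matter mask (~5e4 voxels
at 3 mm) is too large to materialize, so time series are variance-
normalized once and correlation blocks are streamed in row chunks of
``chunk_size``; the result is independent of the chunking.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import BoldSeries, DCMap, VolumeMask
from .preprocess import smooth_volume

__all__ = ["voxelwise_degree", "standardize_dc", "dc_pipeline", "drop_zero_variance"]

log = logging.getLogger(__name__)


def _standardized_series(series: BoldSeries, mask: VolumeMask) -> np.ndarray:
    """In-mask series as a (V, t) matrix with zero mean and unit norm per
    row, so that X @ X.T is the Pearson correlation matrix."""
    X = series.data[mask.data]  # V x t
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return X / norms


def drop_zero_variance(series: BoldSeries, mask: VolumeMask) -> VolumeMask:
    """Return the mask with zero-temporal-variance voxels removed
    (logged); correlations are undefined for constant series."""
    X = series.data[mask.data]
    sd = X.std(axis=1)
    bad = sd == 0
    if not bad.any():
        return mask
    log.warning("dropping %d zero-variance voxel(s) from mask for %s",
                int(bad.sum()), series.subject_id)
    new = mask.data.copy()
    idx = np.argwhere(mask.data)
    new[tuple(idx[bad].T)] = False
    return mask.with_data(new)


def voxelwise_degree(
    series: BoldSeries,
    mask: VolumeMask,
    threshold_r: float = 0.25,
    chunk_size: int = 2048,
    weighted: bool = False,
) -> np.ndarray:
    """Binarized (or Fisher-weighted) degree per in-mask voxel.

    degree(i) = #{ j != i in mask : pearson(x_i, x_j) > threshold_r };
    in weighted mode the count is replaced by ``sum atanh(r_ij)`` over the
    same suprathreshold edges.  Returns a 3D map (0 outside the mask),
    integer-valued in binarized mode.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if not -1.0 < threshold_r < 1.0:
        raise ValueError("threshold_r must lie in (-1, 1)")
    if series.spatial_shape != mask.data.shape:
        raise ValueError("mask shape does not match BOLD grid")
    mask = drop_zero_variance(series, mask)
    n_vox = mask.n_voxels
    if n_vox < 2:
        raise ValueError("need at least 2 in-mask voxels with nonzero variance")

    X = _standardized_series(series, mask)
    dtype = float if weighted else np.int64
    degree = np.zeros(n_vox, dtype=dtype)
    for start in range(0, n_vox, chunk_size):
        stop = min(start + chunk_size, n_vox)
        block = np.clip(X[start:stop] @ X.T, -1.0, 1.0)  # rows x V
        supra = block > threshold_r
        # exclude the self-correlation (always 1 > threshold_r)
        rows = np.arange(start, stop)
        supra[np.arange(stop - start), rows] = False
        if weighted:
            # clamp below 1 to keep atanh finite for duplicated series
            w = np.arctanh(np.minimum(block, 1.0 - 1e-12))
            degree[start:stop] = np.where(supra, w, 0.0).sum(axis=1)
        else:
            degree[start:stop] = supra.sum(axis=1)

    out_dtype = float if weighted else np.int64
    out = np.zeros(mask.data.shape, dtype=out_dtype)
    out[mask.data] = degree
    return out


def standardize_dc(raw_degree: np.ndarray, mask: VolumeMask) -> np.ndarray:
    """Z-score the degree map within the mask: Z(i) = (d_i - mean)/sd.

    Voxels outside the mask are set to 0 in the returned map.
    """
    vals = np.asarray(raw_degree, dtype=float)[mask.data]
    sd = vals.std()
    if sd == 0:
        raise ValueError("degree map is constant within the mask; cannot z-score")
    out = np.zeros(mask.data.shape)
    out[mask.data] = (vals - vals.mean()) / sd
    return out


def dc_pipeline(
    series: BoldSeries,
    mask: VolumeMask,
    threshold_r: float = 0.25,
    smooth_fwhm_mm: float = 6.0,
    method: str = "zscore",
    chunk_size: int = 2048,
) -> DCMap:
    """Full per-subject DC chain: degree -> z-standardize -> smooth.

    ``method`` selects the degree definition that is standardized:
    ``zscore`` (default) z-scores the binarized count; ``fisher_weighted``
    z-scores the sum of Fisher r-to-z transformed suprathreshold weights.
    Smoothing (6 mm FWHM default) is applied after standardization, on
    the zero-filled full grid.
    """
    if method not in ("zscore", "fisher_weighted"):
        raise ValueError(f"unknown standardization method {method!r}")
    mask = drop_zero_variance(series, mask)
    raw = voxelwise_degree(series, mask, threshold_r, chunk_size,
                           weighted=(method == "fisher_weighted"))
    z = standardize_dc(raw, mask)
    if smooth_fwhm_mm > 0:
        z, _ = smooth_volume((z, series.affine), smooth_fwhm_mm)
    return DCMap(
        raw_degree=raw,
        standardized=z,
        threshold_r=threshold_r,
        mask_label=mask.label,
        subject_id=series.subject_id,
        method=method,
        smooth_fwhm_mm=smooth_fwhm_mm,
    )
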