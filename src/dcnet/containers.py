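"""Core in-memory containers shared across pipeline stages.

The pipeline passes four kinds of objects between stages: 4D BOLD series,
3D boolean masks, per-subject motion traces, and per-subject degree
centrality (DC) maps.  All of them are thin dataclasses around numpy
arrays plus the metadata (affine, TR, subject id) needed to write valid
NIfTI-1 output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BoldSeries",
    "VolumeMask",
    "MotionTrace",
    "DCMap",
    "StatMap",
    "voxel_sizes_mm",
]


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge length in mm from a 4x4 affine (column norms)."""
    return np.sqrt((np.asarray(affine, dtype=float)[:3, :3] ** 2).sum(axis=0))


@dataclass
class BoldSeries:
    """One subject's 4D BOLD data (x, y, z, t) with its affine and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in BOLD data for subject {self.subject_id!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=data)


@dataclass
class VolumeMask:
    """Boolean 3D mask defining an analysis domain on the BOLD grid."""

    data: np.ndarray
    label: str = "brain"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "VolumeMask":
        return replace(self, data=data)


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: t rows x 6 columns.

    Columns are translations (mm) along x, y, z then rotations (degrees)
    about x, y, z.  ``aligned_to`` declares whether the rows match the raw
    acquisition or the series after initial-volume discarding.
    """

    params: np.ndarray
    subject_id: str = ""
    aligned_to: str = "raw"

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=np.float64))
        if self.params.shape[1] != 6:
            raise ValueError("motion trace must have 6 columns (3 translations mm, 3 rotations deg)")
        if self.params.shape[0] < 1:
            raise ValueError("motion trace must be nonempty")
        if self.aligned_to not in ("raw", "discarded"):
            raise ValueError("aligned_to must be 'raw' or 'discarded'")

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class DCMap:
    """Per-subject voxel-wise degree-centrality map.

    ``raw_degree`` counts suprathreshold connections per in-mask voxel
    (binarized mode) or sums Fisher-transformed suprathreshold correlation
    weights (weighted mode).  ``standardized`` is the z-scored (and
    optionally smoothed) map; voxels outside the mask are 0.
    """

    raw_degree: np.ndarray
    standardized: np.ndarray | None
    threshold_r: float
    mask_label: str = "gray_matter"
    subject_id: str = ""
    method: str = "zscore"
    smooth_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        self.raw_degree = np.asarray(self.raw_degree)
        if self.raw_degree.ndim != 3:
            raise ValueError("raw_degree must be 3D")
        if not -1.0 < self.threshold_r < 1.0:
            raise ValueError("threshold_r must lie in (-1, 1)")


@dataclass
class StatMap:
    """Voxel-wise t-statistic map from the group GLM, plus what cluster
    inference needs: degrees of freedom, residual smoothness, resels."""

    tmap: np.ndarray
    df: int
    mask: VolumeMask
    affine: np.ndarray
    contrast_name: str = "patient-minus-control"
    residual_fwhm_mm: np.ndarray | None = None
    resel_count: float | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)  # n_subjects x n_mask_voxels

    def __post_init__(self) -> None:
        self.tmap = np.asarray(self.tmap, dtype=np.float64)
        if self.tmap.ndim != 3:
            raise ValueError("tmap must be 3D")
        if self.df < 1:
            raise ValueError("df must be >= 1")
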