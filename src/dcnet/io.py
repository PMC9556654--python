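"""Reading and writing the pipeline's on-disk formats.

Images are NIfTI-1 (via nibabel), motion traces are 6-column whitespace
text, tables are CSV, reports and sidecars are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import GroundTruth
from .containers import BoldSeries, DCMap, MotionTrace, VolumeMask

__all__ = [
    "save_bold", "load_bold", "save_mask", "load_mask",
    "save_motion_trace", "load_motion_trace",
    "save_dc_map", "load_dc_map", "save_ground_truth",
    "array_checksum", "file_checksum",
]


def array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def file_checksum(path: Path | str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def save_bold(series: BoldSeries, path: Path | str) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (series.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def load_bold(path: Path | str, subject_id: str | None = None,
              tr_seconds: float | None = None) -> BoldSeries:
    img = nib.load(str(path))
    tr = tr_seconds if tr_seconds is not None else float(img.header.get_zooms()[3])
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return BoldSeries(np.asarray(img.dataobj, dtype=np.float64), img.affine, tr, sid)


def save_mask(mask: VolumeMask, path: Path | str) -> Path:
    path = Path(path)
    affine = mask.affine if mask.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), path)
    return path


def load_mask(path: Path | str, label: str = "brain") -> VolumeMask:
    img = nib.load(str(path))
    return VolumeMask(np.asarray(img.dataobj) > 0, label=label, affine=img.affine)


def save_motion_trace(trace: MotionTrace, path: Path | str) -> Path:
    path = Path(path)
    np.savetxt(path, trace.params, fmt="%.8f")
    return path


def load_motion_trace(path: Path | str, subject_id: str = "",
                      aligned_to: str = "raw") -> MotionTrace:
    return MotionTrace(np.loadtxt(str(path)), subject_id=subject_id, aligned_to=aligned_to)


def save_dc_map(dc: DCMap, affine: np.ndarray, out_dir: Path | str,
                mask: VolumeMask | None = None) -> dict:
    """Write raw-degree and standardized NIfTIs plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = dc.subject_id or "subject"
    raw_path = out_dir / f"{stem}_degree.nii.gz"
    std_path = out_dir / f"{stem}_dcz.nii.gz"
    nib.save(nib.Nifti1Image(dc.raw_degree.astype(np.float32), affine), raw_path)
    nib.save(nib.Nifti1Image(dc.standardized.astype(np.float32), affine), std_path)
    sidecar = dict(
        subject_id=dc.subject_id,
        threshold_r=dc.threshold_r,
        method=dc.method,
        smooth_fwhm_mm=dc.smooth_fwhm_mm,
        mask_label=dc.mask_label,
        mask_checksum=array_checksum(mask.data) if mask is not None else None,
    )
    sidecar_path = out_dir / f"{stem}_dc.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return dict(raw=raw_path, standardized=std_path, sidecar=sidecar_path)


def load_dc_map(std_path: Path | str) -> DCMap:
    std_path = Path(std_path)
    stem = std_path.name.replace("_dcz.nii.gz", "")
    sidecar = json.loads((std_path.parent / f"{stem}_dc.json").read_text())
    raw = nib.load(str(std_path.parent / f"{stem}_degree.nii.gz"))
    std = nib.load(str(std_path))
    return DCMap(
        raw_degree=np.asarray(raw.dataobj, dtype=float),
        standardized=np.asarray(std.dataobj, dtype=float),
        threshold_r=sidecar["threshold_r"],
        mask_label=sidecar["mask_label"],
        subject_id=sidecar["subject_id"],
        method=sidecar["method"],
        smooth_fwhm_mm=sidecar["smooth_fwhm_mm"],
    )


def save_ground_truth(truth: GroundTruth, affine: np.ndarray, out_dir: Path | str) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nii = out_dir / "ground_truth_labels.nii.gz"
    nib.save(nib.Nifti1Image(truth.region_labels.astype(np.int16), affine), nii)
    sidecar = out_dir / "ground_truth.json"
    hubs = [dict(center=list(h.center), radius=h.radius, sign=h.sign, magnitude=h.magnitude)
            for h in truth.spec.hub_regions]
    sidecar.write_text(json.dumps(dict(
        hub_regions=hubs,
        n_effect_voxels=int(truth.effect_mask.sum()),
        seed=truth.spec.seed,
        n_per_group=truth.spec.n_per_group,
        grid_shape=list(truth.spec.grid_shape),
    ), indent=2))
    return dict(labels=nii, sidecar=sidecar)
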