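"""Run configuration: one flat YAML namespace per pipeline stage.

Every parameter defaults to the emulated protocol's value (5 discarded
volumes, 2 mm / 2 deg motion cut, 0.01-0.1 Hz band, 8 mm and 6 mm
smoothing, r > 0.25 binarization, cluster-forming voxel p < 0.01).
``load(save(cfg)) == cfg`` holds exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


def _simulate_defaults() -> dict:
    return dict(
        n_per_group=10, grid_shape=[16, 16, 16], voxel_size_mm=3.0,
        n_timepoints=60, tr_seconds=2.0, effect_magnitude=0.5,
        noise_sigma=1.0, spatial_fwhm_mm=6.0, n_bad_movers=0, seed=0,
    )


def _preprocess_defaults() -> dict:
    return dict(
        n_discard=5, motion_threshold_mm=2.0, motion_threshold_deg=2.0,
        low_hz=0.01, high_hz=0.1, smooth_fwhm_mm=8.0, use_motion_confounds=True,
    )


def _dc_defaults() -> dict:
    return dict(threshold_r=0.25, smooth_fwhm_mm=6.0, method="zscore", chunk_size=2048)


def _infer_defaults() -> dict:
    return dict(
        voxel_p=0.01, alpha=0.05, method="grf", n_perm=1000,
        connectivity=26, covariates=["age_years", "sex"],
        min_cluster_voxels=0, seed=0,
    )


def _correlate_defaults() -> dict:
    return dict(
        clinical_vars=["hrsd17", "illness_duration_months", "age_years"],
        method="pearson", correction="bonferroni", alpha=0.05,
    )


def _classify_defaults() -> dict:
    return dict(
        c_exponents=[-10, 10, 2], gamma_exponents=[-10, 10, 2],
        cv_scheme="leave_one_out", k=10, protocol="paper", seed=0,
    )


@dataclass
class RunConfig:
    simulate: dict = field(default_factory=_simulate_defaults)
    preprocess: dict = field(default_factory=_preprocess_defaults)
    dc: dict = field(default_factory=_dc_defaults)
    infer: dict = field(default_factory=_infer_defaults)
    correlate: dict = field(default_factory=_correlate_defaults)
    classify: dict = field(default_factory=_classify_defaults)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for stage in ("simulate", "preprocess", "dc", "infer", "correlate", "classify"):
            if stage in d and d[stage] is not None:
                base = getattr(cfg, stage)
                unknown = set(d[stage]) - set(base)
                if unknown:
                    raise ValueError(f"unknown keys in [{stage}]: {sorted(unknown)}")
                base.update(d[stage])
        return cfg

    def save(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def checksum(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
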