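"""Synthetic two-group resting-state fMRI cohort with known ground truth.

The generator emulates a case/control resting-state study: two groups of
subjects, each scanned with TR = 2 s for 212 volumes on a 3 mm isotropic
grid, with latent "network" time courses that make designated hub regions
highly connected, and a planted group difference in hub connectivity of
configurable sign and magnitude.

Signal model per subject ``s`` and voxel ``v``::

    bold(v, t) = offset + sum_k  L[s,k] * a_k(v) * z_k(t)  +  noise(v, t)

where ``z_k`` are unit-variance AR(1) latent time courses shared in form
(but not realization) across subjects, ``a_k(v)`` is a Gaussian-tapered
amplitude supported on network k's spherical voxel set, and ``L[s,k]`` is
a subject loading near 1.  Voxels inside a hub region belong to one of
the networks; for subjects in the patient group their amplitude is scaled
by ``(1 + sign * magnitude)``, which raises (or lowers) their Pearson
correlations with the rest of the network and hence their binarized
degree.  Noise is spatially smoothed Gaussian noise, giving the maps the
spatial autocorrelation that random-field cluster inference assumes.

With ``effect_magnitude = 0`` the two groups are exchangeable by
construction, which is what the permutation-calibration tests rely on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .containers import BoldSeries, MotionTrace, VolumeMask

__all__ = [
    "HubRegion",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_motion_trace",
    "default_hub_regions",
    "confound_masks",
]

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class HubRegion:
    """Spherical voxel set carrying a planted group difference in degree.

    ``sign`` is +1 for patient > control connectivity, -1 for the reverse;
    ``magnitude`` is the fractional change of the latent signal amplitude
    in the patient group (0 = no effect).
    """

    center: tuple[int, int, int]
    radius: float
    sign: int
    magnitude: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("hub region sign must be +1 or -1")
        if self.magnitude < 0:
            raise ValueError("hub region effect magnitude must be >= 0")
        if self.radius <= 0:
            raise ValueError("hub region radius must be positive")


def default_hub_regions(
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    magnitude: float = 0.5,
) -> list[HubRegion]:
    """Six hub regions, three with increased and three with decreased
    patient connectivity, spread over the grid interior."""
    nx, ny, nz = grid_shape
    # margins keep hubs clear of both the grid edge and the corner
    # confound cubes that the analysis mask excludes
    lo = lambda n: max(4, n // 4)
    hi = lambda n: min(n - 5, 3 * n // 4)
    mid = lambda n: n // 2
    centers = [
        (lo(nx), lo(ny), lo(nz)),
        (hi(nx), lo(ny), hi(nz)),
        (mid(nx), hi(ny), lo(nz)),
        (hi(nx), hi(ny), hi(nz)),
        (lo(nx), hi(ny), hi(nz)),
        (hi(nx), mid(ny), lo(nz)),
    ]
    signs = [1, 1, 1, -1, -1, -1]
    return [HubRegion(c, 2.25, s, magnitude) for c, s in zip(centers, signs)]


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of one synthetic cohort.

    Defaults follow the emulated acquisition: 71 subjects per group,
    212 volumes at TR = 2 s, 3 mm isotropic voxels.  The grid defaults to
    a small 16^3 volume so that whole pipelines run at desk scale; the
    physical acquisition constants are unchanged by the grid size.
    """

    n_per_group: int = 71
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 212
    tr_seconds: float = 2.0
    hub_regions: tuple[HubRegion, ...] | None = None
    n_networks: int = 5
    ar_coef: float = 0.3
    latent_band_hz: tuple[float, float] | None = (0.01, 0.1)
    signal_amplitude: float = 0.8
    noise_sigma: float = 1.0
    spatial_fwhm_mm: float = 6.0
    network_radius: float = 2.0
    loading_sd: float = 0.1
    baseline_offset: float = 100.0
    n_bad_movers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers (>= 4 per axis)")
        if self.voxel_size_mm <= 0 or self.tr_seconds <= 0:
            raise ValueError("voxel_size_mm and tr_seconds must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.spatial_fwhm_mm < 0:
            raise ValueError("spatial_fwhm_mm must be >= 0")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.hub_regions is None:
            object.__setattr__(self, "hub_regions",
                               tuple(default_hub_regions(tuple(self.grid_shape))))
        object.__setattr__(self, "hub_regions", tuple(self.hub_regions))
        for hub in self.hub_regions:
            self._check_inside(hub)

    def _check_inside(self, hub: HubRegion) -> None:
        for c, n in zip(hub.center, self.grid_shape):
            if c - hub.radius < 0 or c + hub.radius > n - 1:
                raise ValueError(
                    f"hub region at {hub.center} with radius {hub.radius} "
                    f"does not lie fully inside grid {self.grid_shape}"
                )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Which voxels carry a planted effect, and in which direction."""

    effect_mask: np.ndarray  # bool, 3D
    effect_direction: np.ndarray  # int8, 3D, +-1 inside effect_mask else 0
    region_labels: np.ndarray  # int32, 3D, 1-based hub index, 0 elsewhere
    spec: CohortSpec

    def region_mask(self, index: int) -> np.ndarray:
        """Boolean mask of hub region ``index`` (0-based)."""
        return self.region_labels == index + 1


def _sphere_mask(shape: tuple[int, int, int], center: tuple[int, int, int], radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _tapered_amplitude(shape, center, radius) -> np.ndarray:
    """Gaussian-tapered amplitude on a sphere: 1 at the center, ~0.3 at
    the boundary.  The taper spreads pairwise correlations across the
    binarization threshold so degree responds smoothly to loading."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center)).astype(float)
    sigma = radius / 1.5
    amp = np.exp(-d2 / (2.0 * sigma**2))
    amp[d2 > radius**2] = 0.0
    return amp


def _ar1_series(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) series."""
    innov_sd = np.sqrt(1.0 - phi**2) if phi > 0 else 1.0
    eps = rng.standard_normal(n) * innov_sd
    z = np.empty(n)
    z[0] = rng.standard_normal() if phi == 0 else eps[0] / np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + eps[t]
    return z


def _latent_series(n: int, phi: float, tr: float, band: tuple[float, float] | None,
                   rng: np.random.Generator) -> np.ndarray:
    """One latent network time course: AR(1) innovation structure,
    band-limited to the resting-state fluctuation band and rescaled to
    unit variance.

    Real resting-state network signals concentrate below ~0.1 Hz, which
    is why the preprocessing bandpass retains them while suppressing
    broadband noise; band-limiting the latents reproduces that property.
    """
    z = _ar1_series(n, phi, rng)
    if band is None:
        return z
    from .preprocess import _band_gain

    low, high = band
    high = min(high, 0.95 / (2.0 * tr))
    gain = _band_gain(np.fft.rfftfreq(n, d=tr), low, high)
    z = np.fft.irfft(np.fft.rfft(z) * gain, n=n)
    sd = z.std()
    return z / sd if sd > 0 else z


def confound_masks(spec: CohortSpec) -> tuple[VolumeMask, VolumeMask]:
    """Synthetic white-matter and ventricle confound-extraction masks.

    Two 3-voxel corner cubes, disjoint from the analysis mask, standing in
    for the anatomical WM / ventricle ROIs of a real study.
    """
    wm = np.zeros(spec.grid_shape, dtype=bool)
    wm[:3, :3, :3] = True
    vent = np.zeros(spec.grid_shape, dtype=bool)
    vent[-3:, -3:, -3:] = True
    aff = spec.affine
    return (
        VolumeMask(wm, label="white_matter", affine=aff),
        VolumeMask(vent, label="ventricle", affine=aff),
    )


def _analysis_mask(spec: CohortSpec) -> np.ndarray:
    mask = np.ones(spec.grid_shape, dtype=bool)
    mask[:3, :3, :3] = False  # WM corner cube
    mask[-3:, -3:, -3:] = False  # ventricle corner cube
    return mask


def _network_layout(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-latent amplitude fields (K + H, x, y, z) and hub->latent map.

    The first K latents are background networks on random spheres; each
    hub region then gets a dedicated latent of its own, so planted
    effects in different hubs do not interfere."""
    rng = np.random.default_rng([spec.seed, 1])
    shape = spec.grid_shape
    r = spec.network_radius
    n_hubs = len(spec.hub_regions)
    amps = np.zeros((spec.n_networks + n_hubs,) + tuple(shape))
    for k in range(spec.n_networks):
        center = []
        for n in shape:
            margin = min(int(np.ceil(r)) + 3, (n - 1) // 2)
            hi = n - margin
            center.append(int(rng.integers(margin, hi)) if hi > margin else n // 2)
        amps[k] += _tapered_amplitude(shape, tuple(center), r)
    hub_net = spec.n_networks + np.arange(n_hubs)
    for i, hub in enumerate(spec.hub_regions):
        amps[hub_net[i]] += _tapered_amplitude(shape, hub.center, hub.radius)
    return amps, hub_net


def _ground_truth(spec: CohortSpec) -> GroundTruth:
    shape = spec.grid_shape
    labels = np.zeros(shape, dtype=np.int32)
    direction = np.zeros(shape, dtype=np.int8)
    analysis = _analysis_mask(spec)
    for i, hub in enumerate(spec.hub_regions):
        sph = _sphere_mask(shape, hub.center, hub.radius) & analysis
        labels[sph] = i + 1
        direction[sph] = hub.sign if hub.magnitude > 0 else 0
    effect = direction != 0
    return GroundTruth(effect_mask=effect, effect_direction=direction, region_labels=labels, spec=spec)


def _smooth_noise(shape, n_t, sigma_vox, noise_sigma, rng) -> np.ndarray:
    noise = rng.standard_normal(tuple(shape) + (n_t,))
    if sigma_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0.0,), mode="reflect")
        noise *= noise_sigma / noise.std()
    else:
        noise *= noise_sigma
    return noise


def _sample_metadata(spec: CohortSpec) -> pd.DataFrame:
    """Cohort table matching the emulated study's marginals: patients'
    HRSD-17 ~ N(22.9, 4.3) truncated at >= 17 (the eligibility floor),
    controls ~ N(8.7, 5.8) truncated at >= 0; ages 14-18; ~62% male."""
    rng = np.random.default_rng([spec.seed, 2])
    n = spec.n_per_group
    rows = []

    def _trunc(mean, sd, lo, hi, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    ages_p = _trunc(15.1, 1.9, 14.0, 18.0, n)
    ages_c = _trunc(16.5, 1.9, 14.0, 18.0, n)
    hrsd_p = np.rint(_trunc(22.9, 4.3, 17.0, 52.0, n)).astype(int)
    hrsd_c = np.rint(_trunc(8.7, 5.8, 0.0, 52.0, n)).astype(int)
    dur_p = _trunc(6.3, 3.6, 0.5, 12.0, n)
    sex_p = np.where(rng.random(n) < 0.62, "M", "F")
    sex_c = np.where(rng.random(n) < 0.61, "M", "F")
    edu_p = np.where(rng.random(n) < 0.887, "high_school_or_lower", "undergraduate")
    edu_c = np.where(rng.random(n) < 0.875, "high_school_or_lower", "undergraduate")

    for i in range(n):
        rows.append(
            dict(
                subject_id=f"sub-p{i + 1:03d}",
                group="patient",
                age_years=float(ages_p[i]),
                sex=str(sex_p[i]),
                education=str(edu_p[i]),
                hrsd17=int(hrsd_p[i]),
                illness_duration_months=float(dur_p[i]),
            )
        )
    for i in range(n):
        rows.append(
            dict(
                subject_id=f"sub-c{i + 1:03d}",
                group="control",
                age_years=float(ages_c[i]),
                sex=str(sex_c[i]),
                education=str(edu_c[i]),
                hrsd17=int(hrsd_c[i]),
                illness_duration_months=np.nan,
            )
        )
    return pd.DataFrame(rows)


def generate_motion_trace(
    n_timepoints: int,
    max_abs_mm: float,
    max_abs_deg: float,
    seed: int,
    subject_id: str = "",
) -> MotionTrace:
    """Random-walk motion trace rescaled so the realized absolute maxima
    over the translation and rotation column blocks equal the requested
    maxima exactly (zero maxima give an all-zero block)."""
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if max_abs_mm < 0 or max_abs_deg < 0:
        raise ValueError("motion maxima must be >= 0")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal((n_timepoints, 6)), axis=0)
    walk -= walk[0]  # start at zero displacement
    for cols, target in ((slice(0, 3), max_abs_mm), (slice(3, 6), max_abs_deg)):
        peak = np.abs(walk[:, cols]).max()
        if target == 0 or peak == 0:
            walk[:, cols] = 0.0
        else:
            walk[:, cols] *= target / peak
    return MotionTrace(walk, subject_id=subject_id, aligned_to="raw")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[BoldSeries], list[MotionTrace], VolumeMask, pd.DataFrame, GroundTruth]:
    """Generate the full synthetic cohort.

    Returns BOLD series (patients first, then controls, matching the
    cohort table's row order), per-subject motion traces, the analysis
    mask, the cohort metadata table, and the planted-effect ground truth.
    Identical spec (including seed) gives bit-identical output.
    """
    amps, hub_net = _network_layout(spec)
    truth = _ground_truth(spec)
    table = _sample_metadata(spec)
    mask = VolumeMask(_analysis_mask(spec), label="gray_matter", affine=spec.affine)

    # Patient amplitude fields: hub voxels scaled by (1 + sign*magnitude).
    amps_patient = amps.copy()
    for i, hub in enumerate(spec.hub_regions):
        sph = _sphere_mask(spec.grid_shape, hub.center, hub.radius)
        k = hub_net[i]
        amps_patient[k][sph] *= 1.0 + hub.sign * hub.magnitude

    sigma_vox = spec.spatial_fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_size_mm
    n_sub = 2 * spec.n_per_group
    bad = set(range(min(spec.n_bad_movers, n_sub)))

    bolds: list[BoldSeries] = []
    traces: list[MotionTrace] = []
    for s in range(n_sub):
        sid = table.subject_id.iloc[s]
        is_patient = table.group.iloc[s] == "patient"
        rng = np.random.default_rng([spec.seed, 100 + s])
        n_latents = amps.shape[0]
        latents = np.stack([
            _latent_series(spec.n_timepoints, spec.ar_coef, spec.tr_seconds,
                           spec.latent_band_hz, rng)
            for _ in range(n_latents)
        ])
        loadings = 1.0 + spec.loading_sd * rng.standard_normal(n_latents)
        a = amps_patient if is_patient else amps
        # (K,x,y,z) x (K,t) -> (x,y,z,t)
        signal = np.tensordot(a * loadings[:, None, None, None], latents, axes=(0, 0))
        noise = _smooth_noise(spec.grid_shape, spec.n_timepoints, sigma_vox, spec.noise_sigma, rng)
        data = spec.baseline_offset + spec.signal_amplitude * signal + noise
        bolds.append(BoldSeries(data, spec.affine, spec.tr_seconds, subject_id=sid))

        mm = 2.5 if s in bad else 0.2 + 0.8 * float(np.random.default_rng([spec.seed, 500 + s]).random())
        deg = mm / 2.0
        traces.append(generate_motion_trace(spec.n_timepoints, mm, deg, seed=spec.seed * 1000 + 700 + s, subject_id=sid))

    return bolds, traces, mask, table, truth
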