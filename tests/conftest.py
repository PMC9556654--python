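"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dcnet import CohortSpec, generate_cohort
from dcnet.cohort import HubRegion
from dcnet.containers import BoldSeries, VolumeMask
from dcnet.degree import dc_pipeline


def make_series(data, voxel_mm=3.0, tr=2.0, subject_id="sub-test"):
    """BoldSeries on an RAS+ diagonal affine from a raw 4D array."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return BoldSeries(np.asarray(data, dtype=float), affine, tr, subject_id)


def full_mask(shape, voxel_mm=3.0, label="gray_matter"):
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return VolumeMask(np.ones(shape, dtype=bool), label=label, affine=affine)


@pytest.fixture(scope="session")
def effect_cohort():
    """Two-hub cohort (one increase, one decrease) with a clear planted
    effect: 12 subjects per group, 212 timepoints, 12^3 grid."""
    hubs = (
        HubRegion((4, 4, 4), 2.25, +1, 0.5),
        HubRegion((8, 8, 8), 2.25, -1, 0.5),
    )
    spec = CohortSpec(n_per_group=12, grid_shape=(12, 12, 12), n_timepoints=212,
                      hub_regions=hubs, seed=42)
    bolds, traces, mask, cohort, truth = generate_cohort(spec)
    return dict(spec=spec, bolds=bolds, traces=traces, mask=mask,
                cohort=cohort, truth=truth)


@pytest.fixture(scope="session")
def effect_dc_maps(effect_cohort):
    """Degree-centrality maps for the planted-effect cohort."""
    return [dc_pipeline(b, effect_cohort["mask"]) for b in effect_cohort["bolds"]]


@pytest.fixture(scope="session")
def null_cohort():
    """Effect-free cohort: the two groups are exchangeable."""
    spec = CohortSpec(n_per_group=15, grid_shape=(12, 12, 12), n_timepoints=60,
                      hub_regions=tuple(
                          HubRegion(c, 2.25, s, 0.0)
                          for c, s in (((4, 4, 4), 1), ((8, 8, 8), -1))),
                      seed=7)
    bolds, traces, mask, cohort, truth = generate_cohort(spec)
    return dict(spec=spec, bolds=bolds, traces=traces, mask=mask,
                cohort=cohort, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
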