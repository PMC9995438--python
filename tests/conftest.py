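"""Shared fixtures: desk-scale phantom specs and a small trained cohort.

Expensive objects (cohorts, trained bundles) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctpseg.ground_truth import build_lesion_map
from ctpseg.modeling import ModelConfig, tune_and_train
from ctpseg.patch_sampling import SamplingConfig, build_matrix, split_train_validation
from ctpseg.synthetic_ctp import PhantomSpec, TissueParams, generate_cohort, generate_study

#: compact grid used throughout the unit tests (96 x 96 x 80 mm FOV)
SMALL_SPEC = PhantomSpec(
    grid_shape=(32, 32, 20),
    voxel_spacing_mm=(3.0, 3.0, 4.0),
    brain_axes_mm=(42.0, 42.0, 35.0),
    lesion_center_mm=(-20.0, 0.0, 0.0),
    penumbra_radius_mm=18.0,
    core_radius_mm=11.0,
)

ZERO_NOISE = {"dt": 0.0, "cbf": 0.0, "mtt": 0.0, "cbv": 0.0}

#: same geometry with all variation switched off: four exact tissue signatures
NOISE_FREE_SPEC = PhantomSpec(
    grid_shape=SMALL_SPEC.grid_shape,
    voxel_spacing_mm=SMALL_SPEC.voxel_spacing_mm,
    brain_axes_mm=SMALL_SPEC.brain_axes_mm,
    lesion_center_mm=SMALL_SPEC.lesion_center_mm,
    penumbra_radius_mm=SMALL_SPEC.penumbra_radius_mm,
    core_radius_mm=SMALL_SPEC.core_radius_mm,
    healthy_params=TissueParams(dt=(1.0, 0.0), cbf=(100.0, 0.0), mtt=(4.0, 0.0), cbv=(4.0, 0.0)),
    penumbra_params=TissueParams(dt=(6.0, 0.0), cbf=(60.0, 0.0), mtt=(9.0, 0.0), cbv=(3.2, 0.0)),
    core_params=TissueParams(dt=(9.0, 0.0), cbf=(10.0, 0.0), mtt=(13.0, 0.0), cbv=(1.2, 0.0)),
    noise_sd=ZERO_NOISE,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return SMALL_SPEC


@pytest.fixture(scope="session")
def noise_free_spec() -> PhantomSpec:
    return NOISE_FREE_SPEC


@pytest.fixture(scope="session")
def noise_free_study():
    return generate_study(NOISE_FREE_SPEC)


@pytest.fixture(scope="session")
def small_study():
    import dataclasses

    return generate_study(dataclasses.replace(SMALL_SPEC, seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """8 jittered small-grid studies with their dual-threshold lesion maps."""
    cohort = generate_cohort(8, 1, SMALL_SPEC, seed=7)
    studies = [s for s, _ in cohort]
    truths = [t for _, t in cohort]
    lmaps = [build_lesion_map(s) for s in studies]
    return studies, truths, lmaps


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    studies, _, lmaps = small_cohort
    cfg = SamplingConfig(n_per_class=100, seed=7)
    return build_matrix(studies, lmaps, cfg), cfg


@pytest.fixture(scope="session")
def train_validation(small_matrix):
    matrix, cfg = small_matrix
    return split_train_validation(matrix, cfg)


@pytest.fixture(scope="session")
def xgb_bundle(train_validation):
    train, _ = train_validation
    cfg = ModelConfig(algorithm="xgb", feature_set="four_map", random_candidates=3,
                      grid_refine=False, seed=1)
    return tune_and_train(train, cfg)
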