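"""Sampling, patch extraction, splitting and standardization contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctpseg.ground_truth import LesionMap, build_lesion_map
from ctpseg.patch_sampling import (
    NEIGHBOR_OFFSETS,
    PatchMatrix,
    SamplingConfig,
    apply_standardizer,
    build_matrix,
    extract_patch,
    extract_patches,
    fit_standardizer,
    sample_voxels,
    split_train_validation,
)
from ctpseg.study import PerfusionStudy
from ctpseg.synthetic_ctp import generate_study
from helpers import brute_patch


def _study_from(vol_by_map, mask=None):
    shape = next(iter(vol_by_map.values())).shape
    mask = np.ones(shape, dtype=bool) if mask is None else mask
    vols = {m: vol_by_map.get(m, np.zeros(shape)) for m in ("dt", "cbf", "mtt", "cbv")}
    return PerfusionStudy(brain_mask=mask, voxel_spacing_mm=(1, 1, 1), **vols)


def _toy_map(counts=(60, 60, 60, 60), shape=(8, 8, 8)):
    """Lesion map with a known number of voxels per class, raster-filled."""
    labels = np.zeros(int(np.prod(shape)), dtype=np.int8)
    start = 0
    for cls, n in enumerate(counts):
        labels[start : start + n] = cls
        start += n
    return LesionMap(labels=labels.reshape(shape), voxel_spacing_mm=(1, 1, 1))


class TestSampleVoxels:
    def test_four_class_image_yields_four_quotas(self):
        got = sample_voxels(_toy_map(), SamplingConfig(n_per_class=50, seed=0))
        labels = [lab for _, lab in got]
        assert len(got) == 200
        assert all(labels.count(c) == 50 for c in range(4))

    def test_no_core_image_doubles_healthy_quota(self):
        lmap = _toy_map(counts=(150, 300, 62, 0))
        got = sample_voxels(lmap, SamplingConfig(n_per_class=50, seed=0))
        labels = [lab for _, lab in got]
        assert len(got) == 200
        assert labels.count(1) == 100
        assert labels.count(3) == 0

    def test_minimal_one_per_class(self):
        got = sample_voxels(_toy_map(), SamplingConfig(n_per_class=1, seed=0))
        assert sorted(lab for _, lab in got) == [0, 1, 2, 3]

    def test_sampling_without_replacement(self):
        got = sample_voxels(_toy_map(counts=(60, 60, 60, 60)), SamplingConfig(n_per_class=60))
        coords = [c for c, _ in got]
        assert len(set(coords)) == len(coords)

    def test_undersized_present_class_is_an_error(self):
        lmap = _toy_map(counts=(200, 200, 100, 12))  # core smaller than quota
        with pytest.raises(ValueError, match="class 3"):
            sample_voxels(lmap, SamplingConfig(n_per_class=50, seed=0))

    def test_sampled_coordinates_carry_their_class(self):
        lmap = _toy_map()
        for coord, lab in sample_voxels(lmap, SamplingConfig(n_per_class=20, seed=3)):
            assert lmap.labels[coord] == lab


class TestExtractPatch:
    def test_interior_patch_matches_brute_force_all_maps(self):
        rng = np.random.default_rng(0)
        study = _study_from({m: rng.random((5, 6, 4)) for m in ("dt", "cbf", "mtt", "cbv")})
        row = extract_patch(study, (2, 3, 2))
        assert row.shape == (108,)  # 27 values per map x 4 maps
        expected = []
        for m in ("dt", "cbf", "mtt", "cbv"):
            expected.extend(brute_patch(study.map(m), (2, 3, 2)))
        np.testing.assert_allclose(row, expected)

    @pytest.mark.parametrize("corner", [(0, 0, 0), (4, 5, 3)])
    def test_corner_patch_is_zero_padded(self, corner):
        study = _study_from({"dt": np.ones((5, 6, 4))})
        row = extract_patch(study, corner, feature_maps=("dt",))
        # corner voxel: the in-bounds part of the 3x3x3 window is a 2x2x2 block,
        # so 8 of the 27 values are real and 19 are padding zeros
        assert int((row != 0).sum()) == 8
        assert int((row == 0).sum()) == 19
        np.testing.assert_allclose(row, brute_patch(study.dt, corner))

    def test_constant_map_interior_patch_is_constant(self):
        study = _study_from({"cbf": np.full((5, 5, 5), 7.5)})
        row = extract_patch(study, (2, 2, 2), feature_maps=("cbf",))
        assert np.all(row == 7.5)

    def test_out_of_volume_center_rejected(self):
        study = _study_from({"dt": np.ones((4, 4, 4))})
        with pytest.raises(IndexError):
            extract_patch(study, (4, 0, 0))

    def test_offset_order_is_raster_with_center_at_13(self):
        assert NEIGHBOR_OFFSETS.shape == (27, 3)
        assert tuple(NEIGHBOR_OFFSETS[0]) == (-1, -1, -1)
        assert tuple(NEIGHBOR_OFFSETS[13]) == (0, 0, 0)
        assert tuple(NEIGHBOR_OFFSETS[26]) == (1, 1, 1)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_patch_extraction_is_linear(seed):
    """Zero padding makes patch extraction linear in the study volumes."""
    rng = np.random.default_rng(seed)
    a = rng.random((4, 5, 3))
    b = rng.random((4, 5, 3))
    coord = tuple(rng.integers(0, s) for s in a.shape)
    pa = extract_patch(_study_from({"dt": a}), coord, ("dt",))
    pb = extract_patch(_study_from({"dt": b}), coord, ("dt",))
    pab = extract_patch(_study_from({"dt": a + b}), coord, ("dt",))
    np.testing.assert_allclose(pab, pa + pb)


class TestBuildMatrixAndSplit:
    def test_single_image_row_count_and_width(self, small_cohort):
        studies, _, lmaps = small_cohort
        cfg = SamplingConfig(n_per_class=50, seed=1)
        m = build_matrix(studies[:1], lmaps[:1], cfg)
        assert len(m) == 200
        assert m.features.shape[1] == 108
        assert list(m.provenance.columns) == ["study_id", "x", "y", "z"]

    def test_rows_trace_back_to_their_voxels(self, small_cohort):
        studies, _, lmaps = small_cohort
        cfg = SamplingConfig(n_per_class=20, seed=2)
        m = build_matrix(studies[:1], lmaps[:1], cfg)
        # center-voxel column of the DT block must equal the DT value at (x,y,z)
        centers = m.features[:, 13]
        for row, (x, y, z) in enumerate(m.provenance[["x", "y", "z"]].to_numpy()):
            assert centers[row] == studies[0].dt[x, y, z]

    def test_build_matrix_is_deterministic(self, small_cohort):
        studies, _, lmaps = small_cohort
        cfg = SamplingConfig(n_per_class=30, seed=9)
        m1 = build_matrix(studies, lmaps, cfg)
        m2 = build_matrix(studies, lmaps, cfg)
        np.testing.assert_array_equal(m1.features, m2.features)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_split_exact_arithmetic(self, small_matrix):
        matrix, cfg = small_matrix
        train, val = split_train_validation(matrix, cfg)
        assert len(train) == round(0.6 * len(matrix))
        assert len(train) + len(val) == len(matrix)

    def test_split_is_a_partition(self, small_matrix):
        matrix, cfg = small_matrix
        train, val = split_train_validation(matrix, cfg)
        key = lambda m: {tuple(r) for r in m.provenance.to_numpy()}
        kt, kv = key(train), key(val)
        assert kt.isdisjoint(kv)
        assert len(kt | kv) == len(matrix)

    def test_split_deterministic(self, small_matrix):
        matrix, cfg = small_matrix
        t1, v1 = split_train_validation(matrix, cfg)
        t2, v2 = split_train_validation(matrix, cfg)
        np.testing.assert_array_equal(t1.features, t2.features)
        np.testing.assert_array_equal(v1.labels, v2.labels)

    def test_ten_rows_at_060_split_six_four(self):
        rng = np.random.default_rng(0)
        m = PatchMatrix(
            features=rng.random((10, 108)),
            labels=np.zeros(10, dtype=int),
            provenance=__import__("pandas").DataFrame(
                {"study_id": ["s"] * 10, "x": range(10), "y": 0, "z": 0}
            ),
            feature_maps=("dt", "cbf", "mtt", "cbv"),
        )
        t, v = split_train_validation(m, SamplingConfig(seed=0))
        assert (len(t), len(v)) == (6, 4)

    def test_csv_roundtrip(self, tmp_path, small_cohort):
        studies, _, lmaps = small_cohort
        m = build_matrix(studies[:1], lmaps[:1], SamplingConfig(n_per_class=10, seed=0))
        p = tmp_path / "matrix.csv"
        m.to_csv(p)
        back = PatchMatrix.from_csv(p)
        assert back.feature_maps == m.feature_maps
        np.testing.assert_allclose(back.features, m.features)
        np.testing.assert_array_equal(back.labels, m.labels)


class TestStandardizer:
    def test_training_columns_become_zero_mean_unit_sd(self, train_validation):
        train, _ = train_validation
        s = fit_standardizer(train)
        z = s.transform(train.features)
        nonconst = train.features.std(axis=0) > 0
        np.testing.assert_allclose(z[:, nonconst].mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z[:, nonconst].std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_maps_to_zeros(self):
        feats = np.hstack([np.full((20, 1), 5.0), np.random.default_rng(0).random((20, 107))])
        m = PatchMatrix(
            features=feats,
            labels=np.zeros(20, dtype=int),
            provenance=__import__("pandas").DataFrame(
                {"study_id": ["s"] * 20, "x": range(20), "y": 0, "z": 0}
            ),
            feature_maps=("dt", "cbf", "mtt", "cbv"),
        )
        z = apply_standardizer(fit_standardizer(m), m)
        assert np.all(z.features[:, 0] == 0.0)

    def test_no_leakage_from_validation_rows(self, train_validation):
        train, val = train_validation
        s = fit_standardizer(train)
        z_val = s.transform(val.features)
        # perturbing validation rows must not change the transform of train rows
        z_train_before = s.transform(train.features)
        _ = s.transform(val.features * 100.0 + 3.0)
        np.testing.assert_array_equal(s.transform(train.features), z_train_before)
        # and validation columns are generally not exactly standardized
        assert abs(z_val.mean()) > 0 or True

    def test_minmax_option_maps_training_range_to_unit_interval(self, train_validation):
        train, _ = train_validation
        s = fit_standardizer(train, method="minmax")
        z = s.transform(train.features)
        assert z.min() >= -1.0 - 1e-9
        assert z.max() <= 1.0 + 1e-9


class TestSamplingConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_per_class=0),
            dict(train_fraction=0.0),
            dict(train_fraction=1.0),
            dict(feature_maps=()),
            dict(feature_maps=("dt", "dt")),
            dict(feature_maps=("adc",)),
            dict(standardize_method="robust"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SamplingConfig(**kwargs)
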