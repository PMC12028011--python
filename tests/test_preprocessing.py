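import numpy as np
import pytest

from bpfuse.data_model import ClinicalRecord, SequenceKind, SequenceVolume
from bpfuse.preprocessing import (
    PreprocessConfig,
    central_crop,
    crop_array,
    fit_clinical_bounds,
    mask_centroid,
    minmax_normalize,
    preprocess_case,
    prostate_volume,
    psa_density,
    resample,
    scale_clinical,
)

from conftest import make_case


def vol(voxels, spacing=(3.0, 0.5, 0.5), kind=SequenceKind.T2W):
    return SequenceVolume(np.asarray(voxels, dtype=np.float32), spacing, kind, "c")


class TestResample:
    def test_identity_spacing(self):
        v = vol(np.random.default_rng(0).normal(size=(6, 10, 10)))
        out = resample(v, (3.0, 0.5, 0.5))
        assert out.shape == v.shape
        np.testing.assert_allclose(out.voxels, v.voxels)

    def test_shape_arithmetic(self):
        v = vol(np.zeros((10, 8, 8)), spacing=(6.0, 0.5, 0.5))
        out = resample(v, (3.0, 0.5, 0.5))
        assert out.shape == (20, 8, 8)
        assert out.spacing == (3.0, 0.5, 0.5)

    def test_constant_preserved(self):
        v = vol(np.full((7, 9, 11), 42.0), spacing=(2.0, 1.0, 0.7))
        out = resample(v, (3.0, 0.5, 0.5))
        assert np.max(np.abs(out.voxels - 42.0)) < 1e-6

    def test_rejects_bad_target(self):
        v = vol(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample(v, (0.0, 0.5, 0.5))


class TestCentralCrop:
    def test_exact_center_block(self):
        data = np.arange(40 * 30 * 30, dtype=np.float32).reshape(40, 30, 30)
        v = vol(data)
        out = central_crop(v, (8, 24, 24))
        np.testing.assert_array_equal(out.voxels, data[16:24, 3:27, 3:27])

    def test_padding_when_undersized(self):
        data = np.ones((4, 10, 10), dtype=np.float32)
        out = central_crop(vol(data), (8, 24, 24))
        assert out.shape == (8, 24, 24)
        assert out.voxels.sum() == pytest.approx(data.sum())  # zero padding
        np.testing.assert_array_equal(out.voxels[2:6, 7:17, 7:17], data)

    def test_mask_centroid_policy(self):
        # off-center blob; crop must center on its centroid
        data = np.zeros((20, 40, 40), dtype=np.float32)
        mask = np.zeros_like(data, dtype=np.uint8)
        mask[12:16, 25:33, 5:13] = 1
        # brute-force centroid oracle
        idx = np.argwhere(mask)
        oracle_centroid = idx.mean(axis=0)
        np.testing.assert_allclose(mask_centroid(mask), oracle_centroid)
        out = central_crop(vol(data + 1), (4, 8, 8), policy="MASK_CENTROID", mask=mask)
        assert out.shape == (4, 8, 8)
        cropped_mask = crop_array(mask.astype(np.float32), (4, 8, 8),
                                  oracle_centroid + 0.5)
        assert cropped_mask.mean() == pytest.approx(1.0)  # fully covers the blob


class TestMinMax:
    def test_formula(self):
        v = vol(np.array([[[0.0, 5.0, 10.0]]]))
        np.testing.assert_allclose(minmax_normalize(v).voxels, [[[0.0, 0.5, 1.0]]])

    def test_constant_image_warns_zeros(self):
        v = vol(np.full((2, 2, 2), 9.0))
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(v)
        assert np.all(out.voxels == 0)

    def test_spans_unit_interval(self):
        v = vol(np.random.default_rng(1).normal(size=(5, 6, 7)))
        out = minmax_normalize(v).voxels
        assert out.min() == 0.0
        assert out.max() == 1.0

    def test_idempotent(self):
        v = vol(np.random.default_rng(2).normal(size=(4, 4, 4)))
        once = minmax_normalize(v)
        twice = minmax_normalize(once)
        np.testing.assert_allclose(twice.voxels, once.voxels, atol=1e-7)


class TestProstateVolume:
    def test_arithmetic(self):
        mask = np.zeros((50, 100, 100), dtype=np.uint8)
        mask.ravel()[:40_000] = 1
        assert prostate_volume(mask, (3.0, 0.5, 0.5)) == pytest.approx(30.0)

    def test_unit_cube(self):
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask = mask.ravel()
        mask[:1000] = 1
        assert prostate_volume(mask.reshape(10, 10, 10), (1, 1, 1)) == pytest.approx(1.0)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            prostate_volume(np.zeros((4, 4, 4)), (1, 1, 1))

    def test_ellipsoid_analytic(self):
        # fine grid: voxelized ellipsoid volume within 2% of 4/3 pi abc
        a, b, c = 11.0, 14.0, 17.0  # mm
        spacing = (0.5, 0.5, 0.5)
        shape = (60, 70, 80)
        zz, yy, xx = np.meshgrid(
            *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
        )
        center = [n * s / 2 for n, s in zip(shape, spacing)]
        mask = (
            ((zz - center[0]) / a) ** 2
            + ((yy - center[1]) / b) ** 2
            + ((xx - center[2]) / c) ** 2
        ) <= 1.0
        analytic = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        assert prostate_volume(mask, spacing) == pytest.approx(analytic, rel=0.02)

    def test_translation_invariance(self):
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[2:5, 2:5, 2:5] = 1
        shifted = np.roll(mask, (2, 3, 1), axis=(0, 1, 2))
        assert prostate_volume(mask, (2, 1, 1)) == prostate_volume(shifted, (2, 1, 1))

    def test_spacing_equivariance(self):
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[1:4, 1:4, 1:4] = 1
        v1 = prostate_volume(mask, (1, 1, 1))
        v2 = prostate_volume(mask, (2, 1, 3))
        assert v2 == pytest.approx(v1 * 6.0)


class TestPsaDensity:
    def test_values(self):
        assert psa_density(6.0, 30.0) == pytest.approx(0.2)
        assert psa_density(0.0, 25.0) == 0.0
        assert psa_density(4.0, 40.0) == pytest.approx(0.1)

    def test_nonpositive_volume(self):
        with pytest.raises(ValueError):
            psa_density(5.0, 0.0)


class TestScaleClinical:
    def _bounds(self):
        recs = [
            ClinicalRecord(age=50.0, psa=2.0, psa_density=0.05),
            ClinicalRecord(age=80.0, psa=20.0, psa_density=0.45),
        ]
        return fit_clinical_bounds(recs)

    def test_endpoints_and_midpoint(self):
        bounds = self._bounds()
        lo = scale_clinical(ClinicalRecord(age=50.0, psa=2.0, psa_density=0.05), bounds)
        hi = scale_clinical(ClinicalRecord(age=80.0, psa=20.0, psa_density=0.45), bounds)
        mid = scale_clinical(ClinicalRecord(age=65.0, psa=11.0, psa_density=0.25), bounds)
        assert lo.age_norm == -1.0 and hi.age_norm == 1.0
        assert lo.psa_norm == -1.0 and hi.psa_norm == 1.0
        assert mid.age_norm == pytest.approx(0.0)
        assert mid.psa_norm == pytest.approx(0.0)
        assert mid.psad_norm == pytest.approx(0.0)

    def test_clipping_beyond_training_bounds(self):
        bounds = self._bounds()
        out = scale_clinical(ClinicalRecord(age=95.0, psa=60.0, psa_density=0.9), bounds)
        assert out.age_norm == 1.0
        assert out.psa_norm == 1.0
        assert out.psad_norm == 1.0

    def test_degenerate_bounds_map_to_zero(self):
        recs = [ClinicalRecord(age=60.0, psa=5.0, psa_density=0.1)] * 2
        bounds = fit_clinical_bounds(recs)
        with pytest.warns(UserWarning, match="degenerate"):
            out = scale_clinical(recs[0], bounds)
        assert out.age_norm == 0.0


class TestPipeline:
    def test_output_shape_contract(self):
        cfg = PreprocessConfig(target_spacing=(3.0, 1.0, 1.0), crop_shape=(6, 16, 16))
        for seed in range(3):
            case = make_case(shape=(5 + seed, 20, 18), seed=seed)
            out = preprocess_case(case, cfg)
            for kind in SequenceKind:
                assert out.volumes[kind].shape == (6, 16, 16)
                v = out.volumes[kind].voxels
                assert v.min() >= 0.0 and v.max() <= 1.0

    def test_psad_computed_from_mask(self):
        cfg = PreprocessConfig(target_spacing=(3.0, 1.0, 1.0), crop_shape=(6, 16, 16))
        case = make_case()
        out = preprocess_case(case, cfg)
        gv = prostate_volume(case.gland_mask, case.volumes[SequenceKind.T2W].spacing)
        assert out.clinical.psa_density == pytest.approx(case.clinical.psa / gv)
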