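import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hsibench as hb
from hsibench.hypercube_core import CANCER, NON_MALIGNANT
from hsibench.preprocessing_ops import ArtifactMetrics


def _cube(values, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = hb.WavelengthGrid.from_range(500.0, 500.0 + 5.0 * (values.shape[2] - 1), 5.0)
    return hb.Hypercube(values, grid)


class TestScaling:
    def test_unit_length_closed_form(self):
        cube = _cube(np.full((1, 1, 4), 2.0))
        out = hb.scale_unit_length(cube)
        np.testing.assert_allclose(out.values[0, 0], [0.5, 0.5, 0.5, 0.5])

    def test_flat_92_band_spectrum_lands_in_stated_range(self):
        cube = _cube(np.full((1, 1, 92), 0.37))
        out = hb.scale_unit_length(cube)
        np.testing.assert_allclose(out.values, 1 / np.sqrt(92))
        assert 0 < out.values.max() <= 0.14

    def test_unit_length_output_norms_one(self, rng):
        cube = _cube(rng.random((6, 5, 30)) + 0.05)
        out = hb.scale_unit_length(cube)
        np.testing.assert_allclose(np.linalg.norm(out.values, axis=2), 1.0, atol=1e-9)

    def test_zscore_closed_form_population_sd(self):
        cube = _cube(np.array([1.0, 2.0, 3.0]).reshape(1, 1, 3))
        out = hb.scale_zscore(cube)
        np.testing.assert_allclose(out.values[0, 0], [-1.22474487, 0.0, 1.22474487])

    def test_zscore_moments(self, rng):
        cube = _cube(rng.random((4, 4, 40)))
        out = hb.scale_zscore(cube)
        np.testing.assert_allclose(out.values.mean(axis=2), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=2), 1.0, atol=1e-9)

    @pytest.mark.parametrize("scaler", [hb.scale_unit_length, hb.scale_zscore])
    def test_scaling_idempotence(self, rng, scaler):
        cube = _cube(rng.random((3, 3, 25)) + 0.1)
        once = scaler(cube)
        twice = scaler(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_degenerate_spectra_rejected_with_pixel_named(self):
        zero = _cube(np.zeros((2, 2, 5)))
        with pytest.raises(hb.HypercubeError, match=r"\(0, 0\)"):
            hb.scale_unit_length(zero)
        const = _cube(np.full((2, 2, 5), 0.3))
        with pytest.raises(hb.HypercubeError, match=r"\(0, 0\)"):
            hb.scale_zscore(const)


class TestSmoothing:
    def test_constant_cube_unchanged_by_any_filter(self):
        cube = _cube(np.full((6, 6, 15), 0.4))
        for spec in (
            hb.SmoothingSpec("none"),
            hb.SmoothingSpec("d1", "median", 3),
            hb.SmoothingSpec("d2", "gaussian", 1.5),
            hb.SmoothingSpec("d3", "median", 3),
            hb.SmoothingSpec("d1", "savgol", 9),
        ):
            out = hb.smooth(cube, spec)
            np.testing.assert_allclose(out.values, 0.4, atol=1e-9)
            assert out.shape == cube.shape

    def test_spectral_median_window3_with_edge_replication(self):
        cube = _cube(np.array([1.0, 9.0, 1.0, 9.0, 1.0]).reshape(1, 1, 5))
        out = hb.smooth(cube, hb.SmoothingSpec("d1", "median", 3))
        np.testing.assert_array_equal(out.values[0, 0], [1, 1, 9, 1, 1])

    def test_savgol_restricted_to_spectral_mode(self):
        with pytest.raises(hb.CombinationError, match="spectral-only"):
            hb.SmoothingSpec("d2", "savgol", 9)

    def test_spatial_smoothing_leaves_pixelwise_identical_cube_flat(self, rng):
        spectrum = rng.random(20)
        cube = _cube(np.tile(spectrum, (5, 5, 1)))
        out = hb.smooth(cube, hb.SmoothingSpec("d2", "gaussian", 2.0))
        assert float(out.values.std(axis=(0, 1)).max()) < 1e-12

    def test_window_exceeding_axis_is_an_error(self):
        cube = _cube(np.random.default_rng(0).random((3, 3, 5)))
        with pytest.raises(hb.CombinationError):
            hb.smooth(cube, hb.SmoothingSpec("d1", "median", 7))

    def test_invalid_specs_rejected(self):
        with pytest.raises(hb.CombinationError):
            hb.SmoothingSpec("d1", "median", 4)  # even window
        with pytest.raises(hb.CombinationError):
            hb.SmoothingSpec("d1", "savgol", 1)  # window <= order
        with pytest.raises(hb.CombinationError):
            hb.SmoothingSpec("d9", "median", 3)


class TestArtifactMetrics:
    def test_constant_cube_means(self, grid100):
        cube = hb.Hypercube(np.full((3, 3, 100), 0.3), grid100)
        m = hb.artifact_metrics(cube)
        np.testing.assert_allclose(m.A, 0.3)
        np.testing.assert_allclose(m.B, 0.3)

    def test_c_is_zero_when_window_mean_equals_constant(self, grid100):
        cube = hb.Hypercube(np.full((2, 2, 100), 0.1), grid100)
        m = hb.artifact_metrics(cube, c_constant=0.1)
        np.testing.assert_allclose(m.C, 0.0, atol=1e-12)

    def test_windows_match_brute_force_means(self, grid100, rng):
        cube = hb.Hypercube(rng.random((4, 5, 100)), grid100)
        m = hb.artifact_metrics(cube, c_constant=0.2)
        lam = grid100.centers_nm
        for arr, (lo, hi) in ((m.A, (500, 1000)), (m.B, (510, 570))):
            idx = [i for i, c in enumerate(lam) if lo <= c <= hi]
            brute = cube.values[:, :, idx].mean(axis=2)
            np.testing.assert_allclose(arr, brute)
        idx = [i for i, c in enumerate(lam) if 650 <= c <= 710]
        np.testing.assert_allclose(
            m.C, np.log(cube.values[:, :, idx].mean(axis=2) / 0.2)
        )

    def test_missing_window_is_an_error(self):
        grid = hb.WavelengthGrid.from_range(600.0, 995.0, 5.0)
        cube = hb.Hypercube(np.random.default_rng(1).random((2, 2, 80)), grid)
        with pytest.raises(hb.HypercubeError, match="metric B"):
            hb.artifact_metrics(cube)


class TestExclusionMask:
    def _metrics(self, A, B, C):
        return ArtifactMetrics(np.asarray(A, float), np.asarray(B, float),
                               np.asarray(C, float), 0.1)

    def test_dim_pixel_excluded_by_light_threshold(self):
        m = self._metrics([[0.05]], [[0.2]], [[1.0]])
        mask = hb.exclusion_mask(m, hb.FilterSpec(light_threshold=0.1))
        assert mask[0, 0]

    def test_no_thresholds_means_all_false(self, rng):
        m = self._metrics(rng.random((4, 4)), rng.random((4, 4)), rng.normal(size=(4, 4)))
        assert not hb.exclusion_mask(m, hb.FilterSpec()).any()

    def test_c_conjunct_requires_negative_c(self):
        m = self._metrics([[0.05, 0.05]], [[0.2, 0.2]], [[1.0, -1.0]])
        mask = hb.exclusion_mask(
            m, hb.FilterSpec(light_threshold=0.1, use_c_conjunct=True)
        )
        assert not mask[0, 0] and mask[0, 1]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_both_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        m = self._metrics(rng.random((8, 8)), rng.random((8, 8)), rng.normal(size=(8, 8)))
        lo = hb.exclusion_mask(m, hb.FilterSpec(light_threshold=0.1))
        hi = hb.exclusion_mask(m, hb.FilterSpec(light_threshold=0.25))
        assert np.all(hi[lo])  # raising the light threshold grows the mask
        blo = hb.exclusion_mask(m, hb.FilterSpec(blood_threshold=0.7))
        bhi = hb.exclusion_mask(m, hb.FilterSpec(blood_threshold=0.15))
        assert np.all(bhi[blo])  # lowering the blood threshold grows the mask


class TestApplyCombination:
    def test_identity_combination_matches_band_cut_plus_patches(self, small_cohort):
        rec = small_cohort[0]
        combo = hb.PreprocessingCombination(
            scaling="standardization", patch_size=3
        )
        ps = hb.apply_combination(rec, combo)
        cut = hb.select_bands(rec.cube, 540.0)
        scaled = hb.scale_zscore(cut)
        ref = hb.extract_patches(
            hb.PatientRecord(rec.patient_id, scaled, rec.mask), 3
        )
        assert len(ps) == len(ref)
        np.testing.assert_allclose(ps.patches, ref.patches)

    def test_pipeline_stage_order_is_observable(self, small_cohort):
        trace = []
        combo = hb.PreprocessingCombination(
            smoothing=hb.SmoothingSpec("d1", "median", 3),
            filtering=hb.FilterSpec(blood_threshold=0.2),
        )
        hb.apply_combination(small_cohort[0], combo, trace=trace)
        assert trace == [
            "artifact_metrics",
            "band_exclusion",
            "scaling:standardization",
            "smoothing:d1-median-3",
            "exclusion_mask",
            "patch_extraction",
        ]

    def test_blood_masked_pixel_absent_from_patchset(self, spectral_model, small_cohort):
        rec, _ = hb.inject_artifacts(
            small_cohort[0], spectral_model, blood_fraction=0.05, seed=6
        )
        thr = hb.true_blood_threshold(spectral_model, rec.cube.grid)
        plain = hb.apply_combination(rec, hb.PreprocessingCombination())
        filtered = hb.apply_combination(
            rec,
            hb.PreprocessingCombination(filtering=hb.FilterSpec(blood_threshold=thr)),
        )
        assert len(filtered) < len(plain)
        metrics = hb.artifact_metrics(rec.cube)
        dropped = set(map(tuple, plain.pixel_coords)) - set(map(tuple, filtered.pixel_coords))
        for r, c in dropped:
            assert metrics.B[r, c] > thr

    def test_patch5_on_92_bands(self, small_cohort):
        combo = hb.PreprocessingCombination(patch_size=5)
        ps = hb.apply_combination(small_cohort[0], combo)
        assert ps.patches.shape[1:] == (5, 5, 92)


class TestEnumerateGrid:
    def test_minimal_config_product(self):
        cfg = {
            "scaling": ["normalization", "standardization"],
            "weighting": ["class", "sample"],
            "patch_size": [3],
            "smoothing": {"include_none": True},
            "filtering": {"include_none": True},
        }
        combos = hb.enumerate_grid(cfg)
        assert len(combos) == 4

    def test_savgol_under_d2_rejected(self):
        cfg = {
            "scaling": ["standardization"],
            "weighting": ["sample"],
            "patch_size": [3],
            "smoothing": {"include_none": False,
                          "savgol": {"modes": ["d2"], "params": [9], "order": 2}},
            "filtering": {"include_none": True},
        }
        with pytest.raises(hb.CombinationError):
            hb.enumerate_grid(cfg)

    def test_length_matches_brute_force_product(self):
        cfg = hb.default_grid_config()
        combos = hb.enumerate_grid(cfg)
        n_smooth = 1 + 3 * 3 + 3 * 3 + 1  # none + median + gaussian + savgol(d1)
        n_filter = 3 * 3  # (none + 2 light) x (none + 2 blood)
        expected = 2 * 2 * 2 * n_smooth * n_filter
        assert len(combos) == expected
        # deterministic order
        again = hb.enumerate_grid(hb.default_grid_config())
        assert [c.as_record() for c in combos] == [c.as_record() for c in again]

    def test_records_are_flat_and_unique(self):
        combos = hb.enumerate_grid()
        records = [tuple(sorted(c.as_record().items())) for c in combos]
        assert len(set(records)) == len(records)
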