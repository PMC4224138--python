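"""Temporal preparation: trimming, filtering, averaging, masking, warping."""

import numpy as np
import pytest

from voxnet import (
    BoldVolume,
    TissueMask,
    apply_tissue_mask,
    average_trials,
    concatenate_sessions,
    highpass_filter,
    normalize_then_resample,
    trim_volume,
)
from voxnet.prep import mask_to_coords, resample_labels


def volume_from_series(series, tr=2.68):
    """A 1x1x1 volume holding one time series."""
    return BoldVolume(data=np.asarray(series, dtype=float)[None, None, None, :], tr=tr)


class TestTrim:
    def test_128_minus_4_plus_4_gives_120(self, rng):
        v = BoldVolume(data=rng.normal(size=(4, 4, 2, 128)))
        out = trim_volume(v, 4, 4)
        assert out.n_timepoints == 120
        np.testing.assert_array_equal(out.data, v.data[..., 4:124])

    def test_zero_trim_is_identity(self, rng):
        v = BoldVolume(data=rng.normal(size=(2, 2, 2, 10)))
        np.testing.assert_array_equal(trim_volume(v, 0, 0).data, v.data)

    def test_over_trim_rejected(self, rng):
        v = BoldVolume(data=rng.normal(size=(2, 2, 2, 8)))
        with pytest.raises(ValueError):
            trim_volume(v, 4, 4)

    def test_trims_compose_additively(self, rng):
        v = BoldVolume(data=rng.normal(size=(2, 2, 2, 30)))
        once = trim_volume(v, 5, 7)
        twice = trim_volume(trim_volume(v, 2, 3), 3, 4)
        np.testing.assert_array_equal(once.data, twice.data)


class TestHighpass:
    def test_constant_series_becomes_zero(self):
        v = volume_from_series(np.full(64, 7.5))
        out = highpass_filter(v, 0.02)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_passband_sinusoid_preserved(self):
        tr = 2.68
        t = np.arange(128) * tr
        sig = np.sin(2 * np.pi * 0.1 * t)
        out = highpass_filter(volume_from_series(sig, tr), 0.02).data.ravel()
        # amplitude preserved within 5 % (evaluate on the interior to avoid
        # DCT edge effects)
        assert np.abs(out[10:-10] - sig[10:-10]).max() < 0.05

    def test_stopband_sinusoid_attenuated(self):
        tr = 2.68
        t = np.arange(128) * tr
        sig = np.sin(2 * np.pi * 0.005 * t)
        out = highpass_filter(volume_from_series(sig, tr), 0.02).data.ravel()
        assert np.sqrt(np.mean(out**2)) <= 0.1 * np.sqrt(np.mean(sig**2))

    def test_filter_is_linear(self, rng):
        x = rng.normal(size=48)
        y = rng.normal(size=48)
        a, b = 2.5, -1.25
        f = lambda s: highpass_filter(volume_from_series(s), 0.02).data.ravel()
        np.testing.assert_allclose(f(a * x + b * y), a * f(x) + b * f(y), atol=1e-9)

    def test_cutoff_beyond_nyquist_rejected(self, rng):
        v = volume_from_series(rng.normal(size=32), tr=2.68)
        with pytest.raises(ValueError):
            highpass_filter(v, 0.3)

    def test_output_mean_is_zero(self, rng):
        v = BoldVolume(data=rng.normal(size=(3, 3, 2, 64)) + 100.0)
        out = highpass_filter(v, 0.02)
        np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-9)


class TestAverageTrials:
    def test_constant_voxel_stays_constant(self):
        v = volume_from_series(np.full(40, 7.0))
        out = average_trials(v, [0, 8, 16], 8)
        np.testing.assert_allclose(out.data, 7.0)

    def test_sixty_windows_of_eight(self, rng):
        v = BoldVolume(data=rng.normal(size=(2, 2, 1, 480)))
        out = average_trials(v, list(range(0, 480, 8)), 8)
        assert out.n_timepoints == 8

    def test_two_trial_arithmetic_mean(self):
        v = volume_from_series([1.0, 2.0, 3.0, 4.0])
        out = average_trials(v, [0, 2], 2)
        np.testing.assert_allclose(out.data.ravel(), [2.0, 3.0])

    def test_identical_trials_equal_any_single_trial(self, rng):
        trial = rng.normal(size=8)
        v = volume_from_series(np.tile(trial, 5))
        out = average_trials(v, list(range(0, 40, 8)), 8)
        np.testing.assert_array_equal(out.data.ravel(), trial)

    def test_out_of_range_window_rejected(self):
        v = volume_from_series(np.zeros(16))
        with pytest.raises(ValueError):
            average_trials(v, [12], 8)

    def test_overlapping_windows_warn(self):
        v = volume_from_series(np.zeros(16))
        with pytest.warns(UserWarning, match="overlap"):
            average_trials(v, [0, 4], 8)


class TestConcatenate:
    def test_four_sessions_of_120_give_480(self, rng):
        vs = [BoldVolume(data=rng.normal(size=(2, 2, 1, 120))) for _ in range(4)]
        assert concatenate_sessions(vs).n_timepoints == 480

    def test_single_session_identity(self, rng):
        v = BoldVolume(data=rng.normal(size=(2, 2, 1, 10)))
        np.testing.assert_array_equal(concatenate_sessions([v]).data, v.data)

    def test_mismatched_grids_rejected(self, rng):
        a = BoldVolume(data=rng.normal(size=(2, 2, 1, 10)))
        b = BoldVolume(data=rng.normal(size=(3, 2, 1, 10)))
        with pytest.raises(ValueError):
            concatenate_sessions([a, b])


class TestTissueMask:
    def test_toy_2x2x1_mask(self, rng):
        labels = np.array([[[2], [3]], [[1], [0]]], dtype=np.int16)  # GM WM CSF bg
        m = TissueMask(labels=labels)
        v = BoldVolume(data=rng.normal(size=(2, 2, 1, 5)))
        coords = apply_tissue_mask(v, m, keep=("gm", "wm"))
        assert coords.shape == (2, 3)
        assert {tuple(c) for c in coords} == {(0, 0, 0), (0, 1, 0)}

    def test_all_gm_includes_everything(self, rng):
        m = TissueMask(labels=np.full((3, 2, 2), 2, dtype=np.int16))
        v = BoldVolume(data=rng.normal(size=(3, 2, 2, 4)))
        assert apply_tissue_mask(v, m).shape[0] == 12

    def test_all_csf_excluded(self, rng):
        m = TissueMask(labels=np.full((2, 2, 2), 1, dtype=np.int16))
        v = BoldVolume(data=rng.normal(size=(2, 2, 2, 4)))
        assert apply_tissue_mask(v, m).shape[0] == 0

    def test_raster_order_x_fastest(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        coords = mask_to_coords(mask)
        # x varies fastest, then y, then z
        expected = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                    (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
        assert [tuple(c) for c in coords] == expected


class TestNormalizeThenResample:
    def test_identity_affine_preserves_values(self, rng):
        v = BoldVolume(data=rng.normal(size=(6, 6, 4, 3)))
        out = normalize_then_resample(v, np.eye(4))
        assert out.space_tag == "standard"
        np.testing.assert_allclose(out.data, v.data, atol=1e-9)

    def test_integer_translation_round_trips(self, rng):
        v = BoldVolume(data=rng.normal(size=(8, 8, 4, 2)))
        A = np.eye(4)
        A[:3, 3] = [2, 1, 0]
        out = normalize_then_resample(v, A)
        # Warping by an integer translation and back touches no interpolation
        # weights: interior voxels must round-trip exactly (the forward warp
        # crops what falls off the standard grid, so compare the region that
        # stayed on-grid throughout).
        np.testing.assert_allclose(out.data[:6, :7, :, :], v.data[:6, :7, :, :], atol=1e-9)

    def test_nearest_neighbour_mask_label_subset(self):
        labels = np.random.default_rng(0).integers(0, 4, size=(6, 6, 4)).astype(np.int16)
        m = TissueMask(labels=labels)
        A = np.eye(4)
        A[:3, 3] = [0.4, -0.3, 0.2]
        out = resample_labels(m, A)
        assert set(np.unique(out.labels)) <= set(np.unique(labels))

    def test_warping_increases_spatial_autocorrelation(self):
        # The double trilinear interpolation smooths white noise, raising
        # lag-1 neighbour correlation — the mechanism behind standard-space
        # density inflation.
        rng = np.random.default_rng(5)
        A = np.eye(4)
        A[:3, 3] = [0.5, 0.5, 0.5]

        def lag1(data):
            a = data[:-1].ravel()
            b = data[1:].ravel()
            return np.corrcoef(a, b)[0, 1]

        higher = 0
        trials = 6
        for _ in range(trials):
            v = BoldVolume(data=rng.normal(size=(10, 10, 6, 2)))
            out = normalize_then_resample(v, A)
            if lag1(out.data[..., 0]) > lag1(v.data[..., 0]):
                higher += 1
        assert higher == trials

    def test_singular_affine_rejected(self, rng):
        v = BoldVolume(data=rng.normal(size=(4, 4, 2, 2)))
        with pytest.raises(ValueError):
            normalize_then_resample(v, np.zeros((4, 4)))
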