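import numpy as np
import pytest

from memkymo.io_stacks import InputError
from memkymo.kymograph import (
    Kymograph,
    assemble,
    build_kymograph,
    lowess_columns,
    mean_intensity_timeseries,
    percentile_normalize,
)
from memkymo.sampling import MembraneProfile


def _profile(values, t=0):
    values = np.asarray(values, dtype=float)
    lines = np.zeros((len(values), 1, 2))
    return MembraneProfile(values=values, sample_lines=lines, frame_index=t)


class TestAssemble:
    def test_constant_frames_give_constant_columns(self):
        profiles = [_profile(np.full(37 + 5 * t, 10.0 * (t + 1)), t) for t in range(3)]
        raw = assemble(profiles, n_rows=50)
        for t in range(3):
            np.testing.assert_allclose(raw[:, t], 10.0 * (t + 1))

    def test_identity_when_already_n_rows(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, 64)
        raw = assemble([_profile(v), _profile(v[::-1])], n_rows=64)
        np.testing.assert_allclose(raw[:, 0], v, atol=1e-12)
        np.testing.assert_allclose(raw[:, 1], v[::-1], atol=1e-12)

    def test_default_rows_from_frame_zero(self):
        raw = assemble([_profile(np.ones(80)), _profile(np.ones(95))])
        assert raw.shape == (80, 2)

    def test_sine_resampling_matches_analytic(self):
        u100 = np.arange(100) / 100
        u80 = np.arange(80) / 80
        sine = np.sin(2 * np.pi * u100)
        raw = assemble([_profile(sine), _profile(sine)], n_rows=80)
        np.testing.assert_allclose(raw[:, 0], np.sin(2 * np.pi * u80), atol=0.01)

    def test_periodic_wrap_interpolation(self):
        # value sequence with a jump only across the seam: target positions
        # between the last source knot and 1.0 must blend toward value[0]
        v = np.arange(4.0)  # u = 0, .25, .5, .75
        raw = assemble([_profile(v), _profile(v)], n_rows=8)
        assert raw[7, 0] == pytest.approx(1.5)  # u=7/8 halfway from 3 to 0


class TestLowessColumns:
    def test_constant_column_unchanged(self):
        raw = np.full((50, 3), 4.2)
        np.testing.assert_allclose(lowess_columns(raw, 0.2), raw, atol=1e-10)

    def test_linear_column_unchanged_interior(self):
        col = np.linspace(0, 10, 100)
        raw = np.column_stack([col, col])
        sm = lowess_columns(raw, 0.1)
        np.testing.assert_allclose(sm[5:-5], raw[5:-5], atol=1e-8)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        col = np.linspace(0, 10, 200)
        noisy = col + rng.normal(0, 1, 200)
        sm = lowess_columns(noisy[:, None], 0.1)[:, 0]
        assert np.std(sm - col) < np.std(noisy - col)

    def test_window_too_small_raises(self):
        with pytest.raises(InputError, match="window"):
            lowess_columns(np.ones((10, 2)), 0.1)

    def test_circular_option_smooths_across_seam(self):
        # a smooth circular signal sampled so the seam falls mid-slope:
        # plain LOWESS biases the endpoints, circular padding does not
        u = np.arange(128) / 128
        col = np.sin(2 * np.pi * (u + 0.2))
        sm_circ = lowess_columns(col[:, None], 0.1, circular=True)[:, 0]
        sm_flat = lowess_columns(col[:, None], 0.1, circular=False)[:, 0]
        err_circ = max(abs(sm_circ[0] - col[0]), abs(sm_circ[-1] - col[-1]))
        err_flat = max(abs(sm_flat[0] - col[0]), abs(sm_flat[-1] - col[-1]))
        assert err_circ <= err_flat + 1e-12


def manual_percentile(values, p):
    """Linear interpolation between order statistics (independent oracle)."""
    v = np.sort(np.asarray(values).ravel())
    h = (len(v) - 1) * p / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestPercentileNormalize:
    def test_uniform_ramp_midpoint(self):
        vals = np.arange(101.0).reshape(101, 1)
        raw = np.column_stack([vals, vals])
        norm, lo, hi = percentile_normalize(raw, raw)
        assert lo == pytest.approx(manual_percentile(raw, 2))
        assert hi == pytest.approx(manual_percentile(raw, 98))
        assert norm[50, 0] == pytest.approx((50 - lo) / (hi - lo))

    def test_constant_matrix_zeros_with_warning(self):
        raw = np.full((20, 4), 3.0)
        with pytest.warns(UserWarning, match="degenerate"):
            norm, lo, hi = percentile_normalize(raw, raw)
        assert np.all(norm == 0)

    def test_clipping_to_unit_interval(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(0, 100, (50, 10))
        smoothed = raw + rng.normal(0, 20, raw.shape)
        norm, lo, hi = percentile_normalize(raw, smoothed)
        assert norm.min() >= 0.0 and norm.max() <= 1.0
        above = smoothed > hi
        assert np.all(norm[above] == 1.0)

    def test_anchors_match_oracle_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            raw = rng.normal(50, 12, (30, 8))
            _, lo, hi = percentile_normalize(raw, raw)
            assert lo == pytest.approx(manual_percentile(raw, 2), abs=1e-10)
            assert hi == pytest.approx(manual_percentile(raw, 98), abs=1e-10)

    def test_renormalizing_unit_matrix_is_identity(self):
        rng = np.random.default_rng(4)
        norm = rng.uniform(0, 1, (40, 6))
        anchors = np.zeros_like(norm)
        anchors[0, 0], anchors[1, 0] = 0.0, 1.0
        # anchors 0/1: renormalization must be the identity
        renorm = np.clip((norm - 0.0) / (1.0 - 0.0), 0, 1)
        np.testing.assert_array_equal(renorm, norm)

    def test_shape_mismatch_raises(self):
        with pytest.raises(InputError, match="shape"):
            percentile_normalize(np.ones((3, 3)), np.ones((4, 3)))


class TestMeanIntensityTimeseries:
    def _kymo(self, raw):
        return Kymograph(
            raw=raw, smoothed=raw, normalized=np.clip(raw, 0, 1),
            norm_lo=0, norm_hi=1,
        )

    def test_constant_columns(self):
        raw = np.tile(np.array([1.0, 2.0, 3.0]), (10, 1))
        np.testing.assert_allclose(
            mean_intensity_timeseries(self._kymo(raw), "raw"), [1, 2, 3]
        )

    def test_normalized_series_bounded(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(-1, 2, (20, 5))
        series = mean_intensity_timeseries(self._kymo(raw), "normalized")
        assert series.min() >= 0 and series.max() <= 1

    def test_bad_selector(self):
        with pytest.raises(InputError):
            mean_intensity_timeseries(self._kymo(np.ones((4, 4))), "smoothed")


def test_build_kymograph_shapes_and_range():
    rng = np.random.default_rng(6)
    profiles = [
        _profile(rng.uniform(10, 100, 90 + rng.integers(-5, 6)), t)
        for t in range(6)
    ]
    k = build_kymograph(profiles, n_rows=64)
    assert k.raw.shape == k.smoothed.shape == k.normalized.shape == (64, 6)
    assert 0 <= k.normalized.min() and k.normalized.max() <= 1
    assert k.norm_lo <= k.norm_hi
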