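"""Per-stride double integration and the cumulative distance update."""

import numpy as np
import pytest

from gaitkit import (
    DegenerateVerticalError,
    DistanceParams,
    NoStridesError,
    estimate_distance,
    integrate_stride,
    mask_acceleration,
)
from gaitkit.segmentation import StrideSegment


def seg(start, stop, fs=50.0):
    return StrideSegment.from_indices(start, stop, fs)


def loop_double_sum(a, dt):
    """Brute-force rectangular double sum: v[k] = sum_{j<=k} a[j] dt, d = sum v[k] dt."""
    v = 0.0
    d = 0.0
    for ak in a:
        v += ak * dt
        d += v * dt
    return d


def test_mask_acceleration_gates_samples():
    ax = np.array([[5.0, 0, 0], [2, 0, 0], [3, 0, 0], [7, 0, 0]])
    out = mask_acceleration(ax, np.array([0, 1, 1, 0]))
    np.testing.assert_array_equal(out[:, 0], [0, 2, 3, 0])
    np.testing.assert_array_equal(
        mask_acceleration(ax, np.ones(4, dtype=int)), ax
    )
    np.testing.assert_array_equal(
        mask_acceleration(ax, np.zeros(4, dtype=int)), np.zeros((4, 3))
    )


def test_mask_acceleration_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        mask_acceleration(np.zeros((4, 3)), np.zeros(5))


def test_constant_acceleration_double_sum():
    """a[k] = 2 m/s^2 over 50 samples at 50 Hz gives dMAG = 1.02 m."""
    series = np.tile([0.0, 0.0, 2.0], (50, 1))
    out = integrate_stride(series, seg(0, 50), fs=50.0)
    assert out.d_mag == pytest.approx(1.02, rel=1e-12)
    assert out.dz == pytest.approx(1.02, rel=1e-12)
    assert not out.flagged
    assert out.ratio == pytest.approx(1.0, rel=1e-12)


def test_zero_acceleration_is_flagged():
    out = integrate_stride(np.zeros((30, 3)), seg(0, 30), fs=50.0)
    assert out.d_mag == 0.0
    assert out.dz == 0.0
    assert out.flagged
    assert np.isnan(out.ratio)


def test_double_sums_match_loop_oracle_on_random_inputs():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(5, 80))
        series = rng.normal(0, 4, (n, 3))
        out = integrate_stride(series, seg(0, n), fs=50.0)
        dt = 1.0 / 50
        a_mag = np.sqrt((series**2).sum(axis=1))
        assert out.d_mag == pytest.approx(loop_double_sum(a_mag, dt), rel=1e-12)
        assert out.dz == pytest.approx(loop_double_sum(series[:, 2], dt), rel=1e-12)


def test_half_sine_vertical_profile_matches_loop_oracle():
    n, fs = 20, 50.0
    az = np.sin(np.pi * np.arange(n) / n)  # lift-and-land acceleration pulse
    series = np.column_stack([np.zeros(n), np.zeros(n), az])
    out = integrate_stride(series, seg(0, n), fs=fs)
    assert out.dz == pytest.approx(loop_double_sum(az, 1 / fs), rel=1e-12)


def test_empty_or_out_of_bounds_segment_rejected():
    with pytest.raises(ValueError):
        integrate_stride(np.zeros((10, 3)), seg(5, 5), fs=50.0)
    with pytest.raises(ValueError):
        integrate_stride(np.zeros((10, 3)), seg(5, 20), fs=50.0)


def _two_axis_series(n, ratio_value, c=2.0):
    """Series whose stride ratio is exactly ``ratio_value``: az = c and the
    horizontal magnitude chosen so |a| = ratio_value * c."""
    horiz = c * np.sqrt(ratio_value**2 - 1.0)
    return np.tile([horiz, 0.0, c], (n, 1))


def test_online_update_arithmetic():
    """One stride with dMAG/dz = 2, K = 1, L0 = 0.26 gives d[1] = 2.26."""
    series = _two_axis_series(50, 2.0)
    est = estimate_distance(
        series, [seg(0, 50)], DistanceParams(K=1.0, L0=0.26), fs=50.0
    )
    assert est.total_distance == pytest.approx(2.26, rel=1e-12)
    assert est.stride_count == 1


def test_identical_strides_scale_linearly():
    """N strides of common ratio r total K*N*r + N*L0."""
    n, r, K, L0 = 40, 3.0, 0.7, 0.26
    series = np.concatenate([_two_axis_series(n, r)] * 4)
    segments = [seg(i * n, (i + 1) * n) for i in range(4)]
    est = estimate_distance(series, segments, DistanceParams(K=K, L0=L0), fs=50.0)
    assert est.total_distance == pytest.approx(K * 4 * r + 4 * L0, rel=1e-12)


def test_recursive_total_equals_batch_closed_form():
    rng = np.random.default_rng(1)
    series = rng.normal(0, 3, (400, 3)) + np.array([0, 0, 2.0])
    segments = [seg(10, 50), seg(80, 130), seg(200, 235), seg(300, 390)]
    params = DistanceParams(K=1.3, L0=0.26)
    est = estimate_distance(series, segments, params, fs=50.0)
    ratios = [sd.ratio_used for sd in est.per_stride]
    batch = params.K * sum(ratios) + len(segments) * params.L0
    assert est.total_distance == pytest.approx(batch, rel=1e-12)
    # cumulative distances are non-decreasing and end at the total
    cum = [sd.cumulative_distance for sd in est.per_stride]
    assert all(b >= a for a, b in zip(cum, cum[1:]))
    assert cum[-1] == est.total_distance


def test_total_is_monotone_in_K_and_L0():
    series = _two_axis_series(50, 2.0)
    segments = [seg(0, 50)]
    base = estimate_distance(series, segments, DistanceParams(K=1, L0=0.26), 50.0)
    more_k = estimate_distance(series, segments, DistanceParams(K=2, L0=0.26), 50.0)
    more_l = estimate_distance(series, segments, DistanceParams(K=1, L0=0.30), 50.0)
    assert more_k.total_distance > base.total_distance
    assert more_l.total_distance > base.total_distance


def test_estimator_is_amplitude_scale_invariant():
    """Scaling all acceleration by c > 0 scales dMAG and dz alike, so the
    ratio — and the calibrated distance — is unchanged."""
    rng = np.random.default_rng(9)
    series = rng.normal(0, 3, (200, 3)) + np.array([0, 0, 1.5])
    segments = [seg(20, 60), seg(100, 150)]
    params = DistanceParams(K=1.1, L0=0.26)
    a = estimate_distance(series, segments, params, 50.0)
    b = estimate_distance(series * 37.5, segments, params, 50.0)
    assert b.total_distance == pytest.approx(a.total_distance, rel=1e-12)
    for sa, sb in zip(a.per_stride, b.per_stride):
        assert sb.integrals.d_mag == pytest.approx(37.5 * sa.integrals.d_mag, rel=1e-12)
        assert sb.integrals.dz == pytest.approx(37.5 * sa.integrals.dz, rel=1e-12)


def test_masked_stance_samples_contribute_nothing():
    rng = np.random.default_rng(4)
    series = rng.normal(0, 3, (100, 3))
    mask = np.zeros(100, dtype=int)
    mask[30:70] = 1
    masked = mask_acceleration(series, mask)
    full = integrate_stride(masked, seg(30, 70), 50.0)
    direct = integrate_stride(series, seg(30, 70), 50.0)
    assert full.d_mag == pytest.approx(direct.d_mag, rel=1e-12)
    # everything outside the segment is exactly zero after masking
    assert np.all(masked[:30] == 0) and np.all(masked[70:] == 0)


def test_flagged_stride_uses_median_ratio_of_unflagged():
    n = 40
    good1 = _two_axis_series(n, 2.0)
    good2 = _two_axis_series(n, 4.0)
    dead = np.zeros((n, 3))
    series = np.concatenate([good1, dead, good2])
    segments = [seg(0, n), seg(n, 2 * n), seg(2 * n, 3 * n)]
    est = estimate_distance(series, segments, DistanceParams(K=1, L0=0.0), 50.0)
    assert est.per_stride[1].integrals.flagged
    assert est.per_stride[1].ratio_used == pytest.approx(3.0, rel=1e-12)  # median(2, 4)
    assert est.total_distance == pytest.approx(2 + 3 + 4, rel=1e-12)


def test_no_segments_raises():
    with pytest.raises(NoStridesError, match="no strides"):
        estimate_distance(np.zeros((10, 3)), [], DistanceParams(), 50.0)


def test_all_flagged_raises_degenerate():
    with pytest.raises(DegenerateVerticalError, match="degenerate"):
        estimate_distance(np.zeros((50, 3)), [seg(5, 25)], DistanceParams(), 50.0)
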