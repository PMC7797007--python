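import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eprime.motion import (
    AcquisitionGeometry,
    MotionState,
    channel_direction,
    effective_temporal_resolution,
    load_segment_velocity_table,
    reconstruction_weights,
    sample_mpsf_ensemble,
    segment_velocity,
    synthesize_mpsf,
)
from eprime.phantom import GeometryError, GridSpec


def brute_force_kernel(motion, geom, grid, n_samples, size):
    """Independent dense point-cloud accumulation, re-derived from the model:

    each projection angle contributes its weight at the channel-projected
    displacement ``(v . s) t s`` with per-subset local time, bilinearly split
    over the four neighbouring pixels.
    """
    h = grid.hyper_pixel_size
    k = geom.n_sources * geom.n_segments
    omega = 2.0 * math.pi / geom.rotation_time
    out = np.zeros((size, size))
    c = (size - 1) / 2.0
    v = motion.speed * np.array([math.cos(motion.direction),
                                 math.sin(motion.direction)])
    for i in range(n_samples):
        u = (i + 0.5) / n_samples
        theta = motion.start_angle + u * geom.recon_span
        subset = min(int(u * k), k - 1)
        t = (theta - (motion.start_angle + subset * geom.recon_span / k)) / omega
        s = np.array([math.sin(theta), -math.cos(theta)])
        p = (v @ s) * t * s
        gx, gy = p[0] / h + c, p[1] / h + c
        x0, y0 = int(math.floor(gx)), int(math.floor(gy))
        fx, fy = gx - x0, gy - y0
        out[y0, x0] += (1 - fx) * (1 - fy)
        out[y0, x0 + 1] += fx * (1 - fy)
        out[y0 + 1, x0] += (1 - fx) * fy
        out[y0 + 1, x0 + 1] += fx * fy
    return out / out.sum()


class TestChannelDirection:
    def test_reference_angles(self):
        np.testing.assert_allclose(channel_direction(0.0), [0.0, -1.0], atol=1e-15)
        np.testing.assert_allclose(channel_direction(math.pi / 2), [1.0, 0.0],
                                   atol=1e-15)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(theta=st.floats(-10.0, 10.0))
    def test_unit_norm(self, theta):
        assert np.linalg.norm(channel_direction(theta)) == pytest.approx(1.0)


class TestReconstructionWeights:
    def test_uniform_equal_weights(self):
        np.testing.assert_allclose(
            reconstruction_weights(np.linspace(0, math.pi, 4)), [0.25] * 4
        )

    def test_smooth_transition_tapers_endpoints(self):
        w = reconstruction_weights(np.linspace(0, math.pi, 64), "smooth-transition")
        assert w[0] < w[32]
        assert w[-1] < w[32]
        assert w.sum() == pytest.approx(1.0)

    def test_empty_angles_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_weights(np.array([]))


class TestEffectiveTemporalResolution:
    def test_half_scan_formula(self):
        geom = AcquisitionGeometry(rotation_time=0.33)
        assert effective_temporal_resolution(geom) == pytest.approx(165.0)

    def test_dual_source_halves_window(self):
        single = AcquisitionGeometry(rotation_time=0.33)
        dual = AcquisitionGeometry(rotation_time=0.33, n_sources=2)
        assert effective_temporal_resolution(dual) == pytest.approx(
            effective_temporal_resolution(single) / 2.0
        )
        assert effective_temporal_resolution(dual) == pytest.approx(82.5)

    def test_segments_and_sources_are_symmetric(self):
        a = AcquisitionGeometry(rotation_time=0.30, n_sources=2, n_segments=1)
        b = AcquisitionGeometry(rotation_time=0.30, n_sources=1, n_segments=2)
        assert effective_temporal_resolution(a) == effective_temporal_resolution(b)


class TestSynthesizeMpsf:
    def test_zero_speed_gives_central_delta(self, grid):
        k = synthesize_mpsf(MotionState(speed=0.0), AcquisitionGeometry(0.33), grid)
        c = k.values.shape[0] // 2
        assert k.values[c, c] == pytest.approx(1.0)

    def test_kernel_normalised_and_nonnegative(self, grid):
        k = synthesize_mpsf(
            MotionState(speed=30.0, direction=1.1, start_angle=0.4),
            AcquisitionGeometry(0.33), grid,
        )
        assert k.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert k.values.min() >= 0.0

    def test_support_bounded_by_speed_times_duration(self):
        grid = GridSpec(clinical_pixel_size=0.45, field_of_view=18.0)
        geom = AcquisitionGeometry(rotation_time=0.5)  # half-scan: 0.25 s window
        k = synthesize_mpsf(MotionState(speed=30.0, direction=0.2,
                                        start_angle=1.3), geom, grid)
        h = grid.hyper_pixel_size
        ys, xs = np.nonzero(k.values > 0)
        c = (k.values.shape[0] - 1) / 2.0
        max_mm = max(np.hypot(ys - c, xs - c)) * h
        assert max_mm <= 30.0 * 0.25 + h

    def test_dual_source_support_strictly_smaller(self, grid):
        m = MotionState(speed=30.0, direction=0.9, start_angle=2.0)
        single = synthesize_mpsf(m, AcquisitionGeometry(0.33), grid)
        dual = synthesize_mpsf(m, AcquisitionGeometry(0.33, n_sources=2), grid)

        def extent(k):
            ys, xs = np.nonzero(k.values > 1e-12)
            c = (k.values.shape[0] - 1) / 2.0
            return np.hypot(ys - c, xs - c).max()

        assert extent(dual) < extent(single)

    @pytest.mark.parametrize("n_sources,n_segments", [(1, 1), (2, 1), (1, 2)])
    def test_matches_brute_force_accumulation(self, grid, n_sources, n_segments):
        geom = AcquisitionGeometry(0.33, n_sources=n_sources, n_segments=n_segments)
        m = MotionState(speed=25.0, direction=0.7, start_angle=2.1)
        k = synthesize_mpsf(m, geom, grid, n_angle_samples=1024)
        bf = brute_force_kernel(m, geom, grid, 100_000, k.values.shape[0])
        assert np.abs(k.values - bf).sum() < 0.01

    def test_vanishing_span_gives_delta_at_any_speed(self, grid):
        geom = AcquisitionGeometry(0.33, recon_span=1e-6)
        k = synthesize_mpsf(MotionState(speed=35.0, direction=0.3), geom, grid)
        c = k.values.shape[0] // 2
        assert k.values[c, c] == pytest.approx(1.0, abs=1e-4)

    def test_support_exceeding_grid_fails(self):
        grid = GridSpec(clinical_pixel_size=0.45, field_of_view=3.0)
        with pytest.raises(GeometryError):
            synthesize_mpsf(MotionState(speed=35.0), AcquisitionGeometry(0.5), grid)


class TestEnsemble:
    def test_seeded_reproducibility(self, grid):
        geom = AcquisitionGeometry(0.33)
        a = sample_mpsf_ensemble(20.0, geom, grid, n=5, seed=99)
        b = sample_mpsf_ensemble(20.0, geom, grid, n=5, seed=99)
        for ka, kb in zip(a, b):
            np.testing.assert_array_equal(ka.values, kb.values)

    def test_zero_speed_members_identical(self, grid):
        ks = sample_mpsf_ensemble(0.0, AcquisitionGeometry(0.33), grid, n=4, seed=1)
        for k in ks[1:]:
            np.testing.assert_array_equal(k.values, ks[0].values)

    def test_mean_kernel_isotropy_improves_with_ensemble_size(self, grid):
        geom = AcquisitionGeometry(0.33)

        def anisotropy(n, seed):
            ks = sample_mpsf_ensemble(20.0, geom, grid, n=n, seed=seed,
                                      n_angle_samples=256)
            size = max(k.values.shape[0] for k in ks)
            acc = np.zeros((size, size))
            for k in ks:
                o = (size - k.values.shape[0]) // 2
                acc[o:o + k.values.shape[0], o:o + k.values.shape[0]] += k.values
            acc /= acc.sum()
            c = (size - 1) / 2.0
            ii = np.arange(size) - c
            xx, yy = np.meshgrid(ii, ii)
            cov = np.array([
                [(acc * xx * xx).sum(), (acc * xx * yy).sum()],
                [(acc * xx * yy).sum(), (acc * yy * yy).sum()],
            ])
            ev = np.linalg.eigvalsh(cov)
            return ev[1] / max(ev[0], 1e-12)  # 1 = isotropic

        assert abs(anisotropy(400, 7) - 1.0) < abs(anisotropy(20, 7) - 1.0)


class TestSegmentVelocity:
    def test_default_table_spans_stated_range_for_resting_rates(self):
        table = load_segment_velocity_table()
        for _, row in table.iterrows():
            for hr in (50.0, 75.0, 100.0):
                v = segment_velocity(hr, row["sex"], row["segment_id"], table)
                assert 15.0 <= v <= 35.0

    def test_monotone_in_heart_rate(self):
        v1 = segment_velocity(55.0, "F", "mid-RCA")
        v2 = segment_velocity(95.0, "F", "mid-RCA")
        assert v2 >= v1

    def test_custom_table_affine_mapping(self):
        import pandas as pd

        table = pd.DataFrame([{
            "sex": "F", "segment_id": "x", "v_at_60bpm_mm_s": 20.0,
            "slope_mm_s_per_bpm": 0.2,
        }])
        assert segment_velocity(70.0, "F", "x", table) == pytest.approx(22.0)

    def test_unknown_segment_rejected(self):
        with pytest.raises(KeyError):
            segment_velocity(60.0, "F", "nope")
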