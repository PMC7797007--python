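import numpy as np
import pytest

from eprime.imaging import (
    TTFCurve,
    apply_blur,
    compose_instance,
    downsample,
    generate_correlated_noise,
    parametric_nps,
    parametric_ttf,
    ttf_to_psf,
)
from eprime.motion import AcquisitionGeometry, MotionState, synthesize_mpsf
from eprime.phantom import VesselSpec, render_cross_section


def ideal_ttf() -> TTFCurve:
    """All-pass transfer curve (identity system)."""
    return TTFCurve(frequencies=np.array([0.0, 100.0]), mtf=np.array([1.0, 1.0]),
                    f50=5.0)


class TestParametricTTF:
    @pytest.mark.parametrize("shape", ["gaussian", "sigmoid"])
    def test_pinned_at_dc_and_f50(self, shape):
        ttf = parametric_ttf(0.40, shape=shape)
        assert ttf(0.0) == pytest.approx(1.0)
        assert ttf(0.40) == pytest.approx(0.5, abs=1e-6)

    def test_sharper_system_lies_above(self):
        lo, hi = parametric_ttf(0.32), parametric_ttf(0.52)
        f = np.linspace(0.05, 1.0, 40)
        assert np.all(hi(f) > lo(f))


class TestTtfToPsf:
    def test_ideal_ttf_gives_delta(self, grid):
        psf = ttf_to_psf(ideal_ttf(), grid)
        c = psf.values.shape[0] // 2
        assert psf.values[c, c] == pytest.approx(1.0)

    @pytest.mark.parametrize("f50", [0.32, 0.52])
    def test_round_trip_mtf_within_two_percent(self, grid, f50):
        ttf = parametric_ttf(f50)
        psf = ttf_to_psf(ttf, grid)
        size = psf.values.shape[0]
        amp = np.abs(np.fft.fft2(np.fft.ifftshift(psf.values)))
        fx = np.fft.fftfreq(size, d=psf.pixel_size)
        fr = np.hypot(fx[:, None], fx[None, :])
        nyquist_clinical = 0.5 / grid.clinical_pixel_size
        mask = fr <= nyquist_clinical
        assert np.max(np.abs(amp[mask] - ttf(fr[mask]))) < 0.02

    def test_lower_f50_has_wider_psf(self, grid):
        def fwhm(psf):
            c = psf.values.shape[0] // 2
            row = psf.values[c]
            return (row >= row.max() / 2).sum()

        assert fwhm(ttf_to_psf(parametric_ttf(0.32), grid)) > fwhm(
            ttf_to_psf(parametric_ttf(0.52), grid)
        )


class TestApplyBlur:
    def test_delta_kernel_identity(self, grid, vessel):
        img = render_cross_section(vessel, grid).values
        psf = ttf_to_psf(ideal_ttf(), grid)
        np.testing.assert_allclose(
            apply_blur(img, psf, grid.hyper_pixel_size), img, atol=1e-9
        )

    def test_mean_preserved(self, grid, vessel):
        img = render_cross_section(vessel, grid).values
        psf = ttf_to_psf(parametric_ttf(0.40), grid)
        out = apply_blur(img, psf, grid.hyper_pixel_size)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-6)

    def test_blur_order_commutes(self, grid, vessel):
        img = render_cross_section(vessel, grid).values
        psf = ttf_to_psf(parametric_ttf(0.40), grid)
        mk = synthesize_mpsf(MotionState(speed=20.0, direction=0.5),
                             AcquisitionGeometry(0.33), grid)
        a = apply_blur(apply_blur(img, psf, grid.hyper_pixel_size), mk,
                       grid.hyper_pixel_size)
        b = apply_blur(apply_blur(img, mk, grid.hyper_pixel_size), psf,
                       grid.hyper_pixel_size)
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-6)

    def test_pixel_size_mismatch_rejected(self, grid, vessel):
        img = render_cross_section(vessel, grid).values
        psf = ttf_to_psf(parametric_ttf(0.40), grid)
        with pytest.raises(ValueError, match="pixel size"):
            apply_blur(img, psf, grid.clinical_pixel_size)


class TestDownsample:
    def test_constant_preserved(self):
        out = downsample(np.full((40, 40), 7.5), 10)
        np.testing.assert_allclose(out, 7.5)
        assert out.shape == (4, 4)

    def test_factor_one_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(downsample(img, 1), img)

    def test_checkerboard_block_means(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 * 2.0  # 0/2 checkerboard
        np.testing.assert_allclose(downsample(img, 2), np.full((2, 2), 1.0))

    def test_non_divisible_shape_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros((30, 30)), 7)


class TestCorrelatedNoise:
    def test_zero_sigma_gives_zero_field(self, rng):
        nps = parametric_nps(0.25, sigma=0.0)
        assert not generate_correlated_noise(nps, (32, 32), rng, 0.45).any()

    def test_sample_sd_matches_sigma_exactly(self, rng):
        nps = parametric_nps(0.25, sigma=37.0)
        field = generate_correlated_noise(nps, (48, 48), rng, 0.45)
        assert field.std() == pytest.approx(37.0, abs=1e-12)
        assert field.mean() == pytest.approx(0.0, abs=1e-12)

    def test_flat_nps_is_white(self):
        rng = np.random.default_rng(7)
        nps = parametric_nps(0.25, sigma=10.0, shape="flat")
        n_fields, N = 200, 32
        lag1 = []
        for _ in range(n_fields):
            f = generate_correlated_noise(nps, (N, N), rng, 0.45)
            lag1.append(np.mean(f[:, :-1] * f[:, 1:]) / f.var())
        assert abs(np.mean(lag1)) < 3.0 / np.sqrt(n_fields * N * N)

    def test_disjoint_seeds_uncorrelated(self):
        nps = parametric_nps(0.25, sigma=20.0)
        a = generate_correlated_noise(nps, (64, 64), np.random.default_rng(1), 0.45)
        b = generate_correlated_noise(nps, (64, 64), np.random.default_rng(2), 0.45)
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert abs(r) < 3.0 / 64.0

    def test_density_normalised_to_unit_2d_integral(self):
        nps = parametric_nps(0.25, sigma=30.0)
        area = np.trapezoid(nps.density * 2 * np.pi * nps.frequencies,
                            nps.frequencies)
        assert area == pytest.approx(1.0)


class TestComposeInstance:
    def test_identity_chain_equals_downsampled_phantom(self, grid, vessel):
        phantom = render_cross_section(vessel, grid)
        inst = compose_instance(phantom, ideal_ttf(), None,
                                parametric_nps(0.25, sigma=0.0))
        np.testing.assert_allclose(
            inst.values, downsample(phantom.values, grid.hyper_factor), atol=1e-9
        )

    def test_fixed_seed_bit_identical(self, grid, vessel):
        phantom = render_cross_section(vessel, grid)
        mk = synthesize_mpsf(MotionState(speed=15.0, direction=1.0),
                             AcquisitionGeometry(0.33), grid)
        args = (phantom, parametric_ttf(0.4), mk, parametric_nps(0.25, sigma=25.0))
        a = compose_instance(*args, rng=np.random.default_rng(3))
        b = compose_instance(*args, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_only_instance_has_sd_sigma(self, grid, rng):
        flat = render_cross_section(
            VesselSpec(reference_lumen_diameter=3.0, stenosis_fraction=0.5,
                       lumen_hu=0.0, wall_hu=0.0, plaque_hu=0.0,
                       background_hu=0.0),
            grid,
        )
        flat.values[:] = 0.0
        inst = compose_instance(flat, None, None, parametric_nps(0.25, sigma=22.0),
                                rng=rng)
        assert inst.values.std() == pytest.approx(22.0, abs=1e-12)

    def test_chain_linear_in_phantom(self, grid, vessel):
        phantom = render_cross_section(vessel, grid)
        other = render_cross_section(
            VesselSpec(reference_lumen_diameter=2.0, stenosis_fraction=0.3,
                       lumen_hu=300.0), grid,
        )
        ttf = parametric_ttf(0.4)
        mk = synthesize_mpsf(MotionState(speed=18.0, direction=0.2),
                             AcquisitionGeometry(0.33), grid)
        nps = parametric_nps(0.25, sigma=0.0)

        def chain(p):
            return compose_instance(p, ttf, mk, nps).values

        combo = phantom.values * 2.0 + other.values * -0.5
        mixed = render_cross_section(vessel, grid)
        mixed.values = combo
        np.testing.assert_allclose(
            chain(mixed), 2.0 * chain(phantom) - 0.5 * chain(other),
            rtol=1e-6, atol=1e-6,
        )
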