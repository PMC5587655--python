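import warnings

import numpy as np
import pytest
from scipy import stats

from rcrecon.acquisition import (ApertureSpec, DiscretizationError,
                                 ObservedEnvelope, SamplingMask,
                                 apply_psf, apply_speckle,
                                 arrival_cluster_count, build_psf_bank,
                                 forward_observe, gaussian_pulse,
                                 identity_psf_bank, interpolate_to_lattice,
                                 kernel_lateral_width, make_fanbeam_mask,
                                 one_way_sir, pulse_echo_psf, speckle_noise,
                                 uncertainty_layer)

C = 1540.0
DT = 5e-9


def small_aperture(**kw):
    return ApertureSpec(element_length=1e-3, element_width=1e-3, **kw)


class TestOneWaySIR:
    def test_first_arrival_time(self):
        d = 10e-3
        t = np.arange(0.0, 2 * d / C, DT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            h = one_way_sir(small_aperture(), (0.0, 0.0, d), t)
        first = np.nonzero(h)[0][0]
        assert t[first] == pytest.approx(d / C, abs=2 * DT)

    def test_mirror_symmetry(self):
        ap = ApertureSpec(element_length=4e-3, element_width=0.3e-3)
        t = np.arange(5e-6, 9e-6, DT)
        h1 = one_way_sir(ap, (1e-3, 2e-3, 9e-3), t, axis="y")
        h2 = one_way_sir(ap, (-1e-3, 2e-3, 9e-3), t, axis="y")  # across long axis
        h3 = one_way_sir(ap, (1e-3, -2e-3, 9e-3), t, axis="y")  # across short axis
        assert np.allclose(h1, h2, rtol=1e-9, atol=0)
        assert np.allclose(h1, h3, rtol=1e-9, atol=0)

    def test_far_field_time_integral(self):
        # quadrature oracle: integral of dS/(2 pi r) ~ S/(2 pi d) far away
        d = 50e-3
        ap = small_aperture()
        t = np.arange(0.9 * d / C, 1.2 * d / C, DT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            h = one_way_sir(ap, (0.0, 0.0, d), t)
        S = ap.element_length * ap.element_width
        assert h.sum() * DT == pytest.approx(S / (2 * np.pi * d), rel=0.01)

    def test_strict_mode_raises_on_coarse_grid(self):
        d = 50e-3
        t = np.arange(0.9 * d / C, 1.2 * d / C, 1e-6)  # 1 us bins
        with pytest.raises(DiscretizationError):
            one_way_sir(small_aperture(), (0.0, 0.0, d), t, strict=True)

    def test_on_plane_point_rejected(self):
        t = np.arange(0.0, 1e-5, DT)
        with pytest.raises(ValueError):
            one_way_sir(small_aperture(), (1e-3, 0.0, 0.0), t)


class TestPulseEcho:
    def test_support_is_sum_of_supports(self):
        ap = small_aperture()
        d = 8e-3
        t = np.arange(0.9 * d / C, 1.5 * d / C, DT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            h = one_way_sir(ap, (0.0, 0.0, d), t)
            times, rf, env = pulse_echo_psf(ap, ap, (0.0, 0.0, d), t)
        exc = gaussian_pulse(ap.center_frequency, 0.6, DT)
        nz = np.nonzero(np.abs(rf) > 1e-12 * np.abs(rf).max())[0]
        one_way_support = np.ptp(np.nonzero(h)[0])
        assert nz[-1] - nz[0] <= 2 * one_way_support + exc.size + 2

    def test_edge_wave_ghost_clusters(self):
        # long orthogonal line elements, off-axis scatterer: >= 2 arrivals
        ap = ApertureSpec()  # 4.8 mm x 0.12 mm line elements
        z = 5e-3
        t = np.arange(0.8 * z / C, 3.0 * z / C, DT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, _, env = pulse_echo_psf(ap, ap, (1.5e-3, 0.0, z), t)
        assert arrival_cluster_count(env, threshold_db=-30.0) >= 2

    def test_nonuniform_grid_rejected(self):
        ap = small_aperture()
        t = np.array([0.0, 1e-8, 3e-8, 4e-8])
        with pytest.raises(ValueError):
            pulse_echo_psf(ap, ap, (0.0, 0.0, 10e-3), t)


class TestPSFBank:
    def test_parametric_constant_sigma_identical_kernels(self):
        bank = build_psf_bank("parametric", [5.0, 15.0, 25.0], (0.1, 0.1),
                              sigma_lat=0.3, sigma_ax=0.2)
        for k in bank.kernels[1:]:
            assert np.array_equal(k, bank.kernels[0])

    def test_kernels_normalized(self):
        bank = build_psf_bank("parametric", [5.0, 25.0], (0.1, 0.1),
                              sigma_lat=[0.2, 0.5], sigma_ax=0.2)
        for k in bank.kernels:
            assert k.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_monotone_sigma_rejected(self):
        with pytest.raises(ValueError):
            build_psf_bank("parametric", [5.0, 25.0], (0.1, 0.1),
                           sigma_lat=[0.5, 0.2], sigma_ax=0.2)

    def test_width_monotone_with_depth(self):
        bank = build_psf_bank("parametric", [5.0, 15.0, 25.0], (0.1, 0.1),
                              sigma_lat=[0.2, 0.35, 0.5], sigma_ax=0.2)
        widths = [kernel_lateral_width(k, 0.1) for k in bank.kernels]
        assert np.all(np.diff(widths) >= 0)

    def test_ghost_replicas_added(self):
        bank = build_psf_bank("parametric", [10.0], (0.1, 0.1), sigma_lat=0.2,
                              sigma_ax=0.2, ghost_spec=[(1.0, 0.1), (2.0, 0.05)])
        eff = bank.effective_kernels()[0]
        assert eff.sum() == pytest.approx(1.15, abs=1e-9)
        assert eff.shape[0] > bank.kernels[0].shape[0]

    def test_sir_mode_width_ordering(self):
        bank = build_psf_bank("sir", [10.0, 25.0], (0.1, 0.1))
        w10 = kernel_lateral_width(bank.kernels[0], 0.1)
        w25 = kernel_lateral_width(bank.kernels[1], 0.1)
        assert w25 > w10


class TestApplyPSF:
    def test_identity_bank(self, small_image):
        assert np.array_equal(apply_psf(small_image, identity_psf_bank()),
                              small_image)

    def test_linearity(self, rng):
        bank = build_psf_bank("parametric", [0.0, 8.0], (1.0, 1.0),
                              sigma_lat=[0.8, 1.6], sigma_ax=0.8)
        f1 = rng.standard_normal((16, 16))
        f2 = rng.standard_normal((16, 16))
        lhs = apply_psf(2.0 * f1 - 3.0 * f2, bank)
        rhs = 2.0 * apply_psf(f1, bank) - 3.0 * apply_psf(f2, bank)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_adjoint_dot_product(self, rng):
        bank = build_psf_bank("parametric", [0.0, 16.0, 32.0], (1.0, 1.0),
                              sigma_lat=[0.8, 1.2, 2.0], sigma_ax=1.0,
                              ghost_spec=[(3.0, 0.1)])
        a = rng.standard_normal((32, 32))
        b = rng.standard_normal((32, 32))
        lhs = np.sum(apply_psf(a, bank) * b)
        rhs = np.sum(a * apply_psf(b, bank, adjoint=True))
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_kernel_larger_than_image_rejected(self):
        bank = build_psf_bank("parametric", [0.0], (1.0, 1.0), sigma_lat=3.0,
                              sigma_ax=3.0)
        with pytest.raises(ValueError):
            apply_psf(np.ones((4, 4)), bank)


class TestSpeckle:
    def test_log_variance(self):
        eps = speckle_noise((1000, 1000), 0.5, seed=1)
        assert eps.var() == pytest.approx(np.pi ** 2 / 24, rel=0.01)

    def test_variance_sigma_independent(self):
        for sigma in (0.1, 0.5, 2.0):
            eps = speckle_noise(200_000, sigma, seed=2)
            assert eps.var() == pytest.approx(np.pi ** 2 / 24, rel=0.02)

    def test_density_matches_gumbel_min(self):
        # 2 eps - ln(2 sigma^2) should follow pdf exp(u - e^u) exactly
        sigma = 0.7
        eps = speckle_noise(100_000, sigma, seed=3)
        u = 2.0 * eps - np.log(2.0 * sigma ** 2)
        ks = stats.kstest(u, stats.gumbel_l.cdf)
        assert ks.statistic < 0.01

    def test_seeded_determinism(self):
        f = np.full((16, 16), 2.0)
        assert np.array_equal(apply_speckle(f, 0.5, seed=9),
                              apply_speckle(f, 0.5, seed=9))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            apply_speckle(np.ones((4, 4)), 0.0, seed=1)

    def test_enl_stabilizes_for_constant_field(self):
        # fully developed speckle: ENL of the exponentiated envelope is a
        # region-size-independent constant for constant reflectivity
        rng = np.random.default_rng(17)
        env = np.exp(speckle_noise((400, 400), 0.5, rng=rng))
        quarters = [env[:200, :200], env[:200, 200:], env[200:, :200], env[200:, 200:]]
        enls = [q.mean() ** 2 / q.var() for q in quarters]
        assert np.ptp(enls) < 0.15 * np.mean(enls)


class TestFanbeamMask:
    def test_dense_beams_saturate(self):
        m = make_fanbeam_mask((16, 16), (1.0, 1.0), (10.0, -8.0), apex=(0.0, 0.0),
                              n_beams=720, angular_span=(-44.0, 44.0),
                              samples_per_beam=4000)
        assert m.values.all()
        assert not uncertainty_layer(m).any()

    def test_cr_complement(self):
        m = make_fanbeam_mask((64, 64), (1.0, 1.0), (1.0, -32.0), n_beams=9,
                              angular_span=(-30.0, 30.0), samples_per_beam=200)
        cr = uncertainty_layer(m)
        assert np.array_equal(cr, 1 - m.values)

    def test_halving_beams_decreases_coverage(self):
        kw = dict(pitch=(1.0, 1.0), origin=(1.0, -64.0), apex=(0.0, 0.0),
                  angular_span=(-40.0, 40.0), samples_per_beam=600)
        full = make_fanbeam_mask((128, 128), n_beams=64, **kw)
        half = make_fanbeam_mask((128, 128), n_beams=32, **kw)
        assert half.values.sum() < full.values.sum()

    def test_apex_inside_grid_rejected(self):
        with pytest.raises(ValueError):
            make_fanbeam_mask((16, 16), (1.0, 1.0), (0.0, -8.0), apex=(8.0, 0.0),
                              n_beams=4, angular_span=(-10.0, 10.0),
                              samples_per_beam=50)

    def test_mask_binary(self):
        with pytest.raises(ValueError):
            SamplingMask(values=np.full((4, 4), 2))


class TestForwardObserve:
    def test_noise_free_identity_is_log(self):
        f = np.full((8, 8), 3.0)
        obs = forward_observe(f, identity_psf_bank(), np.ones((8, 8), np.uint8),
                              sigma=None, seed=0)
        assert np.allclose(obs.values, np.log(3.0))

    def test_seeded_purity(self):
        f = np.ones((12, 12)) * 2.0
        mask = np.ones((12, 12), np.uint8)
        a = forward_observe(f, identity_psf_bank(), mask, 0.5, seed=4)
        b = forward_observe(f, identity_psf_bank(), mask, 0.5, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_clipping_warns(self):
        f = np.zeros((8, 8))
        with pytest.warns(RuntimeWarning, match="clipped"):
            forward_observe(f, identity_psf_bank(), np.ones((8, 8), np.uint8),
                            sigma=None)

    def test_cr_flags_unsampled(self):
        mask = np.zeros((6, 6), np.uint8)
        mask[::2] = 1
        obs = forward_observe(np.ones((6, 6)), identity_psf_bank(), mask,
                              sigma=None)
        assert np.array_equal(obs.cr, 1 - mask)


class TestInterpolateToLattice:
    def _obs(self, values, mask):
        return ObservedEnvelope(values=values * mask, mask=mask.astype(np.uint8),
                                cr=(1 - mask).astype(np.uint8), noise_sigma=None)

    def test_full_mask_identity(self, rng):
        v = rng.standard_normal((10, 10))
        out = interpolate_to_lattice(self._obs(v, np.ones((10, 10), int)))
        assert np.array_equal(out, v)

    def test_gap_midway_is_mean(self):
        v = np.zeros((3, 5))
        v[0] = 1.0
        v[2] = 3.0
        mask = np.zeros((3, 5), int)
        mask[0] = mask[2] = 1
        out = interpolate_to_lattice(self._obs(v, mask))
        assert np.allclose(out[1], 2.0)

    def test_no_undefined_values(self, rng):
        v = rng.standard_normal((20, 20))
        mask = (rng.uniform(size=(20, 20)) < 0.3).astype(int)
        mask[0, 0] = mask[-1, -1] = mask[0, -1] = 1
        out = interpolate_to_lattice(self._obs(v, mask))
        assert np.all(np.isfinite(out))

    def test_sampled_voxels_unchanged(self, rng):
        v = rng.standard_normal((15, 15))
        mask = (rng.uniform(size=(15, 15)) < 0.4).astype(int)
        mask[7, 7] = 1
        out = interpolate_to_lattice(self._obs(v, mask))
        assert np.array_equal(out[mask == 1], v[mask == 1])

    def test_too_few_samples_rejected(self):
        v = np.zeros((5, 5))
        mask = np.zeros((5, 5), int)
        mask[2, 2] = 1
        with pytest.raises(ValueError, match="1 sampled"):
            interpolate_to_lattice(self._obs(v, mask))

    def test_roundtrip_noiseless(self):
        # forward_observe then interpolate with full mask / identity / no
        # noise recovers log f exactly
        f = np.abs(np.random.default_rng(5).uniform(0.5, 4.0, (9, 9)))
        obs = forward_observe(f, identity_psf_bank(), np.ones((9, 9), np.uint8),
                              sigma=None)
        assert np.allclose(interpolate_to_lattice(obs), np.log(f))


class TestObservedEnvelopeValidation:
    def test_inconsistent_cr_rejected(self):
        with pytest.raises(ValueError):
            ObservedEnvelope(values=np.zeros((4, 4)), mask=np.ones((4, 4), np.uint8),
                             cr=np.ones((4, 4), np.uint8), noise_sigma=None)

    def test_nonfinite_sampled_rejected(self):
        vals = np.zeros((4, 4))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError):
            ObservedEnvelope(values=vals, mask=np.ones((4, 4), np.uint8),
                             cr=np.zeros((4, 4), np.uint8), noise_sigma=None)
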