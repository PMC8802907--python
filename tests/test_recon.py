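"""EPRY reconstruction: constraint exactness, update behavior, convergence,
shift equivariance, and parameter-recovery experiments."""

import numpy as np
import pytest
from numpy.fft import fft2, ifft2, fftshift, ifftshift
from scipy.stats import pearsonr

import fpmscope as fp
from fpmscope.optics import TWO_PI, make_pupil
from fpmscope.recon import _sweep_order

from conftest import RECOVERY_PIXEL_UM, RECOVERY_SHAPE, config_for, \
    single_led_plan


def decimate_field(img: np.ndarray, factor: int) -> np.ndarray:
    """Coherent (spectrum-crop) downsampling of a band-limited field."""
    n = img.shape[0]
    m = n // factor
    spec = fftshift(fft2(img))
    lo = n // 2 - m // 2
    return ifft2(ifftshift(spec[lo:lo + m, lo:lo + m])) / factor ** 2


def align_global_phase(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    z = (est * np.conj(ref)).sum()
    return est * np.exp(-1j * np.angle(z))


class TestIntensityConstraint:
    def test_magnitude_replaced_exactly(self):
        rng = np.random.default_rng(0)
        psi = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        ip = rng.uniform(0, 2, (16, 16))
        phi = fp.intensity_constraint(psi, ip)
        assert np.allclose(np.abs(phi) ** 2, ip, atol=1e-12)
        # phase is kept
        nz = np.abs(psi) > 0
        assert np.allclose(np.angle(phi[nz] / psi[nz]), 0.0, atol=1e-12)

    def test_fixed_point_when_model_matches_data(self):
        rng = np.random.default_rng(1)
        psi = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        phi = fp.intensity_constraint(psi, np.abs(psi) ** 2)
        assert np.allclose(phi, psi, atol=1e-12)

    def test_zero_field_pixels_become_real_positive(self):
        psi = np.zeros((4, 4), dtype=complex)
        ip = np.full((4, 4), 2.0)
        phi = fp.intensity_constraint(psi, ip)
        assert np.allclose(phi, np.sqrt(2.0))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            fp.intensity_constraint(np.ones((2, 2), complex),
                                    np.full((2, 2), -1.0))


class TestSubregionsAndUpdates:
    def _tiny_state(self, up=2, n=32):
        dx = 0.2
        cfg = config_for(0.25, 10, dx, 1)
        geom = fp.LEDArrayGeometry(used_rows=3, used_cols=3, pitch_mm=8)
        plan = fp.build_illumination_plan(geom, cfg.wavelength_um)
        obj = fp.ComplexObject(np.random.default_rng(0).uniform(.3, 1, (n, n)),
                               np.zeros((n, n)), dx)
        stack = fp.simulate_acquisition(obj, cfg, plan)
        opts = fp.ReconstructionOptions()
        return stack, fp.initialize_reconstruction(stack, up, opts), opts

    def test_subregion_centers_enumerate_plan_wavevectors(self):
        stack, state, _ = self._tiny_state()
        n, big = state.n_low, state.n_high
        centers = np.array([(big // 2 - ty - n // 2, big // 2 - tx - n // 2)
                            for ty, tx in state.windows])
        assert len(centers) == stack.n_images
        assert np.array_equal(centers, stack.shift_px)

    def test_constant_on_axis_image_initializes_to_dc_delta(self):
        dx = 0.2
        n = 16
        cfg = config_for(0.25, 10, dx, 1)
        plan = single_led_plan()
        stack = fp.RawStack(np.ones((1, n, n)), plan, cfg,
                            fp.AcquisitionOptions(), dx)
        state = fp.initialize_reconstruction(stack, 2,
                                             fp.ReconstructionOptions())
        spec = np.abs(state.spectrum)
        dc = spec[state.n_high // 2, state.n_high // 2]
        assert dc == pytest.approx(spec.sum(), rel=1e-9)

    def test_forward_subregion_of_flat_spectrum_is_pupil_transform(self):
        """With an all-ones spectrum window the modeled field equals the
        (explicit-DFT) inverse transform of the pupil disk."""
        stack, state, _ = self._tiny_state()
        state.spectrum[:] = 1.0
        m = 0
        _, psi = fp.forward_subregion(state, m)
        n = state.n_low
        idx = np.arange(n)
        w = np.exp(2j * np.pi * np.outer(idx, idx) / n)
        p_std = ifftshift(state.pupil.array)
        ref = (w @ p_std @ w.T) / (n * n) / state.upsampling ** 2
        assert np.allclose(psi, ref, atol=1e-8)

    def test_zero_spectrum_gives_zero_field(self):
        stack, state, _ = self._tiny_state()
        state.spectrum[:] = 0.0
        big_psi, psi = fp.forward_subregion(state, 0)
        assert not big_psi.any() and not psi.any()

    def test_pupil_bounded_filtering_never_gains_energy(self):
        stack, state, _ = self._tiny_state()
        n = state.n_low
        ty, tx = state.windows[3]
        window = state.spectrum[ty:ty + n, tx:tx + n]
        big_psi, _ = fp.forward_subregion(state, 3)
        assert (np.abs(big_psi) ** 2).sum() <= (np.abs(window) ** 2).sum()

    def test_converged_subregion_is_left_unchanged(self):
        stack, state, opts = self._tiny_state()
        big_psi, psi = fp.forward_subregion(state, 0)
        before_spec = state.spectrum.copy()
        before_pupil = state.pupil.array.copy()
        # phi == psi means delta Psi = 0: no update anywhere
        fp.gauss_newton_update(state, 0, psi, opts)
        assert np.allclose(state.spectrum, before_spec, atol=1e-12)
        assert np.allclose(state.pupil.array, before_pupil, atol=1e-12)

    def test_upsampling_too_small_rejected(self):
        dx = 0.2
        cfg = config_for(0.25, 10, dx, 1)
        geom = fp.LEDArrayGeometry(used_rows=9, used_cols=9, pitch_mm=8)
        plan = fp.build_illumination_plan(geom, cfg.wavelength_um)
        obj = fp.ComplexObject(np.ones((32, 32)), np.zeros((32, 32)), dx)
        stack = fp.simulate_acquisition(obj, cfg, plan)
        with pytest.raises(fp.ConfigurationError):
            fp.initialize_reconstruction(stack, 1, fp.ReconstructionOptions())


class TestReconstruct:
    def test_single_onaxis_image_with_allpass_pupil_returns_sqrt(self):
        """Degenerate N=1 case: the constraint is exact, so one sweep recovers
        amplitude = sqrt(I) of the measurement."""
        rng = np.random.default_rng(2)
        n, dx = 16, 0.2
        amp = rng.uniform(0.2, 1.0, (n, n))
        cfg = config_for(0.25, 10, dx, 1)
        plan = single_led_plan()
        stack = fp.RawStack(amp[None] ** 2, plan, cfg,
                            fp.AcquisitionOptions(), dx)
        flat = fp.PupilFunction.flat((n, n), TWO_PI / (n * dx),
                                     cfg.wavelength_um)
        res = fp.reconstruct(stack, upsampling=1,
                             options=fp.ReconstructionOptions(
                                 max_iterations=1, initial_pupil=flat,
                                 pupil_recovery=False))
        assert np.allclose(res.amplitude, amp, atol=1e-6)

    def test_constraint_exact_every_subregion_every_sweep(self):
        """|phi|^2 equals the measured intensity exactly at every visit."""
        n, dx = 32, 0.2
        cfg = config_for(0.25, 10, dx, 1)
        geom = fp.LEDArrayGeometry(used_rows=3, used_cols=3, pitch_mm=8)
        plan = fp.build_illumination_plan(geom, cfg.wavelength_um)
        obj, _ = fp.generate_chromosome_phantom(1, dx, seed=5, shape=(n, n),
                                                length_range_um=(2, 3))
        stack = fp.simulate_acquisition(obj, cfg, plan)
        order = []
        deviations = []

        def check(m, psi, phi):
            order.append(m)
            deviations.append(
                np.abs(np.abs(phi) ** 2 - stack.images[m]).max())

        fp.reconstruct(stack, upsampling=2,
                       options=fp.ReconstructionOptions(
                           max_iterations=3, tolerance=0.0, callback=check))
        assert len(order) == 3 * stack.n_images
        assert max(deviations) < 1e-12

    def test_residuals_monotone_with_known_pupil_on_noiseless_data(self):
        """Data residual is non-increasing over the first 10 sweeps on a
        64x64 phantom when the pupil is known and the data noiseless."""
        n, dx = 64, 0.2
        cfg = config_for(0.25, 10, dx, 1)
        geom = fp.LEDArrayGeometry(used_rows=9, used_cols=9)
        plan = fp.build_illumination_plan(geom, cfg.wavelength_um)
        obj, _ = fp.generate_chromosome_phantom(1, dx, seed=2, shape=(n, n),
                                                length_range_um=(5, 7))
        stack = fp.simulate_acquisition(obj, cfg, plan)
        res = fp.reconstruct(stack, upsampling=2,
                             options=fp.ReconstructionOptions(
                                 max_iterations=10, tolerance=0.0,
                                 pupil_recovery=False))
        r = np.asarray(res.residual_history)
        assert len(r) == 10
        assert np.all(np.diff(r) <= 1e-12)

    def test_reconstruction_is_deterministic(self):
        n, dx = 32, 0.2
        cfg = config_for(0.25, 10, dx, 1)
        geom = fp.LEDArrayGeometry(used_rows=3, used_cols=3, pitch_mm=8)
        plan = fp.build_illumination_plan(geom, cfg.wavelength_um)
        obj, _ = fp.generate_chromosome_phantom(1, dx, seed=5, shape=(n, n),
                                                length_range_um=(2, 3))
        stack = fp.simulate_acquisition(obj, cfg, plan)
        a = fp.reconstruct(stack, upsampling=2,
                           options=fp.ReconstructionOptions(max_iterations=5))
        b = fp.reconstruct(stack, upsampling=2,
                           options=fp.ReconstructionOptions(max_iterations=5))
        assert np.array_equal(a.amplitude, b.amplitude)
        assert np.array_equal(a.phase, b.phase)

    def test_piston_gauge_zero_phase_at_brightest_pixel(self, recovery_run):
        _, _, result = recovery_run
        i = np.argmax(result.amplitude)
        assert abs(result.phase.flat[i]) < 1e-9

    def test_shifted_scene_reconstructs_to_shifted_image(self):
        """Circularly shifting the object shifts the reconstruction by the
        same amount (scaled to the high-resolution grid), amplitude-identical
        to 1e-8."""
        n, dx, up = 32, 0.2, 2
        cfg = config_for(0.25, 10, dx, 1)
        geom = fp.LEDArrayGeometry(used_rows=3, used_cols=3, pitch_mm=8)
        plan = fp.build_illumination_plan(geom, cfg.wavelength_um)
        rng = np.random.default_rng(8)
        amp = rng.uniform(0.3, 1.0, (n, n))
        phase = rng.uniform(0, 0.5, (n, n))
        shift = (5, -3)
        obj = fp.ComplexObject(amp, phase, dx)
        obj_shift = fp.ComplexObject(np.roll(amp, shift, (0, 1)),
                                     np.roll(phase, shift, (0, 1)), dx)
        opts = dict(max_iterations=6, tolerance=0.0, pupil_recovery=False)
        res_a = fp.reconstruct(fp.simulate_acquisition(obj, cfg, plan),
                               upsampling=up,
                               options=fp.ReconstructionOptions(**opts))
        res_b = fp.reconstruct(fp.simulate_acquisition(obj_shift, cfg, plan),
                               upsampling=up,
                               options=fp.ReconstructionOptions(**opts))
        rolled = np.roll(res_a.amplitude, (shift[0] * up, shift[1] * up),
                         (0, 1))
        assert np.allclose(res_b.amplitude, rolled, atol=1e-8)

    def test_spiral_order_visits_brightfield_first(self, usaf4x_stack):
        state = fp.initialize_reconstruction(usaf4x_stack, 4,
                                             fp.ReconstructionOptions())
        order = _sweep_order(usaf4x_stack, state, "spiral")
        k = usaf4x_stack.plan.k_array
        norms = np.hypot(k[:, 0], k[:, 1])[order]
        assert np.all(np.diff(norms) >= -1e-9)


class TestParameterRecovery:
    def test_complex_object_recovered_to_five_percent(self, recovery_run):
        """Noiseless 128x128 chromosome phantom, correct pupil: the recovered
        complex transmission matches the ground truth to < 0.05 relative RMS
        after global-phase alignment."""
        obj, stack, result = recovery_run
        est = decimate_field(result.complex_image, 2)
        est = align_global_phase(est, obj.field)
        err = np.linalg.norm(est - obj.field) / np.linalg.norm(obj.field)
        assert err < 0.05

    def test_planted_defocus_pupil_phase_recovered(self, pupil_recovery_run):
        """Embedded pupil recovery finds a pupil phase correlating >= 0.9
        (masked Pearson) with a planted 10-um defocus aberration."""
        cfg, stack, result = pupil_recovery_run
        n = RECOVERY_SHAPE
        dk = TWO_PI / (n * RECOVERY_PIXEL_UM)
        planted = make_pupil((n, n), dk, cfg.objective_na, cfg.wavelength_um,
                             defocus_um=10.0)
        mask = planted.support
        c = n // 2

        def piston_free_phase(arr):
            ref = arr[c, c] / abs(arr[c, c])
            return np.angle(arr * np.conj(ref))[mask]

        r, _ = pearsonr(piston_free_phase(result.pupil.array),
                        piston_free_phase(planted.array))
        assert r >= 0.9

    def test_recovered_pupil_magnitude_bounded(self, pupil_recovery_run):
        _, _, result = pupil_recovery_run
        assert np.abs(result.pupil.array).max() <= 1.0 + 1e-9
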