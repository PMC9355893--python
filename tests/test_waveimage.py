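"""Image-plane simulation: synthetic lattice, CTF imaging, tilt averaging."""

import numpy as np
import pytest

import decosim as ds
from decosim.waveimage import (
    ExitWave,
    carrier_max_defoci,
    commensurate_spacing,
    lorentzian_tilt_quadrature,
    synthetic_lattice_exit_wave,
    tilt_averaged_image,
)

FOV = 128.0


@pytest.fixture(scope="module")
def lens():
    return ds.LensConfig(cs_A=2.7e7)


@pytest.fixture(scope="module")
def wave():
    return synthetic_lattice_exit_wave(field_of_view_A=FOV)


class TestSyntheticWave:
    def test_zero_amplitude_is_plane_wave(self):
        w = synthetic_lattice_exit_wave(phase_amplitude_rad=0.0,
                                        field_of_view_A=FOV)
        assert np.allclose(w.field, 1.0)

    def test_phase_power_peaks_at_lattice_frequency(self, wave):
        phase = np.angle(wave.field)
        spec = np.abs(np.fft.fft2(phase)) ** 2
        spec[0, 0] = 0.0
        k = np.fft.fftfreq(wave.n, d=wave.pixel_size_A)
        KX, KY = np.meshgrid(k, k, indexing="ij")
        kr = np.sqrt(KX**2 + KY**2)
        peak_k = kr.flat[np.argmax(spec)]
        dk = 1.0 / FOV
        assert abs(peak_k - 1.0 / 2.35) <= dk

    def test_modulation_confined_to_disc(self, wave):
        x = (np.arange(wave.n) - wave.n // 2) * wave.pixel_size_A
        X, Y = np.meshgrid(x, x, indexing="ij")
        outside = (X**2 + Y**2) > 50.0**2
        phase = np.angle(wave.field)
        assert (phase[outside] ** 2).sum() < 0.01 * (phase**2).sum()

    def test_coarse_pixels_rejected(self):
        with pytest.raises(ValueError):
            synthetic_lattice_exit_wave(spacing_d_A=2.35, pixel_size_A=1.0)


class TestCtfImaging:
    def test_weak_phase_flat_in_focus(self, beam300):
        lens0 = ds.LensConfig(cs_A=0.0)
        w = synthetic_lattice_exit_wave(phase_amplitude_rad=0.05,
                                        field_of_view_A=FOV)
        img = ds.image_through_ctf(w, lens0, beam300, 0.0)
        assert np.ptp(img) < 4 * 0.05**2

    def test_intensity_conserved(self, wave, lens, beam300):
        img = ds.image_through_ctf(wave, lens, beam300, -5000.0)
        assert img.sum() / wave.n**2 == pytest.approx(1.0, rel=1e-6)

    def test_reflection_power_peaks_at_stationary_defocus(self, beam300, lens):
        d = commensurate_spacing(2.35, FOV)
        w = synthetic_lattice_exit_wave(spacing_d_A=d, particle_diameter_A=2 * FOV,
                                        field_of_view_A=FOV)
        tE = ds.characteristic_angle(23.0, beam300)
        grid = np.arange(6000.0, -10001.0, -1000.0)
        curve = ds.reflection_fading_curve(w, lens, beam300, tE, d, grid,
                                           n_tilts=(16, 8))
        peak = curve.defocus_A[np.argmax(curve.signal)]
        expect = ds.stationary_defocus(d, lens.cs_A, beam300)
        assert abs(peak - expect) <= 1000.0


class TestReflectionPower:
    def test_plane_wave_has_no_reflection(self):
        img = np.ones((256, 256))
        assert ds.reflection_power(img, 0.5, 2.35) == pytest.approx(0.0, abs=1e-12)

    def test_pure_sinusoid_power_in_annulus(self):
        n = 256
        x = np.arange(n) * 0.5
        d = commensurate_spacing(2.35, n * 0.5)
        img = 1.0 + 0.1 * np.cos(2 * np.pi * x / d)[:, None] * np.ones(n)
        power = ds.reflection_power(img, 0.5, d)
        spec = np.abs(np.fft.fft2(img)) ** 2
        spec[0, 0] = 0
        assert power == pytest.approx(spec.sum(), rel=1e-9)

    def test_translation_invariance(self, wave, lens, beam300):
        img = ds.image_through_ctf(wave, lens, beam300, -3000.0)
        rolled = np.roll(img, (17, -31), axis=(0, 1))
        assert ds.reflection_power(rolled, 0.5, 2.35) == pytest.approx(
            ds.reflection_power(img, 0.5, 2.35), rel=1e-9)

    def test_off_grid_spacing_rejected(self):
        with pytest.raises(ValueError):
            ds.reflection_power(np.ones((64, 64)), 1.0, 1.5)


class TestTiltAveraging:
    def test_zero_thetaE_equals_plain_imaging(self, wave, lens, beam300):
        plain = ds.image_through_ctf(wave, lens, beam300, -1900.0)
        avg = tilt_averaged_image(wave, lens, beam300, -1900.0, 0.0)
        assert np.array_equal(avg.intensity, plain)

    def test_quadrature_weights_normalized(self):
        _, w = lorentzian_tilt_quadrature(4.7e-5, 32, 8)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w > 0)

    def test_quadrature_matches_monte_carlo(self, lens, beam300):
        d = commensurate_spacing(2.35, FOV)
        w = synthetic_lattice_exit_wave(spacing_d_A=d, particle_diameter_A=2 * FOV,
                                        field_of_view_A=FOV)
        tE = ds.characteristic_angle(23.0, beam300)
        dz = float(carrier_max_defoci([-15000.0], lens, beam300, d)[0])
        quadimg = tilt_averaged_image(w, lens, beam300, dz, tE, n_tilts=(32, 8))
        rng = np.random.default_rng(4)
        mcimg = tilt_averaged_image(w, lens, beam300, dz, tE, n_tilts=4000,
                                    rng=rng)
        pq = ds.reflection_power(quadimg.intensity, 0.5, d)
        pm = ds.reflection_power(mcimg.intensity, 0.5, d)
        assert pm == pytest.approx(pq, rel=0.1)

    def test_huge_tilt_rejected(self, wave, lens, beam300):
        with pytest.raises(ValueError):
            tilt_averaged_image(wave, lens, beam300, -1900.0, 1e-2)

    def test_fading_matches_envelope_prediction(self, lens, beam300):
        """Reflection-power fading of the tilt-averaged image agrees with the
        squared Lorentzian coherence envelope within 25% in FWHM."""
        from decosim.envelopes import FadingCurve, extract_fwhm, scaled_envelope

        d = commensurate_spacing(2.35, FOV)
        w = synthetic_lattice_exit_wave(spacing_d_A=d, particle_diameter_A=2 * FOV,
                                        field_of_view_A=FOV)
        tE = ds.characteristic_angle(23.0, beam300)
        grid = np.arange(10000.0, -40001.0, -2500.0)
        curve = ds.reflection_fading_curve(w, lens, beam300, tE, d, grid,
                                           n_tilts=(24, 8))
        fwhm = extract_fwhm(curve)
        gamma = tE / beam300.wavelength_A
        theta = beam300.wavelength_A / d
        D = np.abs(curve.defocus_A * theta + lens.cs_A * theta**3)
        pred = FadingCurve(curve.defocus_A, scaled_envelope()(gamma * D) ** 2, d)
        assert abs(fwhm - extract_fwhm(pred)) / extract_fwhm(pred) < 0.25
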