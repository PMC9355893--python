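"""Coherence envelopes, fading curves, FWHM extraction."""

import numpy as np
import pytest

import decosim as ds
from decosim.envelopes import (
    EnvelopeParams,
    FadingCurve,
    ctf_fading_curve,
    envelope_fading_curve,
    extract_fwhm,
    scaled_envelope,
)


def params_for(loss_eV, beam, D):
    return EnvelopeParams.from_loss(loss_eV, beam, D)


class TestLorentzianEnvelope:
    def test_unity_at_zero_displacement(self, beam300):
        assert ds.lorentzian_envelope(params_for(23.0, beam300, 0.0)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_raw_integral_closed_form(self, beam300):
        # mass inside the cutoff qc = 2 gamma is 1 - 1/sqrt(5)
        raw = ds.lorentzian_envelope(params_for(23.0, beam300, 0.0),
                                     renormalize=False)
        assert raw == pytest.approx(1.0 - 1.0 / np.sqrt(5.0), abs=1e-6)

    def test_decays_at_large_displacement(self, beam300):
        p0 = params_for(23.0, beam300, 0.0)
        big = EnvelopeParams(p0.gamma, p0.cutoff_qc, 50.0 / p0.gamma)
        assert abs(ds.lorentzian_envelope(big)) < 0.05

    def test_quadrature_matches_brute_force_tilt_average(self, beam300):
        """Envelope equals the averaged fringe phase factor over tilts drawn
        from the truncated Lorentzian (independent Monte Carlo oracle)."""
        lam = beam300.wavelength_A
        thetaE = 23.0 / beam300.momentum_velocity_eV
        gamma = thetaE / lam
        rng = np.random.default_rng(17)
        n = 1_000_000
        # inverse CDF of the kernel q (q^2+g^2)^(-3/2) truncated at 2g
        F = rng.random(n) * (1.0 - 1.0 / np.sqrt(5.0))
        mag = gamma * np.sqrt(1.0 / (1.0 - F) ** 2 - 1.0)
        phi = rng.uniform(0, 2 * np.pi, n)
        u_par = mag * np.cos(phi)  # tilt component in frequency units
        for D in np.linspace(5.0, 250.0, 10):
            brute = np.cos(2 * np.pi * u_par * D).mean()
            quadv = ds.lorentzian_envelope(
                EnvelopeParams(gamma, 2 * gamma, D))
            assert quadv == pytest.approx(brute, abs=0.01)

    def test_scaled_table_matches_quadrature(self, beam300):
        gamma = 23.0 / beam300.momentum_velocity_eV / beam300.wavelength_A
        tab = scaled_envelope()
        for D in (0.0, 13.0, 57.0, 140.0, 400.0):
            direct = ds.lorentzian_envelope(EnvelopeParams(gamma, 2 * gamma, D))
            assert tab(gamma * D) == pytest.approx(direct, abs=5e-4)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EnvelopeParams(gamma=0.0, cutoff_qc=1.0, displacement=0.0)


class TestFwhmExtraction:
    def grid(self):
        return np.arange(-30000.0, 30001.0, 100.0)

    def test_exact_lorentzian_both_methods(self):
        x = self.grid()
        curve = FadingCurve(x, 1.0 / (1.0 + (x / 1500.0) ** 2), 2.35)
        for method in ("interpolate", "lorentz-fit"):
            assert extract_fwhm(curve, method) == pytest.approx(3000.0, rel=0.01)

    def test_symmetric_curve_centered_at_focus(self):
        x = self.grid()
        curve = FadingCurve(x, np.exp(-((x / 8000.0) ** 2)), 2.35)
        i0 = np.argmax(curve.signal)
        assert x[i0] == 0.0
        left = extract_fwhm(curve) / 2
        assert np.interp(-left, x, curve.signal) == pytest.approx(
            np.interp(left, x, curve.signal), rel=1e-6)

    def test_unreached_half_maximum_raises(self):
        x = self.grid()
        curve = FadingCurve(x, 1.0 / (1.0 + (x / 1e6) ** 2), 2.35)
        with pytest.raises(ValueError):
            extract_fwhm(curve)


@pytest.fixture(scope="module")
def slit23(carbon2000_ensemble):
    return carbon2000_ensemble.filtered(ds.EnergyFilter(23.0, 6.0))


class TestFadingCurves:
    wide_grid = np.arange(110_000.0, -110_001.0, -400.0)

    def test_envelope_curve_peaks_at_stationary_defocus(self, slit23, lens_cs27,
                                                        beam300):
        grid = np.arange(10000.0, -20001.0, -100.0)
        curve = envelope_fading_curve(slit23, lens_cs27, 2.35, grid)
        peak = curve.defocus_A[np.argmax(curve.signal)]
        expect = ds.stationary_defocus(2.35, lens_cs27.cs_A, beam300)
        assert abs(peak - expect) <= 100.0

    def test_ctf_curve_peaks_near_stationary_defocus(self, slit23, lens_cs27,
                                                     beam300):
        curve = ctf_fading_curve(slit23, lens_cs27, 2.35, self.wide_grid)
        peak = curve.defocus_A[np.argmax(curve.signal)]
        expect = ds.stationary_defocus(2.35, lens_cs27.cs_A, beam300)
        assert abs(peak - expect) <= 2000.0

    def test_cross_method_agreement(self, carbon2000_ensemble, lens_cs27):
        """CTF- and envelope-method FWHMs agree within 25% for every slit."""
        for center in (9.0, 15.0, 23.0, 30.0):
            sub = carbon2000_ensemble.filtered(ds.EnergyFilter(center, 6.0))
            fe = extract_fwhm(envelope_fading_curve(sub, lens_cs27, 2.35,
                                                    self.wide_grid))
            fc = extract_fwhm(ctf_fading_curve(sub, lens_cs27, 2.35,
                                               self.wide_grid))
            assert abs(fc - fe) / fe < 0.25

    def test_zero_loss_electrons_follow_source_envelope(self, carbon2000_ensemble,
                                                        lens_cs27, beam300):
        # slit narrower than twice the loss onset: only unscattered electrons
        sub = carbon2000_ensemble.filtered(ds.EnergyFilter(0.0, 5.0))
        assert np.all(sub.n_events == 0)
        grid = np.arange(10000.0, -50001.0, -500.0)
        curve = envelope_fading_curve(sub, lens_cs27, 2.35, grid,
                                      normalization="absolute")
        expected = ds.gaussian_source_envelope(1 / 2.35, lens_cs27.source_alpha_rad,
                                               lens_cs27, beam300, defocus_A=grid)
        assert np.max(np.abs(curve.signal - expected)) < 1e-9

    def test_narrower_slit_at_higher_loss_fades_faster(self, carbon2000_ensemble,
                                                       lens_cs27):
        f9 = extract_fwhm(envelope_fading_curve(
            carbon2000_ensemble.filtered(ds.EnergyFilter(9.0, 6.0)),
            lens_cs27, 2.35, self.wide_grid))
        f30 = extract_fwhm(envelope_fading_curve(
            carbon2000_ensemble.filtered(ds.EnergyFilter(30.0, 6.0)),
            lens_cs27, 2.35, self.wide_grid))
        assert f30 < f9


@pytest.fixture(scope="module")
def family():
    return ds.figure5_curves(n_electrons=30_000, seed=21)


class TestFigureFamily:
    def test_zero_loss_level(self, family):
        assert family.zero_loss_level == pytest.approx(0.44, abs=0.05)

    def test_resolution_ordering_of_fwhm(self, family):
        f = {d: extract_fwhm(family.curves[d]["additional"])
             for d in (2.4, 9.0, 30.0)}
        assert f[30.0] > f[9.0] > f[2.4]

    def test_ceiling_bounds_total(self, family):
        for d, comps in family.curves.items():
            assert np.all(comps["no-decoherence"].signal
                          >= comps["total"].signal - 1e-9)
            assert np.ptp(comps["no-decoherence"].signal) == 0.0

    def test_partition_conservation(self, family):
        edges = np.arange(0.0, 841.0, 20.0)
        parts = family.partition_curves(2.4, edges)
        total = family.curves[2.4]["total"]
        summed = family.curves[2.4]["zero-loss"].signal.copy()
        for p in parts:
            summed += p.signal
        err = np.max(np.abs(summed - total.signal)) / total.signal.max()
        assert err < 0.01
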