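"""Image-plane verification of the envelope treatment.

A synthetic weak-phase lattice object (a sinusoidal phase grating inside a
disc) is imaged through the aberration phase over an ensemble of beam
tilts weighted by the truncated Lorentzian angular distribution; the power
of the lattice reflection in the averaged image, tracked against defocus,
reproduces the coherence-envelope fading without any envelope formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import BeamParameters, LensConfig, wave_aberration

__all__ = [
    "ExitWave",
    "TiltEnsembleImage",
    "synthetic_lattice_exit_wave",
    "image_through_ctf",
    "tilt_averaged_image",
    "reflection_power",
    "lorentzian_tilt_quadrature",
    "reflection_fading_curve",
    "carrier_max_defoci",
    "commensurate_spacing",
]


@dataclass
class ExitWave:
    """A complex exit wavefunction on a square grid."""

    field: np.ndarray
    pixel_size_A: float

    def __post_init__(self) -> None:
        if self.field.ndim != 2 or self.field.shape[0] != self.field.shape[1]:
            raise ValueError("exit wave must be a square 2-D field")

    @property
    def n(self) -> int:
        return self.field.shape[0]

    @property
    def field_of_view_A(self) -> float:
        return self.n * self.pixel_size_A


@dataclass
class TiltEnsembleImage:
    """Tilt-averaged image intensity with the quadrature weights used."""

    intensity: np.ndarray
    weights: np.ndarray
    defocus_A: float

    def __post_init__(self) -> None:
        if np.any(self.intensity < -1e-9):
            raise ValueError("intensity must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def commensurate_spacing(spacing_d_A: float, field_of_view_A: float) -> float:
    """Nearest lattice spacing whose reflection falls exactly on a Fourier
    pixel of the given field of view (avoids spectral leakage, so the
    CTF-carrier removal of :func:`carrier_max_defoci` is exact)."""
    return field_of_view_A / round(field_of_view_A / spacing_d_A)


def synthetic_lattice_exit_wave(spacing_d_A: float = 2.35,
                                particle_diameter_A: float = 100.0,
                                phase_amplitude_rad: float = 0.05,
                                pixel_size_A: float = 0.5,
                                field_of_view_A: float = 256.0) -> ExitWave:
    """Weak-phase lattice object: unit-amplitude wave with a sinusoidal
    phase modulation at the given spacing inside a disc, zero outside.

    The sampling contract requires pixel_size <= d/4.
    """
    if pixel_size_A > spacing_d_A / 4.0:
        raise ValueError(
            f"pixel size {pixel_size_A} A too coarse for spacing {spacing_d_A} A "
            "(need <= d/4)"
        )
    n = int(round(field_of_view_A / pixel_size_A))
    x = (np.arange(n) - n // 2) * pixel_size_A
    X, Y = np.meshgrid(x, x, indexing="ij")
    disc = (X**2 + Y**2) <= (particle_diameter_A / 2.0) ** 2
    phase = phase_amplitude_rad * np.sin(2.0 * np.pi * X / spacing_d_A) * disc
    return ExitWave(np.exp(1j * phase), pixel_size_A)


def _aberration_factor(wave: ExitWave, lens: LensConfig, beam: BeamParameters,
                       defocus_A: float) -> np.ndarray:
    n = wave.n
    k = np.fft.fftfreq(n, d=wave.pixel_size_A)
    KX, KY = np.meshgrid(k, k, indexing="ij")
    theta = beam.wavelength_A * np.sqrt(KX**2 + KY**2)
    W = wave_aberration(theta, lens, beam, defocus_A=defocus_A)
    return np.exp(-1j * W)


def image_through_ctf(wave: ExitWave, lens: LensConfig, beam: BeamParameters,
                      defocus_A: float) -> np.ndarray:
    """Apply the aberration phase in Fourier space and return |psi|^2."""
    spec = np.fft.fft2(wave.field)
    img = np.fft.ifft2(spec * _aberration_factor(wave, lens, beam, defocus_A))
    return np.abs(img) ** 2


def lorentzian_tilt_quadrature(thetaE_rad: float, n_radial: int = 64,
                               n_azimuthal: int = 16):
    """Deterministic quadrature nodes/weights over the truncated Lorentzian.

    Radial Gauss-Legendre nodes on [0, 2 thetaE] against the radial density
    theta/(theta^2+thetaE^2), uniform azimuth; weights normalized to 1.
    Returns (tilts (m, 2), weights (m,)).
    """
    nodes, w = np.polynomial.legendre.leggauss(n_radial)
    theta = (nodes + 1.0) * thetaE_rad  # [0, 2 thetaE]
    wr = w * thetaE_rad * theta / (theta**2 + thetaE_rad**2)
    phi = (np.arange(n_azimuthal) + 0.5) * (2.0 * np.pi / n_azimuthal)
    tilts = np.column_stack([
        np.outer(theta, np.cos(phi)).ravel(),
        np.outer(theta, np.sin(phi)).ravel(),
    ])
    weights = np.repeat(wr / n_azimuthal, n_azimuthal)
    return tilts, weights / weights.sum()


def tilt_averaged_image(wave: ExitWave, lens: LensConfig, beam: BeamParameters,
                        defocus_A: float, thetaE_rad: float,
                        n_tilts: int | tuple[int, int] = (64, 16),
                        rng: np.random.Generator | None = None) -> TiltEnsembleImage:
    """Average images over beam tilts weighted by the bounded Lorentzian.

    Each tilt shifts the wave's spectrum (a linear phase ramp in real
    space) before imaging; intensities are averaged with the quadrature
    weights.  Pass ``rng`` for the Monte Carlo cross-check mode, in which
    ``n_tilts`` random tilts are sampled instead.
    """
    if thetaE_rad == 0.0:
        return TiltEnsembleImage(image_through_ctf(wave, lens, beam, defocus_A),
                                 np.array([1.0]), defocus_A)
    if rng is None:
        nr, na = n_tilts if isinstance(n_tilts, tuple) else (int(n_tilts), 16)
        tilts, weights = lorentzian_tilt_quadrature(thetaE_rad, nr, na)
    else:
        from .scattering import LorentzianAngles, sample_inelastic_tilt

        m = int(n_tilts) if not isinstance(n_tilts, tuple) else n_tilts[0] * n_tilts[1]
        tilts = sample_inelastic_tilt(LorentzianAngles(thetaE_rad), rng, size=m)
        weights = np.full(m, 1.0 / m)
    _check_tilts_on_grid(wave, beam, tilts)
    acc = _tilt_average(wave, lens, beam, np.array([defocus_A]), tilts, weights)[0]
    return TiltEnsembleImage(acc, weights, defocus_A)


def _check_tilts_on_grid(wave, beam, tilts):
    kmax = 0.5 / wave.pixel_size_A
    if np.max(np.abs(tilts)) / beam.wavelength_A > 0.25 * kmax:
        raise ValueError("tilt shifts exceed a quarter of the Fourier range")


def _tilt_average(wave, lens, beam, defoci, tilts, weights):
    """Accumulate tilt-averaged intensities for every defocus at once.

    A tilted illumination shifts the exit-wave spectrum by tilt/lambda;
    equivalently (and exactly, even for shifts between Fourier pixels) the
    aberration is evaluated at the tilt-shifted frequency while the
    spectrum stays on the grid.
    """
    n = wave.n
    k = np.fft.fftfreq(n, d=wave.pixel_size_A)
    KX, KY = np.meshgrid(k, k, indexing="ij")
    lam = beam.wavelength_A
    out = np.zeros((defoci.size, n, n))
    spec = np.fft.fft2(wave.field)
    c_dz = np.pi / lam
    c_cs = (np.pi / (2.0 * lam)) * lens.cs_A
    for tilt, w in zip(tilts, weights):
        theta2 = lam**2 * ((KX + tilt[0] / lam) ** 2 + (KY + tilt[1] / lam) ** 2)
        cs_phase = c_cs * theta2**2
        for i, dz in enumerate(defoci):
            img = np.fft.ifft2(spec * np.exp(-1j * (c_dz * dz * theta2 + cs_phase)))
            out[i] += w * np.abs(img) ** 2
    return out


def carrier_max_defoci(approx_grid_A, lens: LensConfig, beam: BeamParameters,
                       spacing_d_A: float) -> np.ndarray:
    """Snap defocus values to the nearest CTF-carrier maximum.

    The reflection power of a weak-phase lattice oscillates with defocus as
    sin^2 W(theta_g) under the coherence envelope; sampling at the defoci
    where |sin W| = 1 removes the carrier and leaves the envelope fading.
    """
    theta_g = beam.wavelength_A / spacing_d_A
    c1 = np.pi * theta_g**2 / beam.wavelength_A
    c0 = (np.pi / (2.0 * beam.wavelength_A)) * lens.cs_A * theta_g**4
    grid = np.asarray(approx_grid_A, float)
    m = np.round((c1 * grid + c0) / np.pi - 0.5)
    return ((m + 0.5) * np.pi - c0) / c1


def reflection_power(intensity: np.ndarray, pixel_size_A: float,
                     spacing_d_A: float, annulus_px: int = 2) -> float:
    """Background-subtracted spectral power in an annulus at |k| = 1/d.

    Power is integrated over Fourier pixels within ``annulus_px`` of the
    target ring; the local background per pixel is estimated from the two
    neighbouring rings and subtracted.
    """
    n = intensity.shape[0]
    spec = np.abs(np.fft.fft2(intensity)) ** 2
    spec[0, 0] = 0.0
    k = np.fft.fftfreq(n, d=pixel_size_A)
    KX, KY = np.meshgrid(k, k, indexing="ij")
    kr = np.sqrt(KX**2 + KY**2)
    dk = 1.0 / (n * pixel_size_A)
    target = 1.0 / spacing_d_A
    if target > np.max(np.abs(k)):
        raise ValueError("reflection lies outside the Fourier grid")
    ring = np.abs(kr - target) <= annulus_px * dk
    inner = np.abs(kr - (target - 2 * (annulus_px + 1) * dk)) <= annulus_px * dk
    outer = np.abs(kr - (target + 2 * (annulus_px + 1) * dk)) <= annulus_px * dk
    bg_px = np.concatenate([spec[inner], spec[outer]])
    background = np.median(bg_px) if bg_px.size else 0.0
    return float(np.maximum(spec[ring] - background, 0.0).sum())


def reflection_fading_curve(wave: ExitWave, lens: LensConfig,
                            beam: BeamParameters, thetaE_rad: float,
                            spacing_d_A: float,
                            defocus_grid_A: np.ndarray,
                            n_tilts: tuple[int, int] = (64, 16),
                            snap_to_carrier_max: bool = True):
    """Reflection power vs defocus of the tilt-averaged image.

    With ``snap_to_carrier_max`` (default) each requested defocus is moved
    to the nearest CTF-carrier maximum so the curve traces the coherence
    fading rather than the sin^2 W oscillation.  Returns a unit-peak
    :class:`decosim.envelopes.FadingCurve` whose FWHM can be compared with
    the coherence-envelope prediction.
    """
    from .envelopes import FadingCurve

    defoci = np.asarray(defocus_grid_A, float)
    if snap_to_carrier_max:
        defoci = np.unique(carrier_max_defoci(defoci, lens, beam, spacing_d_A))
    if thetaE_rad > 0:
        tilts, weights = lorentzian_tilt_quadrature(thetaE_rad, *n_tilts)
        _check_tilts_on_grid(wave, beam, tilts)
    else:
        tilts, weights = np.zeros((1, 2)), np.array([1.0])
    stack = _tilt_average(wave, lens, beam, defoci, tilts, weights)
    power = np.array([
        reflection_power(img, wave.pixel_size_A, spacing_d_A) for img in stack
    ])
    peak = power.max()
    if peak > 0:
        power = power / peak
    return FadingCurve(defoci, power, spacing_d_A, "unit-peak", "loss-window")
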