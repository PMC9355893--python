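"""Relativistic beam quantities, the wave aberration function, CTF and the
Gaussian source-coherence envelope.

Conventions used throughout the package
---------------------------------------
* Lengths are in angstroms, angles in radians, energies in eV unless a name
  says otherwise.
* Underfocus is **negative**: the defocus at which phase contrast is usually
  collected is a negative number of angstroms.
* Scattering angles and spatial frequencies are interchangeable through
  ``theta = wavelength * q``; the aberration function takes an angle, the
  envelopes take a spatial frequency, and both views are exposed where the
  mixing would otherwise be confusing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._constants import (
    ELECTRON_MASS_KG,
    ELECTRON_REST_ENERGY_EV,
    ELEMENTARY_CHARGE_C,
    PLANCK_JS,
    SPEED_OF_LIGHT_MS,
)

__all__ = [
    "BeamParameters",
    "LensConfig",
    "electron_wavelength",
    "wave_aberration",
    "ctf_value",
    "stationary_defocus",
    "gaussian_source_envelope",
]


def electron_wavelength(voltage_kV: float) -> float:
    """Relativistic de Broglie wavelength of an electron in angstrom.

    Parameters
    ----------
    voltage_kV : accelerating voltage in kilovolt; must be positive.
    """
    if voltage_kV <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage_kV} kV")
    V = voltage_kV * 1e3
    lam_m = PLANCK_JS / math.sqrt(
        2.0
        * ELECTRON_MASS_KG
        * ELEMENTARY_CHARGE_C
        * V
        * (1.0 + ELEMENTARY_CHARGE_C * V / (2.0 * ELECTRON_MASS_KG * SPEED_OF_LIGHT_MS**2))
    )
    return lam_m * 1e10


@dataclass(frozen=True)
class BeamParameters:
    """Derived relativistic quantities for a beam of given accelerating voltage.

    Attributes
    ----------
    accelerating_voltage_kV : accelerating voltage (kV).
    wavelength_A : relativistic wavelength (angstrom).
    momentum_velocity_eV : the product p*v in eV; the characteristic inelastic
        angle for a small energy loss dE is ``dE / momentum_velocity_eV``.
    lorentz_factor : total energy over rest energy, >= 1.
    """

    accelerating_voltage_kV: float
    wavelength_A: float = field(init=False)
    momentum_velocity_eV: float = field(init=False)
    lorentz_factor: float = field(init=False)

    def __post_init__(self) -> None:
        lam = electron_wavelength(self.accelerating_voltage_kV)
        E0 = self.accelerating_voltage_kV * 1e3  # kinetic energy, eV
        mc2 = ELECTRON_REST_ENERGY_EV
        object.__setattr__(self, "wavelength_A", lam)
        object.__setattr__(self, "momentum_velocity_eV", E0 * (E0 + 2 * mc2) / (E0 + mc2))
        object.__setattr__(self, "lorentz_factor", 1.0 + E0 / mc2)

    @property
    def kinetic_energy_eV(self) -> float:
        return self.accelerating_voltage_kV * 1e3


@dataclass(frozen=True)
class LensConfig:
    """Objective lens / illumination configuration.

    ``cs_A`` is the spherical aberration coefficient in angstrom (2.7 mm =
    2.7e7 A; use :meth:`from_config` to pass mm).  ``defocus_A`` follows the
    underfocus-negative convention.  ``source_fwhm_rad`` is the FWHM of the
    Gaussian angular distribution of the illumination; the 1/e semi-angle
    used by the source envelope is ``source_fwhm_rad / (2 sqrt(ln 2))``.

    ``cc_corrected`` flags chromatic-aberration correction.  No numeric Cc is
    modelled: correction means inelastically scattered electrons are imaged
    at the same defocus as elastic ones.
    """

    cs_A: float = 2.7e7
    defocus_A: float = 0.0
    source_fwhm_rad: float = 1.0e-5
    cc_corrected: bool = False

    def __post_init__(self) -> None:
        if self.cs_A < 0:
            raise ValueError("Cs must be non-negative")
        if self.source_fwhm_rad < 0:
            raise ValueError("source angle FWHM must be non-negative")

    @property
    def source_alpha_rad(self) -> float:
        """1/e semi-angle of the Gaussian source distribution."""
        return self.source_fwhm_rad / (2.0 * math.sqrt(math.log(2.0)))

    @property
    def source_sigma_rad(self) -> float:
        """Per-component standard deviation of the Gaussian source tilt."""
        return self.source_fwhm_rad / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    @classmethod
    def from_config(cls, cfg: dict) -> "LensConfig":
        """Build from a key-value config: voltage handled elsewhere; accepts
        ``cs_mm`` or ``cs_A``, ``defocus_A``, ``source_fwhm_mrad``,
        ``cc_corrected``."""
        if "cs_mm" in cfg:
            cs = float(cfg["cs_mm"]) * 1e7
        else:
            cs = float(cfg.get("cs_A", 2.7e7))
        fwhm = float(cfg.get("source_fwhm_mrad", 0.01)) * 1e-3
        return cls(
            cs_A=cs,
            defocus_A=float(cfg.get("defocus_A", 0.0)),
            source_fwhm_rad=fwhm,
            cc_corrected=bool(cfg.get("cc_corrected", False)),
        )


def wave_aberration(theta, lens: LensConfig, beam: BeamParameters, defocus_A=None):
    """Aberration phase W(theta) = (pi / 2 lambda) (2 dz theta^2 + Cs theta^4).

    ``theta`` may be a scalar or array of angles (rad).  ``defocus_A``
    overrides ``lens.defocus_A`` when given (the fading-curve code sweeps it).
    Returns the phase in radians.
    """
    theta = np.asarray(theta, dtype=float)
    dz = lens.defocus_A if defocus_A is None else defocus_A
    lam = beam.wavelength_A
    return (np.pi / (2.0 * lam)) * (2.0 * dz * theta**2 + lens.cs_A * theta**4)


def ctf_value(theta, lens: LensConfig, beam: BeamParameters, defocus_A=None):
    """Contrast transfer: the sine of the aberration phase, in [-1, 1]."""
    return np.sin(wave_aberration(theta, lens, beam, defocus_A=defocus_A))


def stationary_defocus(resolution_d_A: float, cs_A: float, beam: BeamParameters) -> float:
    """Defocus where dW/dtheta vanishes at the angle of a given spacing.

    For spacing d the diffraction angle is theta = lambda/d and the
    stationary point of W sits at dz = -Cs theta^2 (a negative number:
    underfocus).  This is the defocus of maximum fading-curve signal.
    """
    if resolution_d_A <= 0:
        raise ValueError("resolution must be positive")
    theta = beam.wavelength_A / resolution_d_A
    return -cs_A * theta**2


def gaussian_source_envelope(q, alpha_rad: float, lens: LensConfig,
                             beam: BeamParameters, defocus_A=None):
    """Spatial-coherence envelope of a Gaussian source.

    Es(q) = exp[-(pi alpha / lambda)^2 (lambda dz q + Cs lambda^3 q^3)^2]
    with ``alpha_rad`` the 1/e semi-angle of the source angular distribution
    and ``q`` a spatial frequency in 1/angstrom.  Equals the characteristic
    function of the Gaussian tilt ensemble evaluated at the aberration-
    gradient displacement D = dz*theta + Cs*theta^3, theta = lambda*q.
    """
    q = np.asarray(q, dtype=float)
    lam = beam.wavelength_A
    dz = lens.defocus_A if defocus_A is None else defocus_A
    displacement = lam * dz * q + lens.cs_A * lam**3 * q**3
    return np.exp(-((np.pi * alpha_rad / lam) ** 2) * displacement**2)
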