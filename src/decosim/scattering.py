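"""Cross-section-level physics: characteristic inelastic angle, bounded
Lorentzian angular sampling, Poisson scattering statistics, materials and
mixtures.

The inelastic angular distribution of a plasmon-type loss is taken as the
Lorentzian differential cross section 1/(theta^2 + thetaE^2) with
characteristic angle thetaE = dE/(p v), truncated at the plasmon cutoff
2*thetaE.  Scattering event counts follow Poisson statistics in t/lambda.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .beam import BeamParameters

__all__ = [
    "Material",
    "Specimen",
    "LorentzianAngles",
    "MATERIALS",
    "get_material",
    "characteristic_angle",
    "sample_inelastic_tilt",
    "poisson_event_probabilities",
    "zero_loss_fraction",
    "mixture_inelastic_mfp",
    "single_elastic_signal_fraction",
    "parse_mixture",
]


@dataclass(frozen=True)
class Material:
    """A homogeneous amorphous material with scattering mean free paths.

    Mean free paths are defined at ``reference_voltage_kV``; no implicit
    voltage scaling is applied — other voltages need user-supplied values.
    ``elastic_mfp_A`` may be None when only inelastic bookkeeping is needed.
    """

    name: str
    density_g_cm3: float
    inelastic_mfp_A: float
    elastic_mfp_A: float | None = None
    reference_voltage_kV: float = 300.0

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.inelastic_mfp_A <= 0:
            raise ValueError("inelastic mean free path must be positive")
        if self.elastic_mfp_A is not None and self.elastic_mfp_A <= 0:
            raise ValueError("elastic mean free path must be positive")


def _load_registry() -> dict[str, Material]:
    reg: dict[str, Material] = {}
    src = importlib.resources.files("decosim").joinpath("data/materials.tsv")
    for line in src.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, dens, li, le, v = line.split("\t")
        reg[name] = Material(
            name=name,
            density_g_cm3=float(dens),
            inelastic_mfp_A=float(li),
            elastic_mfp_A=float(le) if le not in ("", "-") else None,
            reference_voltage_kV=float(v),
        )
    return reg


MATERIALS: dict[str, Material] = _load_registry()


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(MATERIALS)}"
        ) from None


def mixture_inelastic_mfp(components: list[tuple[Material, float]]) -> float:
    """Inelastic mean free path of a mixture by inverse-MFP additivity.

    ``components`` is a list of (material, volume_fraction); fractions must
    sum to 1.  1/lambda_mix = sum_i f_i / lambda_i.
    """
    fracs = [f for _, f in components]
    if abs(sum(fracs) - 1.0) > 1e-6:
        raise ValueError(f"volume fractions must sum to 1, got {sum(fracs)}")
    inv = 0.0
    for mat, f in components:
        if mat.inelastic_mfp_A is None:
            raise ValueError(f"material {mat.name!r} has no inelastic MFP")
        inv += f / mat.inelastic_mfp_A
    return 1.0 / inv


def _mixture_elastic_mfp(components: list[tuple[Material, float]]) -> float:
    inv = 0.0
    for mat, f in components:
        if mat.elastic_mfp_A is None:
            raise ValueError(f"material {mat.name!r} has no elastic MFP configured")
        inv += f / mat.elastic_mfp_A
    return 1.0 / inv


@dataclass(frozen=True)
class Specimen:
    """A specimen of given thickness, either a single material or a mixture.

    ``components`` holds (Material, volume_fraction) pairs summing to 1.
    """

    components: tuple[tuple[Material, float], ...]
    thickness_A: float

    def __post_init__(self) -> None:
        if self.thickness_A <= 0:
            raise ValueError("thickness must be positive")
        if abs(sum(f for _, f in self.components) - 1.0) > 1e-6:
            raise ValueError("volume fractions must sum to 1")

    @classmethod
    def single(cls, material: Material | str, thickness_A: float) -> "Specimen":
        if isinstance(material, str):
            material = get_material(material)
        return cls(components=((material, 1.0),), thickness_A=thickness_A)

    @classmethod
    def mixture(cls, components, thickness_A: float) -> "Specimen":
        comps = tuple(
            (get_material(m) if isinstance(m, str) else m, float(f))
            for m, f in components
        )
        return cls(components=comps, thickness_A=thickness_A)

    @classmethod
    def protein_in_ice(cls, thickness_A: float,
                       protein_fraction: float = 0.3) -> "Specimen":
        """The continuum protein/amorphous-ice mixture (default 30:70)."""
        return cls.mixture(
            [("protein", protein_fraction), ("ice", 1.0 - protein_fraction)],
            thickness_A,
        )

    @property
    def inelastic_mfp_A(self) -> float:
        return mixture_inelastic_mfp(list(self.components))

    @property
    def elastic_mfp_A(self) -> float:
        return _mixture_elastic_mfp(list(self.components))


def parse_mixture(text: str, thickness_A: float) -> Specimen:
    """Parse a CLI mixture spec like ``"protein:0.3,ice:0.7"``."""
    comps = []
    for part in text.split(","):
        name, frac = part.split(":")
        comps.append((name.strip(), float(frac)))
    return Specimen.mixture(comps, thickness_A)


def characteristic_angle(energy_loss_eV: float, beam: BeamParameters) -> float:
    """Characteristic inelastic scattering angle thetaE = dE / (p v), rad.

    Small-loss relativistic form; valid for losses much smaller than the
    beam energy.
    """
    if np.any(np.asarray(energy_loss_eV) <= 0):
        raise ValueError("energy loss must be positive")
    if np.any(np.asarray(energy_loss_eV) >= beam.kinetic_energy_eV):
        raise ValueError("energy loss must be below the beam energy")
    return np.asarray(energy_loss_eV, dtype=float) / beam.momentum_velocity_eV


@dataclass(frozen=True)
class LorentzianAngles:
    """Angular parameters of a single plasmon-type loss.

    The radial sampling density is proportional to theta/(theta^2+thetaE^2)
    on [0, cutoff] with cutoff = 2 thetaE.
    """

    characteristic_angle_thetaE: float
    cutoff_angle: float = field(init=False)

    def __post_init__(self) -> None:
        if self.characteristic_angle_thetaE <= 0:
            raise ValueError("thetaE must be positive")
        object.__setattr__(self, "cutoff_angle", 2.0 * self.characteristic_angle_thetaE)

    @classmethod
    def from_loss(cls, energy_loss_eV: float, beam: BeamParameters) -> "LorentzianAngles":
        return cls(float(characteristic_angle(energy_loss_eV, beam)))


def truncated_lorentzian_cdf(theta, thetaE: float, cutoff: float | None = None):
    """Closed-form CDF of the radial law theta/(theta^2+thetaE^2) on [0, b]."""
    if cutoff is None:
        cutoff = 2.0 * thetaE
    theta = np.asarray(theta, dtype=float)
    num = np.log1p(np.clip(theta, 0.0, cutoff) ** 2 / thetaE**2)
    den = np.log1p(cutoff**2 / thetaE**2)
    return num / den


def sample_inelastic_tilt(angles: LorentzianAngles, rng: np.random.Generator,
                          size: int | None = None) -> np.ndarray:
    """Draw planar tilt vectors from the bounded Lorentzian radial law.

    The radial magnitude is drawn by inverse transform from the density
    proportional to theta/(theta^2 + thetaE^2) truncated at the cutoff;
    the azimuth is uniform.  Returns shape (2,) or (size, 2) in radians.
    """
    n = 1 if size is None else int(size)
    tE = angles.characteristic_angle_thetaE
    b = angles.cutoff_angle
    u = rng.random(n)
    # F^{-1}(u) with F(theta) = ln(1 + theta^2/tE^2) / ln(1 + b^2/tE^2)
    mag = tE * np.sqrt(np.expm1(u * np.log1p(b**2 / tE**2)))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    out = np.column_stack([mag * np.cos(phi), mag * np.sin(phi)])
    return out[0] if size is None else out


def poisson_event_probabilities(thickness_A: float, mfp_A: float,
                                n_max: int) -> np.ndarray:
    """P(n) = exp(-t/mfp) (t/mfp)^n / n! for n = 0..n_max."""
    if thickness_A < 0:
        raise ValueError("thickness must be non-negative")
    if mfp_A <= 0:
        raise ValueError("mean free path must be positive")
    return stats.poisson.pmf(np.arange(n_max + 1), thickness_A / mfp_A)


def zero_loss_fraction(specimen: Specimen, beam: BeamParameters | None = None) -> float:
    """Fraction of electrons with no inelastic event: exp(-t / lambda_i)."""
    return float(np.exp(-specimen.thickness_A / specimen.inelastic_mfp_A))


def single_elastic_signal_fraction(specimen: Specimen,
                                   beam: BeamParameters | None = None,
                                   include_inelastic_loss: bool = False,
                                   normalize_thickness_A: float | None = None) -> float:
    """Poisson probability of exactly one elastic scattering event.

    With ``include_inelastic_loss`` the single-elastic probability is
    multiplied by the zero-inelastic probability (electrons that also lost
    energy are discarded, as in zero-loss filtered imaging).  With
    ``normalize_thickness_A`` the value is divided by the same quantity for
    a specimen of that thickness (the conventional normalization anchor).
    """

    def raw(spec: Specimen) -> float:
        x = spec.thickness_A / spec.elastic_mfp_A
        frac = x * np.exp(-x)
        if include_inelastic_loss:
            frac *= zero_loss_fraction(spec)
        return float(frac)

    value = raw(specimen)
    if normalize_thickness_A is not None:
        ref = Specimen(components=specimen.components,
                       thickness_A=normalize_thickness_A)
        value /= raw(ref)
    return value
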