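"""Minimum identifiable molecular mass in situ versus specimen thickness.

The detectable-mass floor for template matching in a vitrified specimen of
thickness t rises with the loss of usable signal:

    Mmin(t)      = (M0 * damage_scale + Mblur) / exp(-t a (1/li + 1/le))

without chromatic correction (energy-filtered imaging: only unscattered,
elastically scattered electrons carry signal), and

    Mmin_cc(t)   = (M0 * damage_scale + Mblur) /
                   [ E exp(-t a / le) + (1 - E) exp(-t a (1/li + 1/le)) ]

with chromatic correction, where E in [0, 1] is the fractional signal
retained by inelastically scattered electrons (set by the spatial-coherence
envelope at the resolution of interest).  M0 = 42 kDa is the zero-thickness
detection floor, a = 1.05 a protein-size correction factor, li and le the
inelastic and elastic mean free paths.  ``damage_scale`` rescales M0 only
(e.g. 1/1.5 for a reduced radiation-damage rate with extra cooling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamParameters, LensConfig

__all__ = [
    "MassModelParams",
    "min_mass_filtered",
    "min_mass_cc",
    "min_mass_cc_defocus_integrated",
    "mass_vs_thickness_table",
]


@dataclass(frozen=True)
class MassModelParams:
    """Constants of the minimum-mass model.

    The default elastic mean free path is an uncalibrated heuristic (see
    docs/methods.md); quantities compared in tests are either
    lambda_e-independent or use it explicitly.
    """

    M0_kDa: float = 42.0
    Mblur_kDa: float = 0.0
    a: float = 1.05
    inelastic_mfp_A: float = 2436.5  # 30:70 protein:water mixture at 300 kV
    elastic_mfp_A: float = 9000.0
    damage_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.M0_kDa <= 0 or self.a < 0 or self.Mblur_kDa < 0:
            raise ValueError("require M0 > 0, a >= 0, Mblur >= 0")
        if self.inelastic_mfp_A <= 0 or self.elastic_mfp_A <= 0:
            raise ValueError("mean free paths must be positive")

    @property
    def numerator_kDa(self) -> float:
        return self.M0_kDa * self.damage_scale + self.Mblur_kDa


def min_mass_filtered(thickness_A, params: MassModelParams):
    """Minimum identifiable mass without chromatic correction (kDa)."""
    t = np.asarray(thickness_A, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    atten = np.exp(-t * params.a * (1.0 / params.inelastic_mfp_A
                                    + 1.0 / params.elastic_mfp_A))
    out = params.numerator_kDa / atten
    return float(out) if np.isscalar(thickness_A) else out


def min_mass_cc(thickness_A, params: MassModelParams, envelope_fraction):
    """Minimum identifiable mass with chromatic correction (kDa).

    ``envelope_fraction`` is the fractional signal E retained by the
    inelastically scattered electrons at the spatial frequency of interest.
    """
    E = np.asarray(envelope_fraction, dtype=float)
    if np.any((E < 0) | (E > 1)):
        raise ValueError("envelope fraction must lie in [0, 1]")
    t = np.asarray(thickness_A, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    elastic_only = np.exp(-t * params.a / params.elastic_mfp_A)
    both = np.exp(-t * params.a * (1.0 / params.inelastic_mfp_A
                                   + 1.0 / params.elastic_mfp_A))
    denom = E * elastic_only + (1.0 - E) * both
    out = params.numerator_kDa / denom
    return float(out) if np.isscalar(thickness_A) and np.isscalar(envelope_fraction) else out


def mean_envelope_fraction(thickness_A: float, beam: BeamParameters,
                           lens: LensConfig, resolution_d_A: float,
                           center_defocus_A: float, params: MassModelParams,
                           n_electrons: int = 20000, seed: int = 0,
                           n_defocus: int = 41) -> float:
    """Mean coherence-envelope signal of the inelastic electrons, averaged
    over the defocus range [center - t/2, center + t/2] spanned by the
    specimen (each depth sits at its own defocus)."""
    from .envelopes import _envelope_means
    from .scattering import Specimen
    from .transit import simulate_transit

    specimen = Specimen.protein_in_ice(thickness_A)
    ensemble = simulate_transit(specimen, beam, n_electrons, seed, lens=lens)
    inelastic = ensemble.n_events > 0
    if not inelastic.any():
        return 1.0
    grid = np.linspace(center_defocus_A - thickness_A / 2.0,
                       center_defocus_A + thickness_A / 2.0, n_defocus)
    vals = _envelope_means(ensemble, lens, resolution_d_A, grid, mask=inelastic)
    return float(np.clip(vals.mean(), 0.0, 1.0))


def min_mass_cc_defocus_integrated(thickness_A: float, params: MassModelParams,
                                   lens: LensConfig, beam: BeamParameters,
                                   resolution_d_A: float,
                                   center_defocus_A: float = 0.0,
                                   n_electrons: int = 20000,
                                   seed: int = 0) -> float:
    """Chromatically corrected minimum mass with the envelope fraction
    averaged over the defocus spread across the specimen thickness."""
    if thickness_A == 0:
        return min_mass_cc(0.0, params, 1.0)
    E = mean_envelope_fraction(thickness_A, beam, lens, resolution_d_A,
                               center_defocus_A, params,
                               n_electrons=n_electrons, seed=seed)
    return float(min_mass_cc(thickness_A, params, E))


def mass_vs_thickness_table(params: MassModelParams,
                            thickness_grid_A=None,
                            beam: BeamParameters | None = None,
                            lens: LensConfig | None = None,
                            resolution_d_A: float = 2.4,
                            integrated_centers=(0.0, -5000.0),
                            integrated_thicknesses=None,
                            seed: int = 0) -> dict:
    """Tabulate the mass-limit variants on a thickness grid.

    Columns: the filtered (no-Cc) curve, the ideal Cc curve (E = 1), the
    damage-reduced filtered curve (damage rate lowered 1.5-fold), and
    defocus-integrated Cc points at the requested centre defoci.
    """
    if thickness_grid_A is None:
        thickness_grid_A = np.arange(0.0, 5001.0, 100.0)
    t = np.asarray(thickness_grid_A, dtype=float)
    cooled = MassModelParams(
        M0_kDa=params.M0_kDa, Mblur_kDa=params.Mblur_kDa, a=params.a,
        inelastic_mfp_A=params.inelastic_mfp_A,
        elastic_mfp_A=params.elastic_mfp_A,
        damage_scale=params.damage_scale / 1.5,
    )
    table = {
        "thickness_A": t,
        "filtered_kDa": min_mass_filtered(t, params),
        "cc_ideal_kDa": min_mass_cc(t, params, np.ones_like(t)),
        "filtered_damage_reduced_kDa": min_mass_filtered(t, cooled),
    }
    if beam is not None and lens is not None:
        if integrated_thicknesses is None:
            integrated_thicknesses = t[:: max(1, t.size // 10)][1:]
        pts = {}
        for c in integrated_centers:
            pts[c] = np.array([
                min_mass_cc_defocus_integrated(float(tt), params, lens, beam,
                                               resolution_d_A, c, seed=seed)
                for tt in integrated_thicknesses
            ])
        table["integrated_thickness_A"] = np.asarray(integrated_thicknesses, float)
        table["cc_integrated_kDa"] = pts
    return table
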