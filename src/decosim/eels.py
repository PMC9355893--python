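"""Electron energy-loss spectra.

A spectrum is an idealized zero-loss delta (its mass stored separately) plus
a loss density on a uniform eV grid.  The built-in synthetic single-scattering
spectrum emulates a thin-carbon plasmon spectrum: a truncated Lorentzian
peaked at 23 eV with support up to 140 eV.  Thickness scaling is the
compound-Poisson mixture of n-fold self-convolutions.  File I/O supports a
plain-CSV dialect and the EMSA/MAS (.msa) two-column spectral format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyLossSpectrum",
    "EnergyFilter",
    "synthetic_thin_spectrum",
    "thickness_scaled_spectrum",
    "sample_energy_loss",
    "filter_pass",
    "read_spectrum",
    "write_spectrum",
    "SpectrumParseError",
]


class SpectrumParseError(ValueError):
    """Raised on malformed spectral files; message carries the line number."""


@dataclass
class EnergyLossSpectrum:
    """Probability density of energy loss on a uniform eV grid.

    ``density`` integrates (trapezoid) to ``1 - zero_loss_fraction``; the
    zero-loss peak is an idealized delta at 0 eV whose mass is stored in
    ``zero_loss_fraction``.
    """

    energy_eV: np.ndarray
    density: np.ndarray
    zero_loss_fraction: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energy_eV = np.asarray(self.energy_eV, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.energy_eV.ndim != 1 or self.energy_eV.size < 2:
            raise ValueError("energy grid must be a 1-D array of >= 2 points")
        steps = np.diff(self.energy_eV)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("energy grid must be uniform and increasing")
        if self.energy_eV[0] < 0:
            raise ValueError("energy grid must be non-negative")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if not 0.0 <= self.zero_loss_fraction <= 1.0:
            raise ValueError("zero-loss fraction must be in [0, 1]")
        total = self.zero_loss_fraction + self.loss_integral
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"probability not normalized: total = {total}")

    @property
    def grid_step_eV(self) -> float:
        return float(self.energy_eV[1] - self.energy_eV[0])

    @property
    def loss_integral(self) -> float:
        return float(np.trapezoid(self.density, self.energy_eV))

    @property
    def mode_eV(self) -> float:
        """Most probable loss of the loss part."""
        return float(self.energy_eV[np.argmax(self.density)])

    @property
    def mean_loss_eV(self) -> float:
        """Mean energy loss including the zero-loss mass."""
        return float(np.trapezoid(self.energy_eV * self.density, self.energy_eV))

    def loss_cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Normalized CDF of the loss part (for inverse-transform sampling)."""
        step = self.grid_step_eV
        cdf = np.concatenate(
            [[0.0], np.cumsum((self.density[1:] + self.density[:-1]) * 0.5 * step)]
        )
        if cdf[-1] <= 0:
            raise ValueError("loss part is empty; nothing to sample")
        return self.energy_eV, cdf / cdf[-1]

    def window_fraction(self, lo_eV: float, hi_eV: float) -> float:
        """Probability that the loss falls in [lo, hi] (zero loss excluded
        unless lo <= 0)."""
        e, d = self.energy_eV, self.density
        mask = (e >= lo_eV) & (e <= hi_eV)
        if mask.sum() < 2:
            return 0.0
        frac = float(np.trapezoid(d[mask], e[mask]))
        if lo_eV <= 0:
            frac += self.zero_loss_fraction
        return frac


def synthetic_thin_spectrum(peak_eV: float = 23.0, hwhm_eV: float = 8.0,
                            onset_eV: float = 3.0,
                            support: tuple[float, float] = (0.0, 140.0),
                            grid_step_eV: float = 0.2) -> EnergyLossSpectrum:
    """Synthetic single-scattering plasmon loss spectrum.

    A Lorentzian of the given peak and half width, zeroed below the low-loss
    onset and truncated at the support bounds, normalized to unit integral
    (the spectrum of electrons that did scatter exactly once).
    """
    lo, hi = support
    if not (lo < peak_eV < hi) or hi <= lo:
        raise ValueError("require support[0] < peak < support[1]")
    if hwhm_eV <= 0 or grid_step_eV <= 0:
        raise ValueError("width and grid step must be positive")
    energy = np.arange(lo, hi + 0.5 * grid_step_eV, grid_step_eV)
    dens = 1.0 / ((energy - peak_eV) ** 2 + hwhm_eV**2)
    dens[energy < onset_eV] = 0.0
    dens /= np.trapezoid(dens, energy)
    return EnergyLossSpectrum(
        energy, dens, zero_loss_fraction=0.0,
        metadata={"kind": "synthetic-thin", "peak_eV": peak_eV,
                  "hwhm_eV": hwhm_eV, "onset_eV": onset_eV},
    )


def _poisson_weights(mean: float, n_max: int) -> np.ndarray:
    n = np.arange(n_max + 1)
    from scipy import stats

    w = stats.poisson.pmf(n, mean)
    deficit = 1.0 - w.sum()
    if deficit > 1e-3:
        warnings.warn(
            f"n_max={n_max} covers only {1 - deficit:.4f} of the Poisson mass",
            stacklevel=3,
        )
    return w


def thickness_scaled_spectrum(thin: EnergyLossSpectrum, thickness_A: float,
                              mfp_A: float, n_max: int = 6,
                              method: str = "convolve",
                              n_mc: int = 10**6,
                              rng: np.random.Generator | None = None
                              ) -> EnergyLossSpectrum:
    """Compound-Poisson thickness scaling of a single-scattering spectrum.

    The loss density of a specimen of thickness t is the Poisson(t/mfp)
    mixture of n-fold self-convolutions of the thin single-scattering
    density; the zero-loss mass is P(0) = exp(-t/mfp).  ``method`` selects
    the direct convolution path or a Monte Carlo path (sum of per-event
    draws binned back onto the extended grid); the two agree and the MC
    path exists as a cross-check.
    """
    if thickness_A < 0:
        raise ValueError("thickness must be non-negative")
    mean = thickness_A / mfp_A
    step = thin.grid_step_eV
    e_max = float(thin.energy_eV[-1])
    grid = np.arange(0.0, n_max * e_max + 0.5 * step, step)
    weights = _poisson_weights(mean, n_max)
    meta = {"kind": "thickness-scaled", "thickness_A": thickness_A,
            "mfp_A": mfp_A, "n_max": n_max, "method": method}

    if thickness_A == 0:
        dens = np.zeros_like(grid)
        return EnergyLossSpectrum(grid, dens, zero_loss_fraction=1.0, metadata=meta)

    base = np.zeros_like(grid)
    base[: thin.density.size] = thin.density

    if method == "convolve":
        dens = np.zeros_like(grid)
        conv = base.copy()  # n-fold self-convolution, starting at n = 1
        for n in range(1, n_max + 1):
            if n > 1:
                conv = np.convolve(conv, base)[: grid.size] * step
                total = np.trapezoid(conv, grid)
                if total > 0:  # counteract grid-edge normalization drift
                    conv = conv / total
            dens += weights[n] * conv
    elif method == "mc":
        rng = np.random.default_rng(0) if rng is None else rng
        n_events = np.minimum(rng.poisson(mean, n_mc), n_max)
        e_cdf, cdf = thin.loss_cdf()
        totals = np.zeros(n_mc)
        for i in range(1, n_max + 1):
            sel = n_events >= i
            totals[sel] += np.interp(rng.random(int(sel.sum())), cdf, e_cdf)
        scattered = totals[n_events > 0]
        edges = np.concatenate([grid - 0.5 * step, [grid[-1] + 0.5 * step]])
        hist, _ = np.histogram(scattered, bins=edges)
        dens = hist / (n_mc * step)
        dens = dens / np.trapezoid(dens, grid) * (1.0 - weights[0] - max(0.0, 1 - weights.sum()))
    else:
        raise ValueError(f"unknown method {method!r}")

    # rescale the loss part so the total mass is exactly 1 - P(0)
    zlf = float(weights[0])
    loss_mass = np.trapezoid(dens, grid)
    dens = dens * (1.0 - zlf) / loss_mass
    return EnergyLossSpectrum(grid, dens, zero_loss_fraction=zlf, metadata=meta)


def sample_energy_loss(spectrum: EnergyLossSpectrum, rng: np.random.Generator,
                       size: int | None = None):
    """Draw energy losses: 0 with the zero-loss probability, otherwise an
    inverse-transform draw from the loss density."""
    n = 1 if size is None else int(size)
    out = np.zeros(n)
    lost = rng.random(n) >= spectrum.zero_loss_fraction
    k = int(lost.sum())
    if k:
        e, cdf = spectrum.loss_cdf()
        out[lost] = np.interp(rng.random(k), cdf, e)
    return float(out[0]) if size is None else out


@dataclass(frozen=True)
class EnergyFilter:
    """Top-hat energy-selection slit: full width ``slit_width_eV`` centred on
    ``center_eV``; edges inclusive."""

    center_eV: float
    slit_width_eV: float

    def __post_init__(self) -> None:
        if self.slit_width_eV <= 0:
            raise ValueError("slit width must be positive")

    def passes(self, energy_loss_eV):
        e = np.asarray(energy_loss_eV, dtype=float)
        return np.abs(e - self.center_eV) <= 0.5 * self.slit_width_eV


def filter_pass(energy_loss_eV, energy_filter: EnergyFilter):
    """True iff the loss falls within the slit (inclusive edges)."""
    return energy_filter.passes(energy_loss_eV)


# ---------------------------------------------------------------------------
# file I/O

_MSA_REQUIRED = ("#FORMAT", "#NPOINTS", "#XUNITS", "#DATATYPE")


def write_spectrum(spectrum: EnergyLossSpectrum, path) -> None:
    """Write a spectrum as .msa (EMSA/MAS two-column dialect) or .csv."""
    path = str(path)
    if path.endswith(".msa"):
        lines = [
            "#FORMAT      : EMSA/MAS Spectral Data File",
            "#VERSION     : 1.0",
            f"#NPOINTS     : {spectrum.energy_eV.size}",
            "#XUNITS      : eV",
            "#YUNITS      : probability/eV",
            "#DATATYPE    : XY",
            f"#XPERCHAN    : {spectrum.grid_step_eV!r}",
            f"#OFFSET      : {spectrum.energy_eV[0]!r}",
            f"##ZLFRACTION : {spectrum.zero_loss_fraction!r}",
            "#SPECTRUM    : Spectral Data Starts Here",
        ]
        lines += [f"{e:.6f}, {d:.9e}" for e, d in zip(spectrum.energy_eV, spectrum.density)]
        lines.append("#ENDOFDATA   : ")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        with open(path, "w") as fh:
            fh.write("energy_eV,counts\n")
            fh.write(f"# zero_loss_fraction = {spectrum.zero_loss_fraction!r}\n")
            for e, d in zip(spectrum.energy_eV, spectrum.density):
                fh.write(f"{e:.6f},{d:.9e}\n")


def _normalize_counts(energy, counts, zlp_window_eV, zlf_hint=None):
    counts = np.asarray(counts, dtype=float)
    if zlf_hint is not None:
        zlf = float(zlf_hint)
        dens = counts.copy()
    else:
        zlp = np.abs(energy) < zlp_window_eV
        total = np.trapezoid(counts, energy)
        zlf = float(np.trapezoid(counts[zlp], energy[zlp]) / total) if zlp.sum() >= 2 else 0.0
        dens = counts.copy()
        dens[zlp] = 0.0
    loss = np.trapezoid(dens, energy)
    if loss > 0:
        dens *= (1.0 - zlf) / loss
    return dens, zlf


def read_spectrum(path, zlp_window_eV: float = 3.0) -> EnergyLossSpectrum:
    """Read a spectrum from .msa or .csv; counts are normalized on read.

    The zero-loss mass is taken from an explicit ``ZLFRACTION`` header when
    present, otherwise estimated from the |E| < ``zlp_window_eV`` window.
    """
    path = str(path)
    if path.endswith(".msa"):
        return _read_msa(path, zlp_window_eV)
    return _read_csv(path, zlp_window_eV)


def _read_csv(path, zlp_window_eV):
    energies, counts = [], []
    zlf_hint = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.lower().startswith("energy"):
                continue
            if line.startswith("#"):
                if "zero_loss_fraction" in line:
                    zlf_hint = float(line.split("=")[1])
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                e, c = float(parts[0]), float(parts[1])
            except ValueError:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric value") from None
            if c < 0:
                raise SpectrumParseError(f"{path}:{lineno}: negative counts")
            energies.append(e)
            counts.append(c)
    if len(energies) < 2:
        raise SpectrumParseError(f"{path}: no data rows")
    energy = np.asarray(energies)
    dens, zlf = _normalize_counts(energy, counts, zlp_window_eV, zlf_hint)
    return EnergyLossSpectrum(energy, dens, zero_loss_fraction=zlf,
                              metadata={"source": path})


def _read_msa(path, zlp_window_eV):
    header: dict[str, str] = {}
    energies, counts = [], []
    in_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key = line.split(":", 1)[0].strip()
                val = line.split(":", 1)[1].strip() if ":" in line else ""
                header[key.upper()] = val
                if key.upper() == "#SPECTRUM":
                    in_data = True
                if key.upper() == "#ENDOFDATA":
                    in_data = False
                continue
            if not in_data:
                raise SpectrumParseError(f"{path}:{lineno}: data before #SPECTRUM marker")
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                e, c = float(parts[0]), float(parts[1])
            except ValueError:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric value") from None
            if c < 0:
                raise SpectrumParseError(f"{path}:{lineno}: negative counts")
            energies.append(e)
            counts.append(c)
    for kw in _MSA_REQUIRED:
        if kw not in header:
            raise SpectrumParseError(f"{path}: missing required header keyword {kw}")
    npoints = int(float(header["#NPOINTS"]))
    if npoints != len(energies):
        raise SpectrumParseError(
            f"{path}: #NPOINTS = {npoints} but {len(energies)} data rows"
        )
    energy = np.asarray(energies)
    zlf_hint = header.get("##ZLFRACTION")
    dens, zlf = _normalize_counts(energy, counts, zlp_window_eV,
                                  float(zlf_hint) if zlf_hint is not None else None)
    return EnergyLossSpectrum(energy, dens, zero_loss_fraction=zlf,
                              metadata={"source": path, **{k: v for k, v in header.items()}})
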