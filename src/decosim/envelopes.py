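"""Spatial-coherence envelopes and fading curves.

The Lorentzian coherence envelope of a single plasmon-type loss is

    E(D) = int_0^qc  gamma q (q^2 + gamma^2)^(-3/2) J0(2 pi q D) dq,

the 2-D Fourier transform of the truncated Lorentzian angular distribution
expressed in spatial-frequency units: gamma = thetaE / lambda is the HWHM,
qc = 2 thetaE / lambda the plasmon cutoff, and D = dz*theta + Cs*theta^3 the
aberration-gradient displacement at the angle theta = lambda/d of the
resolution of interest.  Because qc/gamma = 2 is fixed, E depends only on
x = gamma*D, which makes per-electron evaluation over a defocus grid cheap
(a single precomputed profile is interpolated).

Fading curves collect, per defocus, either the average |sin(aberration
phase)| over a Monte Carlo tilt ensemble (the CTF method) or the average
per-electron envelope product (the envelope method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit
from scipy.special import j0

from .beam import BeamParameters, LensConfig, gaussian_source_envelope
from .transit import TransitEnsemble

__all__ = [
    "EnvelopeParams",
    "FadingCurve",
    "lorentzian_envelope",
    "ctf_fading_curve",
    "envelope_fading_curve",
    "extract_fwhm",
    "figure5_curves",
    "Figure5Family",
    "default_defocus_grid",
]


def default_defocus_grid() -> np.ndarray:
    """The conventional fading-curve grid: +10000 to -50000 A in 100 A steps."""
    return np.arange(10000.0, -50001.0, -100.0)


@dataclass(frozen=True)
class EnvelopeParams:
    """Parameters of the Lorentzian coherence envelope.

    gamma and cutoff are spatial frequencies (1/A); displacement is in A.
    """

    gamma: float
    cutoff_qc: float
    displacement: float

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cutoff_qc <= 0:
            raise ValueError("gamma and cutoff must be positive")
        if self.displacement < 0:
            raise ValueError("displacement must be non-negative")

    @classmethod
    def from_loss(cls, energy_loss_eV: float, beam: BeamParameters,
                  displacement_A: float) -> "EnvelopeParams":
        thetaE = energy_loss_eV / beam.momentum_velocity_eV
        lam = beam.wavelength_A
        return cls(gamma=thetaE / lam, cutoff_qc=2.0 * thetaE / lam,
                   displacement=displacement_A)


def lorentzian_envelope(params: EnvelopeParams, renormalize: bool = True,
                        rtol: float = 1e-8) -> float:
    """Numerical quadrature of the Lorentzian coherence envelope.

    Renormalized by the D = 0 value so a zero displacement returns exactly 1
    (the raw integral at D = 0 is 1 - gamma/sqrt(qc^2 + gamma^2), the
    probability mass inside the cutoff).
    """
    g, qc, D = params.gamma, params.cutoff_qc, params.displacement

    def integrand(q):
        return g * q * (q * q + g * g) ** -1.5 * j0(2.0 * np.pi * q * D)

    # subdivide at the Bessel zeros for robust oscillatory quadrature
    if D > 0:
        period = 1.0 / (2.0 * np.pi * D) * np.pi  # half-period in q
        pts = np.arange(period, qc, period)[:2000]
    else:
        pts = None
    val, err = quad(integrand, 0.0, qc, limit=3000,
                    points=pts, epsabs=0.0, epsrel=rtol)
    if not np.isfinite(val) or (abs(val) > 1e-12 and err > 1e-3 * abs(val) + 1e-9):
        raise ArithmeticError(
            f"envelope quadrature did not converge: value={val}, err={err}, "
            f"gamma={g}, qc={qc}, D={D}"
        )
    if renormalize:
        val /= 1.0 - g / math.sqrt(qc * qc + g * g)
    return float(val)


class _ScaledEnvelope:
    """Tabulated E(x) for the fixed cutoff ratio qc/gamma = 2, x = gamma*D."""

    def __init__(self, xmax: float = 60.0, dx: float = 2e-3, order: int = 800):
        nodes, w = np.polynomial.legendre.leggauss(order)
        u = nodes + 1.0  # map to [0, 2]
        kern = u * (1.0 + u * u) ** -1.5 * w
        self.x = np.arange(0.0, xmax + dx, dx)
        norm = 1.0 - 1.0 / math.sqrt(5.0)
        self.values = (j0(2.0 * np.pi * np.outer(self.x, u)) * kern).sum(axis=1) / norm

    def __call__(self, x):
        return np.interp(np.abs(x), self.x, self.values, right=0.0)


_scaled_envelope_cache: _ScaledEnvelope | None = None


def scaled_envelope() -> _ScaledEnvelope:
    global _scaled_envelope_cache
    if _scaled_envelope_cache is None:
        _scaled_envelope_cache = _ScaledEnvelope()
    return _scaled_envelope_cache


@dataclass
class FadingCurve:
    """Signal versus defocus at a fixed resolution."""

    defocus_A: np.ndarray
    signal: np.ndarray
    resolution_d_A: float
    normalization_mode: str = "unit-peak"
    component_label: str = "all"

    def __post_init__(self) -> None:
        self.defocus_A = np.asarray(self.defocus_A, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        d = np.diff(self.defocus_A)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("defocus grid must be strictly monotone")

    def fwhm(self, method: str = "interpolate") -> float:
        return extract_fwhm(self, method=method)

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        if self.defocus_A[0] < self.defocus_A[-1]:
            return self.defocus_A, self.signal
        return self.defocus_A[::-1], self.signal[::-1]


def _normalize(signal: np.ndarray, mode: str, electron_fraction: float) -> np.ndarray:
    if mode == "unit-peak":
        peak = np.max(np.abs(signal))
        return signal / peak if peak > 0 else signal
    if mode == "per-electron-fraction":
        return signal * electron_fraction
    if mode == "absolute":
        return signal
    raise ValueError(f"unknown normalization mode {mode!r}")


def ctf_fading_curve(ensemble: TransitEnsemble, lens: LensConfig,
                     resolution_d_A: float,
                     defocus_grid_A: np.ndarray | None = None,
                     normalization: str = "unit-peak",
                     demodulate: bool = True) -> FadingCurve:
    """Absolute ensemble-averaged CTF at each defocus.

    An electron with total tilt tau contributes the phase
    W(theta_g + tau_par) - W(tau_par), where tau_par is the tilt component
    along the reflection direction and theta_g = lambda/d; this reduces to
    the displacement form dW/dtheta * tau to first order.  The signed CTFs
    are averaged so that tilt dephasing attenuates the mean, giving
    |<sin phase>| = |sin W| * coherence factor.

    The |sin W| carrier oscillates in defocus with period lambda/theta_g^2;
    with ``demodulate`` (default) the returned signal is the upper envelope
    of the oscillation (block maxima over one carrier period), which is the
    smooth fading curve whose FWHM is comparable with the envelope method.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    grid = default_defocus_grid() if defocus_grid_A is None else np.asarray(defocus_grid_A, float)
    beam = ensemble.beam
    lam = beam.wavelength_A
    theta_g = lam / resolution_d_A
    tau = ensemble.total_tilt[:, 0]
    # W(theta) = (pi/2 lam)(2 dz th^2 + Cs th^4); precompute tilt-dependent parts
    a = (theta_g + tau) ** 2 - tau**2
    b = (theta_g + tau) ** 4 - tau**4
    c1 = np.pi / lam
    c2 = np.pi / (2.0 * lam) * lens.cs_A
    signal = np.empty(grid.size)
    for k, dz in enumerate(grid):
        signal[k] = abs(np.sin(c1 * dz * a + c2 * b).mean())
    if demodulate:
        from scipy.ndimage import maximum_filter1d

        period = lam / theta_g**2  # defocus change for one carrier half-cycle
        step = float(np.abs(np.diff(grid)).min())
        size = max(3, int(round(period / step)) | 1)
        signal = maximum_filter1d(signal, size=size, mode="nearest")
    signal = _normalize(signal, normalization, 1.0 - ensemble.discarded_fraction)
    return FadingCurve(grid, signal, resolution_d_A, normalization, "all")


def _envelope_means(ensemble: TransitEnsemble, lens: LensConfig,
                    resolution_d_A: float, grid: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Mean per-electron envelope product times the source envelope."""
    beam = ensemble.beam
    lam = beam.wavelength_A
    theta = lam / resolution_d_A
    q = 1.0 / resolution_d_A
    gammas = ensemble.event_losses / beam.momentum_velocity_eV / lam  # (N, n_cap)
    if mask is not None:
        gammas = gammas[mask]
    if gammas.shape[0] == 0:
        return np.zeros(grid.size)
    env = scaled_envelope()
    disp = grid * theta + lens.cs_A * theta**3
    out = np.empty(grid.size)
    for k, D in enumerate(disp):
        out[k] = env(gammas * abs(D)).prod(axis=1).mean()
    source = gaussian_source_envelope(q, lens.source_alpha_rad, lens, beam,
                                      defocus_A=grid)
    return out * source


def envelope_fading_curve(ensemble: TransitEnsemble, lens: LensConfig,
                          resolution_d_A: float,
                          defocus_grid_A: np.ndarray | None = None,
                          normalization: str = "unit-peak") -> FadingCurve:
    """Average Lorentzian-envelope signal over the ensemble at each defocus.

    Per electron, the envelopes of its individual events multiply
    (independent tilts convolve, so their characteristic functions
    multiply); each event's gamma derives from its sampled loss.  The
    Gaussian source envelope multiplies in analytically.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    grid = default_defocus_grid() if defocus_grid_A is None else np.asarray(defocus_grid_A, float)
    signal = _envelope_means(ensemble, lens, resolution_d_A, grid)
    signal = _normalize(signal, normalization, 1.0 - ensemble.discarded_fraction)
    return FadingCurve(grid, signal, resolution_d_A, normalization, "all")


def extract_fwhm(curve: FadingCurve, method: str = "interpolate") -> float:
    """Full width at half of (peak - baseline) of a fading curve.

    "interpolate" detects the two half crossings linearly (fading curves
    decay toward zero, so the baseline is zero); "lorentz-fit" fits a
    Lorentzian plus constant baseline by least squares and returns the
    fitted FWHM.
    """
    x, y = curve.ascending()
    i0 = int(np.argmax(y))
    if i0 == 0 or i0 == y.size - 1:
        raise ValueError("curve maximum sits at the grid edge")
    if method == "interpolate":
        half = 0.5 * y[i0]
        right = np.nonzero(y[i0:] < half)[0]
        left = np.nonzero(y[: i0 + 1][::-1] < half)[0]
        if right.size == 0 or left.size == 0:
            raise ValueError("half maximum not reached within the defocus grid")
        ir = i0 + right[0]
        xr = np.interp(half, [y[ir], y[ir - 1]], [x[ir], x[ir - 1]])
        il = i0 - left[0]
        xl = np.interp(half, [y[il], y[il + 1]], [x[il], x[il + 1]])
        return float(xr - xl)
    if method == "lorentz-fit":
        def model(z, A, z0, w, b):
            return A / (1.0 + ((z - z0) / w) ** 2) + b

        p0 = (float(y[i0] - y.min()), float(x[i0]),
              max(float(np.ptp(x)) / 10.0, 1.0), float(y.min()))
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
        return float(2.0 * abs(popt[2]))
    raise ValueError(f"unknown FWHM method {method!r}")


@dataclass
class Figure5Family:
    """Fading-curve family for a thick specimen at several resolutions.

    ``curves[d]`` maps a resolution (A) to the component curves:
    "total" (all electrons), "zero-loss" (flat level of unscattered
    electrons), "additional" (inelastic contribution above the zero-loss
    level), "no-decoherence" (ceiling if every electron stayed coherent)
    and "loss-window" curves for the energy-slit windows.  All curves are in
    per-electron-fraction normalization so components are additive.
    """

    curves: dict[float, dict]
    zero_loss_level: float
    ensemble: TransitEnsemble
    lens: LensConfig

    def partition_curves(self, resolution_d_A: float,
                         edges: np.ndarray) -> list[FadingCurve]:
        """Loss-window curves over a half-open partition (lo, hi] of losses,
        for conservation checks against the total curve."""
        grid = self.curves[resolution_d_A]["total"].defocus_A
        out = []
        loss = self.ensemble.total_loss
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (loss > lo) & (loss <= hi)
            frac = float(mask.mean())
            sig = _envelope_means(self.ensemble, self.lens, resolution_d_A,
                                  grid, mask=mask) * frac
            out.append(FadingCurve(grid, sig, resolution_d_A,
                                   "per-electron-fraction", f"loss({lo},{hi}]"))
        return out


def figure5_curves(ensemble: TransitEnsemble | None = None,
                   lens: LensConfig | None = None,
                   resolutions=(2.4, 9.0, 30.0),
                   slit_centers=(9.0, 15.0, 23.0, 30.0),
                   slit_width_eV: float = 6.0,
                   n_electrons: int = 10**5, seed: int = 0,
                   defocus_grids: dict | None = None) -> Figure5Family:
    """Fading-curve family for a 2000 A 30:70 protein:water specimen.

    Defaults reproduce the aberration-free (Cs = 0) imaging conditions at
    300 kV; the defocus grids are symmetric about focus and sized per
    resolution so the half maximum of every component is bracketed.
    """
    from .scattering import Specimen
    from .transit import simulate_transit

    if ensemble is None:
        specimen = Specimen.protein_in_ice(2000.0)
        beam = BeamParameters(300.0)
        lens = lens if lens is not None else LensConfig(cs_A=0.0, defocus_A=0.0,
                                                        source_fwhm_rad=1e-5)
        ensemble = simulate_transit(specimen, beam, n_electrons, seed, lens=lens)
    elif lens is None:
        lens = ensemble.lens

    if defocus_grids is None:
        defocus_grids = {}
        for d in resolutions:
            span = 10000.0 * d  # fading scales linearly with d
            step = max(100.0, span / 200.0)
            defocus_grids[d] = np.arange(-span, span + 0.5 * step, step)

    n0 = float((ensemble.n_events == 0).mean())
    inelastic = ensemble.n_events > 0
    beam = ensemble.beam
    curves: dict[float, dict] = {}
    for d in resolutions:
        grid = np.asarray(defocus_grids[d], float)
        q = 1.0 / d
        source = gaussian_source_envelope(q, lens.source_alpha_rad, lens, beam,
                                          defocus_A=grid)
        zero_loss = FadingCurve(grid, n0 * source, d, "per-electron-fraction",
                                "zero-loss")
        add_sig = _envelope_means(ensemble, lens, d, grid, mask=inelastic) \
            * float(inelastic.mean())
        additional = FadingCurve(grid, add_sig, d, "per-electron-fraction",
                                 "inelastic-total")
        total = FadingCurve(grid, zero_loss.signal + add_sig, d,
                            "per-electron-fraction", "all")
        ceiling = FadingCurve(grid, np.ones(grid.size), d,
                              "per-electron-fraction", "no-decoherence")
        windows = {}
        for c in slit_centers:
            mask = np.abs(ensemble.total_loss - c) <= 0.5 * slit_width_eV
            sig = _envelope_means(ensemble, lens, d, grid, mask=mask) \
                * float(mask.mean())
            windows[c] = FadingCurve(grid, sig, d, "per-electron-fraction",
                                     "loss-window")
        curves[d] = {"total": total, "zero-loss": zero_loss,
                     "additional": additional, "no-decoherence": ceiling,
                     "loss-windows": windows}
    return Figure5Family(curves=curves, zero_loss_level=n0,
                         ensemble=ensemble, lens=lens)
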