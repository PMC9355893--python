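"""Monte Carlo transit of electrons through a specimen.

Each electron gets an isotropic Gaussian source tilt, a Poisson number of
inelastic events (capped), an energy loss per event drawn from the thin
single-scattering spectrum, and a planar tilt per event drawn from the
bounded Lorentzian of that event's characteristic angle.  Tilt vectors add
in the small-angle approximation.  Elastic scattering does not deflect
electrons here; it enters only through the Poisson signal-fraction
bookkeeping in :mod:`decosim.scattering`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beam import BeamParameters, LensConfig
from .eels import EnergyFilter, EnergyLossSpectrum, synthetic_thin_spectrum, thickness_scaled_spectrum
from .scattering import Specimen

__all__ = ["ElectronRecord", "TransitEnsemble", "simulate_transit", "angular_distribution"]


@dataclass(frozen=True)
class ElectronRecord:
    """Per-electron view into a :class:`TransitEnsemble`."""

    source_tilt: np.ndarray
    total_energy_loss: float
    n_inelastic_events: int
    cumulative_inelastic_tilt: np.ndarray
    per_event_losses: np.ndarray


@dataclass
class TransitEnsemble:
    """Struct-of-arrays record of a Monte Carlo transit.

    ``event_losses`` is (n_electrons, n_cap), zero-padded beyond each
    electron's event count.  Reproducible bit-for-bit from (seed, params).
    """

    source_tilt: np.ndarray
    n_events: np.ndarray
    event_losses: np.ndarray
    inelastic_tilt: np.ndarray
    specimen: Specimen
    beam: BeamParameters
    lens: LensConfig
    seed: int
    n_electrons: int
    energy_filter: EnergyFilter | None = None
    discarded_fraction: float = 0.0
    total_loss: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.total_loss = self.event_losses.sum(axis=1)

    def __len__(self) -> int:
        return self.source_tilt.shape[0]

    def record(self, i: int) -> ElectronRecord:
        n = int(self.n_events[i])
        return ElectronRecord(
            source_tilt=self.source_tilt[i],
            total_energy_loss=float(self.total_loss[i]),
            n_inelastic_events=n,
            cumulative_inelastic_tilt=self.inelastic_tilt[i],
            per_event_losses=self.event_losses[i, :n],
        )

    @property
    def total_tilt(self) -> np.ndarray:
        return self.source_tilt + self.inelastic_tilt

    def loss_window_fraction(self, lo_eV: float, hi_eV: float) -> float:
        """Fraction of surviving electrons whose total loss is in [lo, hi]."""
        return float(((self.total_loss >= lo_eV) & (self.total_loss <= hi_eV)).mean())

    def select(self, mask: np.ndarray) -> "TransitEnsemble":
        return TransitEnsemble(
            source_tilt=self.source_tilt[mask],
            n_events=self.n_events[mask],
            event_losses=self.event_losses[mask],
            inelastic_tilt=self.inelastic_tilt[mask],
            specimen=self.specimen,
            beam=self.beam,
            lens=self.lens,
            seed=self.seed,
            n_electrons=self.n_electrons,
            energy_filter=self.energy_filter,
            discarded_fraction=self.discarded_fraction,
        )

    def filtered(self, energy_filter: EnergyFilter) -> "TransitEnsemble":
        """Keep only electrons whose total loss passes the slit."""
        mask = np.asarray(energy_filter.passes(self.total_loss))
        out = self.select(mask)
        out.energy_filter = energy_filter
        out.discarded_fraction = 1.0 - float(mask.mean())
        return out


def _conditional_event_counts(total_losses, specimen, thin, n_cap, rng):
    """Draw n | total loss from the compound-Poisson model (optional mode).

    P(n | dE) is proportional to P(n) f^{*n}(dE); the n-fold convolutions
    come from the thickness-scaled spectrum machinery.
    """
    mean = specimen.thickness_A / specimen.inelastic_mfp_A
    from scipy import stats

    step = thin.grid_step_eV
    e_max = float(thin.energy_eV[-1])
    grid = np.arange(0.0, n_cap * e_max + 0.5 * step, step)
    base = np.zeros_like(grid)
    base[: thin.density.size] = thin.density
    convs = []
    conv = base.copy()
    for n in range(1, n_cap + 1):
        if n > 1:
            conv = np.convolve(conv, base)[: grid.size] * step
            tot = np.trapezoid(conv, grid)
            if tot > 0:
                conv = conv / tot
        convs.append(conv)
    pn = stats.poisson.pmf(np.arange(1, n_cap + 1), mean)
    pn[-1] += stats.poisson.sf(n_cap, mean)
    dens_n = np.array([np.interp(total_losses, grid, c) for c in convs])  # (n_cap, N)
    w = pn[:, None] * dens_n
    w_sum = w.sum(axis=0)
    w_sum[w_sum == 0] = 1.0
    cum = np.cumsum(w / w_sum, axis=0)
    u = rng.random(total_losses.size)
    return 1 + (u[None, :] > cum).sum(axis=0)


def simulate_transit(specimen: Specimen, beam: BeamParameters,
                     n_electrons: int, seed: int,
                     lens: LensConfig | None = None,
                     thin_spectrum: EnergyLossSpectrum | None = None,
                     energy_filter: EnergyFilter | None = None,
                     n_cap: int = 6, cap_mode: str = "assign",
                     event_count_mode: str = "poisson") -> TransitEnsemble:
    """Monte Carlo transit producing a :class:`TransitEnsemble`.

    Parameters
    ----------
    n_electrons : number of primary electrons (>= 1).
    seed : integer seed; required for the reproducibility contract.
    lens : supplies the Gaussian source-tilt FWHM (default 0.01 mrad).
    thin_spectrum : single-scattering loss spectrum (default synthetic).
    energy_filter : if given, electrons failing the slit are discarded and
        the discarded fraction recorded.
    n_cap : event-count cap; ``cap_mode`` "assign" puts the Poisson mass
        above the cap at n = n_cap, "renormalize" redistributes it.
    event_count_mode : "poisson" draws n directly from Poisson(t/mfp);
        "spectrum" first draws the total loss from the thickness-scaled
        spectrum, draws n | total loss from the compound model, and rescales
        per-event thin-spectrum draws to the sampled total.
    """
    if n_electrons < 1:
        raise ValueError("need at least one electron")
    if seed is None or not isinstance(seed, (int, np.integer)):
        raise ValueError("an integer seed is required for reproducibility")
    lens = lens if lens is not None else LensConfig(defocus_A=0.0)
    thin = thin_spectrum if thin_spectrum is not None else synthetic_thin_spectrum()
    rng = np.random.default_rng(seed)
    N = int(n_electrons)

    sigma = lens.source_sigma_rad
    source_tilt = rng.normal(0.0, sigma, size=(N, 2)) if sigma > 0 else np.zeros((N, 2))

    mean = specimen.thickness_A / specimen.inelastic_mfp_A
    e_grid, cdf = thin.loss_cdf()

    if event_count_mode == "poisson":
        n_events = rng.poisson(mean, N)
        if cap_mode == "assign":
            n_events = np.minimum(n_events, n_cap)
        elif cap_mode == "renormalize":
            while np.any(n_events > n_cap):
                redo = n_events > n_cap
                n_events[redo] = rng.poisson(mean, int(redo.sum()))
        else:
            raise ValueError(f"unknown cap_mode {cap_mode!r}")
        event_losses = np.zeros((N, n_cap))
        for i in range(1, n_cap + 1):
            sel = n_events >= i
            k = int(sel.sum())
            if k:
                event_losses[sel, i - 1] = np.interp(rng.random(k), cdf, e_grid)
    elif event_count_mode == "spectrum":
        thick = thickness_scaled_spectrum(thin, specimen.thickness_A,
                                          specimen.inelastic_mfp_A, n_max=n_cap)
        from .eels import sample_energy_loss

        totals = sample_energy_loss(thick, rng, size=N)
        n_events = np.zeros(N, dtype=int)
        lost = totals > 0
        if lost.any():
            n_events[lost] = _conditional_event_counts(totals[lost], specimen,
                                                       thin, n_cap, rng)
        event_losses = np.zeros((N, n_cap))
        for i in range(1, n_cap + 1):
            sel = n_events >= i
            k = int(sel.sum())
            if k:
                event_losses[sel, i - 1] = np.interp(rng.random(k), cdf, e_grid)
        sums = event_losses.sum(axis=1)
        scale = np.divide(totals, sums, out=np.ones(N), where=sums > 0)
        event_losses *= scale[:, None]
    else:
        raise ValueError(f"unknown event_count_mode {event_count_mode!r}")

    # per-event bounded-Lorentzian tilts, summed vectorially
    pv = beam.momentum_velocity_eV
    inelastic_tilt = np.zeros((N, 2))
    for i in range(n_cap):
        losses = event_losses[:, i]
        sel = losses > 0
        k = int(sel.sum())
        if not k:
            continue
        tE = losses[sel] / pv
        u = rng.random(k)
        mag = tE * np.sqrt(np.expm1(u * np.log(5.0)))  # cutoff at 2 thetaE
        phi = rng.uniform(0.0, 2.0 * np.pi, k)
        inelastic_tilt[sel, 0] += mag * np.cos(phi)
        inelastic_tilt[sel, 1] += mag * np.sin(phi)

    ens = TransitEnsemble(
        source_tilt=source_tilt, n_events=n_events, event_losses=event_losses,
        inelastic_tilt=inelastic_tilt, specimen=specimen, beam=beam, lens=lens,
        seed=int(seed), n_electrons=N,
    )
    if energy_filter is not None:
        ens = ens.filtered(energy_filter)
    return ens


def angular_distribution(ensemble: TransitEnsemble, bins=200):
    """Radial density of the total (source + inelastic) tilt magnitude.

    Returns (bin_centers, density) with density normalized so that
    ``sum(density * bin_width) = 1``; suitable for log-log plotting.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    mag = np.hypot(*ensemble.total_tilt.T)
    hist, edges = np.histogram(mag, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist
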