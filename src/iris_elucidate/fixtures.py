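"""Seed-deterministic synthetic data with known ground truth.

Every stage of the workflow can be exercised without instrument data:

* :func:`make_scan_series` emulates wavelength-stepped acquisition — 4 to 8
  replicate fragmentation mass spectra per step, multiplicative intensity
  noise (ion-count fluctuations scale with signal), and a smooth
  frequency-dependent pulse-energy envelope so that the linear power
  correction is non-trivial;
* :func:`make_conformer_set` samples conformer ensembles with known exact
  Boltzmann populations;
* :func:`make_isomer_pair` builds the classic discrimination scenario: a
  true candidate, a decoy whose carbonyl-stretch band is shifted, and a
  noisy "experimental" spectrum generated from the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import IRSpectrum, normalize
from .theory import BroadeningPolicy, ConformerRecord, boltzmann_weights
from .yield_spectrum import ScanRecord, ScanSeries

__all__ = [
    "FixtureSpec",
    "make_scan_series",
    "make_conformer_set",
    "make_isomer_pair",
    "gaussian_bands",
    "default_energy_profile",
]


def gaussian_bands(
    grid: np.ndarray, bands: list[tuple[float, float, float]]
) -> np.ndarray:
    """Sum of Gaussian bands given as (center, height, fwhm) triples."""
    out = np.zeros_like(grid, dtype=float)
    for center, height, fwhm in bands:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += height * np.exp(-((grid - center) ** 2) / (2.0 * sigma**2))
    return out


def default_energy_profile(wavenumber: np.ndarray) -> np.ndarray:
    """Smooth pulse-energy envelope (arbitrary units) peaking mid-range,
    emulating a free-electron-laser power curve."""
    w = np.asarray(wavenumber, dtype=float)
    center, width = 1600.0, 2400.0
    return 20.0 + 60.0 * np.exp(-((w - center) ** 2) / (2.0 * width**2))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic scan-series acquisition."""

    seed: int = 0
    noise_sigma: float = 0.0  # relative (multiplicative) intensity noise
    n_replicates: int = 6  # instrument averages 4-8 spectra per step
    grid_start: float = 550.0
    grid_stop: float = 1850.0
    grid_step: float = 5.0
    peak_list: tuple[tuple[float, float, float], ...] = (
        (1100.0, 0.6, 40.0),
        (1400.0, 0.3, 35.0),
        (1700.0, 1.0, 30.0),
    )
    precursor_mz: float = 499.19
    fragment_mzs: tuple[float, ...] = (363.07, 321.0)
    max_yield: float = 0.8  # peak dissociation yield of the true spectrum

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 1 <= self.n_replicates:
            raise ValueError("need at least one replicate")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def make_scan_series(
    spec: FixtureSpec, true_spectrum: IRSpectrum | None = None
) -> tuple[ScanSeries, IRSpectrum]:
    """Generate a scan series whose reconstructed spectrum equals a ground
    truth up to noise.

    The truth (default: the spec's peak list on its grid, scaled so the
    maximum dissociation yield is ``max_yield``) is converted at each step
    into a target yield multiplied by the pulse-energy envelope, so that
    dividing by pulse energy recovers the truth. Replicates carry
    multiplicative Gaussian noise on the target yield. Returns the series
    and the normalized ground-truth spectrum.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid() if true_spectrum is None else true_spectrum.grid
    if true_spectrum is None:
        truth_vals = gaussian_bands(grid, list(spec.peak_list))
    else:
        truth_vals = true_spectrum.values.astype(float)
    peak = truth_vals.max(initial=0.0)
    if peak <= 0:
        raise ValueError("ground-truth spectrum must have positive intensity")

    energy = default_energy_profile(grid)
    # corrected value = yield / energy must reproduce the truth shape;
    # scale so the largest yield across the scan equals max_yield
    target = truth_vals / peak  # normalized truth
    yields = target * energy
    yields *= spec.max_yield / yields.max()

    total_intensity = 1000.0
    records: list[ScanRecord] = []
    for wn, e, y in zip(grid, energy, yields):
        for rep in range(spec.n_replicates):
            noisy = y * (1.0 + rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma else y
            noisy = float(np.clip(noisy, 0.0, 1.0))
            i_f_total = noisy * total_intensity
            i_p = (1.0 - noisy) * total_intensity
            # distribute fragment intensity across the fragment channels
            fracs = np.full(len(spec.fragment_mzs), 1.0 / len(spec.fragment_mzs))
            peaks = [(spec.precursor_mz, i_p)] + [
                (f, i_f_total * frac) for f, frac in zip(spec.fragment_mzs, fracs)
            ]
            records.append(ScanRecord(float(wn), float(e), rep, peaks))

    series = ScanSeries.from_fragment_mzs(
        records, spec.precursor_mz, list(spec.fragment_mzs)
    )
    truth = normalize(IRSpectrum(grid, target, kind="experimental"))
    return series, truth


def make_conformer_set(
    n: int,
    energy_spread: float,
    band_centers: list[float] | None = None,
    seed: int = 0,
    site_tags: list[str] | None = None,
    temperature: float = 298.15,
) -> tuple[list[ConformerRecord], np.ndarray]:
    """Sample ``n`` conformers with energies spanning ``energy_spread`` kJ/mol.

    Energies are evenly spaced from 0 to ``energy_spread`` (n = 1 gives a
    single conformer at 0); stick spectra place one band per center with
    seeded intensities. Returns the records and their exact Boltzmann
    weights at ``temperature``.
    """
    if n < 1:
        raise ValueError("need n >= 1 conformers")
    rng = np.random.default_rng(seed)
    centers = band_centers if band_centers is not None else [1100.0, 1700.0]
    energies = (
        np.linspace(0.0, energy_spread, n) if n > 1 else np.array([0.0])
    )
    records = []
    for i, g in enumerate(energies):
        freqs = np.array(centers, dtype=float) + rng.normal(0.0, 5.0, len(centers))
        intens = rng.uniform(50.0, 300.0, len(centers))
        records.append(
            ConformerRecord(
                id=f"synth{i}",
                gibbs_free_energy=float(g),
                frequencies=np.sort(freqs),
                intensities=intens,
                ionization_site_tag=(site_tags[i % len(site_tags)] if site_tags else "O1"),
                geometry_fingerprint=tuple(rng.uniform(0.5, 3.0, 3)),
            )
        )
    weights = boltzmann_weights(energies, temperature)
    return records, weights


def make_isomer_pair(
    shift: float,
    seed: int = 0,
    noise_sigma: float = 0.02,
    broadening: BroadeningPolicy = BroadeningPolicy(grid_stop=1900.0),
) -> tuple[IRSpectrum, IRSpectrum, IRSpectrum]:
    """(truth, decoy, noisy experimental) spectra for a discrimination test.

    The decoy is identical to the truth except its carbonyl-stretch band is
    displaced by ``shift`` cm^-1 — the classic isomer-discrimination
    signature. The experimental spectrum is the truth plus seeded Gaussian
    noise of relative amplitude ``noise_sigma``.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    rng = np.random.default_rng(seed)
    grid = broadening.grid()
    base_bands = [(1100.0, 0.7, 40.0), (1450.0, 0.4, 35.0)]
    co_band = (1740.0, 1.0, broadening.fwhm)
    truth_vals = gaussian_bands(grid, base_bands + [co_band])
    decoy_vals = gaussian_bands(
        grid, base_bands + [(co_band[0] + shift, co_band[1], co_band[2])]
    )
    exp_vals = np.clip(
        truth_vals + rng.normal(0.0, noise_sigma * truth_vals.max(), grid.size),
        0.0,
        None,
    )
    truth = normalize(IRSpectrum(grid, truth_vals, kind="theoretical"))
    decoy = normalize(IRSpectrum(grid, decoy_vals, kind="theoretical"))
    experimental = normalize(IRSpectrum(grid, exp_vals, kind="experimental"))
    return truth, decoy, experimental
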