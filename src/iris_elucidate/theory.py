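"""Boltzmann-weighted theoretical IR spectra from harmonic conformer data.

The pipeline mirrors the standard quantum-chemistry post-processing used to
compare computed spectra against IR ion spectroscopy:

1. duplicate conformers are collapsed (energy + geometry fingerprint);
2. the ensemble is filtered by a relative Gibbs free-energy window
   (default 40 kJ/mol) and a per-ionization-site conformer cap (default 20);
3. harmonic frequencies are scaled (0.975 below 2500 cm^-1, 0.955 above;
   modes dominated by an S atom instead use 1.049, which compensates the
   systematic B3LYP error of sulfonate S-O stretches);
4. each stick spectrum is broadened with a 20 cm^-1 FWHM Gaussian;
5. conformer spectra are averaged with Boltzmann weights at 298.15 K and
   the result max-normalized.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .constants import HARTREE_TO_KJ_MOL, R_GAS
from .spectrum import IRSpectrum, normalize

__all__ = [
    "ConformerRecord",
    "EnsemblePolicy",
    "ScalingPolicy",
    "BroadeningPolicy",
    "dedup_conformers",
    "filter_ensemble",
    "boltzmann_weights",
    "scale_frequencies",
    "broaden",
    "ensemble_spectrum",
    "parse_frequency_output",
]


@dataclass
class ConformerRecord:
    """One conformer: free energy plus its harmonic stick spectrum."""

    id: str
    gibbs_free_energy: float  # kJ/mol (relative or absolute; only differences matter)
    frequencies: np.ndarray  # cm^-1
    intensities: np.ndarray  # km/mol
    ionization_site_tag: str = ""
    s_mode_flags: np.ndarray | None = None
    geometry_fingerprint: tuple[float, float, float] | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequencies and intensities must have equal length")
        if np.any(self.frequencies <= 0):
            # imaginary modes come out of harmonic analysis as negative numbers
            self.valid = False
        if np.any(self.intensities < 0):
            raise ValueError("IR intensities must be non-negative")
        if self.s_mode_flags is not None:
            self.s_mode_flags = np.asarray(self.s_mode_flags, dtype=bool)
            if self.s_mode_flags.shape != self.frequencies.shape:
                raise ValueError("s_mode_flags length must match frequencies")


@dataclass(frozen=True)
class EnsemblePolicy:
    """Relative-energy window, per-site cap, and weighting temperature."""

    energy_cutoff: float = 40.0  # kJ/mol, inclusive
    per_site_cap: int = 20
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.energy_cutoff <= 0:
            raise ValueError("energy cutoff must be positive")
        if self.per_site_cap < 1:
            raise ValueError("per-site cap must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class ScalingPolicy:
    """Empirical harmonic-frequency scaling factors."""

    fingerprint_factor: float = 0.975
    high_factor: float = 0.955
    boundary: float = 2500.0  # cm^-1, applied to the unscaled frequency
    s_mode_factor: float = 1.049

    def __post_init__(self) -> None:
        for f in (self.fingerprint_factor, self.high_factor, self.s_mode_factor):
            if f <= 0:
                raise ValueError("scaling factors must be positive")


@dataclass(frozen=True)
class BroadeningPolicy:
    """Gaussian line broadening on a regular output grid."""

    fwhm: float = 20.0  # cm^-1
    grid_start: float = 550.0
    grid_stop: float = 3700.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValueError("grid must be ascending")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


def dedup_conformers(
    records: list[ConformerRecord],
    energy_tol: float = 0.1,
    fingerprint_tol: float = 0.01,
) -> list[ConformerRecord]:
    """Collapse duplicate conformers to their lowest-energy representative.

    Two records are duplicates when their energies agree within
    ``energy_tol`` kJ/mol and their rotational-constant fingerprints agree
    within a relative ``fingerprint_tol`` per axis. Records without a
    fingerprint are compared on energy alone.
    """
    kept: list[ConformerRecord] = []
    for rec in sorted(records, key=lambda r: r.gibbs_free_energy):
        dup = False
        for ref in kept:
            if abs(rec.gibbs_free_energy - ref.gibbs_free_energy) > energy_tol:
                continue
            fa, fb = rec.geometry_fingerprint, ref.geometry_fingerprint
            if fa is None or fb is None:
                dup = True
            else:
                dup = all(
                    abs(x - y) <= fingerprint_tol * max(abs(x), abs(y), 1e-12)
                    for x, y in zip(fa, fb)
                )
            if dup:
                break
        if not dup:
            kept.append(rec)
    return kept


def filter_ensemble(
    records: list[ConformerRecord], policy: EnsemblePolicy = EnsemblePolicy()
) -> list[ConformerRecord]:
    """Energy-window filter (inclusive cutoff) then per-site conformer cap."""
    records = [r for r in records if r.valid]
    if not records:
        raise ValueError("no valid conformer records to filter")
    gmin = min(r.gibbs_free_energy for r in records)
    windowed = [
        r for r in records if r.gibbs_free_energy - gmin <= policy.energy_cutoff
    ]
    by_site: dict[str, list[ConformerRecord]] = {}
    for r in windowed:
        by_site.setdefault(r.ionization_site_tag, []).append(r)
    out: list[ConformerRecord] = []
    for site in by_site:
        ranked = sorted(by_site[site], key=lambda r: (r.gibbs_free_energy, r.id))
        out.extend(ranked[: policy.per_site_cap])
    out.sort(key=lambda r: (r.gibbs_free_energy, r.id))
    return out


def boltzmann_weights(
    free_energies: np.ndarray | list[float], temperature: float = 298.15
) -> np.ndarray:
    """Normalized Boltzmann populations exp(-dG/RT) / sum.

    Energies in kJ/mol; the minimum is shifted to zero first, which makes the
    computation overflow-safe and the weights invariant under any uniform
    energy offset.
    """
    g = np.asarray(free_energies, dtype=float)
    if g.size == 0:
        raise ValueError("need at least one free energy")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rt = R_GAS * temperature / 1000.0  # kJ/mol
    x = np.exp(-(g - g.min()) / rt)
    return x / x.sum()


def scale_frequencies(
    freqs: np.ndarray | list[float],
    s_mode_flags: np.ndarray | list[bool] | None = None,
    policy: ScalingPolicy = ScalingPolicy(),
) -> np.ndarray:
    """Apply region- and mode-dependent scaling factors to harmonic frequencies.

    The region boundary is evaluated on the unscaled frequency; the S-mode
    factor replaces the fingerprint factor where flagged.
    """
    f = np.asarray(freqs, dtype=float)
    factors = np.where(f < policy.boundary, policy.fingerprint_factor, policy.high_factor)
    if s_mode_flags is not None:
        flags = np.asarray(s_mode_flags, dtype=bool)
        if flags.shape != f.shape:
            raise ValueError("s_mode_flags length must match frequencies")
        factors = np.where(flags, policy.s_mode_factor, factors)
    return f * factors


def broaden(
    sticks: list[tuple[float, float]] | np.ndarray,
    policy: BroadeningPolicy = BroadeningPolicy(),
) -> IRSpectrum:
    """Convolve a stick spectrum with a normalized Gaussian lineshape.

    Each stick of intensity I contributes an area-I Gaussian, so the
    integrated spectrum over an unbounded grid equals the summed stick
    intensities; broadening is therefore linear in the stick list.
    """
    grid = policy.grid()
    values = np.zeros_like(grid)
    sigma = policy.sigma
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    arr = np.asarray(sticks, dtype=float).reshape(-1, 2) if len(sticks) else np.empty((0, 2))
    for freq, inten in arr:
        values += inten * norm * np.exp(-((grid - freq) ** 2) / (2.0 * sigma**2))
    return IRSpectrum(grid, values, kind="theoretical")


def ensemble_spectrum(
    records: list[ConformerRecord],
    ensemble: EnsemblePolicy = EnsemblePolicy(),
    scaling: ScalingPolicy = ScalingPolicy(),
    broadening: BroadeningPolicy = BroadeningPolicy(),
    dedup: bool = True,
) -> IRSpectrum:
    """Full assembly: dedup -> filter -> scale+broaden -> weight-sum -> normalize."""
    if dedup:
        records = dedup_conformers(records)
    retained = filter_ensemble(records, ensemble)
    weights = boltzmann_weights(
        [r.gibbs_free_energy for r in retained], ensemble.temperature
    )
    grid = broadening.grid()
    total = np.zeros_like(grid)
    for w, rec in zip(weights, retained):
        scaled = scale_frequencies(rec.frequencies, rec.s_mode_flags, scaling)
        spec = broaden(list(zip(scaled, rec.intensities)), broadening)
        total += w * spec.values
    return normalize(IRSpectrum(grid, total, kind="theoretical"))


# ---------------------------------------------------------------------------
# quantum-chemistry frequency-block text parser
# ---------------------------------------------------------------------------

_FREQ_RE = re.compile(r"Frequencies\s*--\s*(.+)")
_INTEN_RE = re.compile(r"IR Inten\s*--\s*(.+)")
_GIBBS_RE = re.compile(
    r"Sum of electronic and thermal Free Energies\s*=\s*(-?\d+\.\d+)"
)


def parse_frequency_output(text: str, id_prefix: str = "conf") -> list[ConformerRecord]:
    """Extract conformer records from concatenated frequency-job text output.

    Recognizes the common ``Frequencies --`` / ``IR Inten --`` block layout
    and the thermochemistry line ``Sum of electronic and thermal Free
    Energies= <Hartree>``. A record closes at each thermochemistry line;
    free energies are converted to kJ/mol. Records containing imaginary
    (negative) frequencies are returned with ``valid=False``.
    """
    records: list[ConformerRecord] = []
    freqs: list[float] = []
    intens: list[float] = []
    for line in text.splitlines():
        m = _FREQ_RE.search(line)
        if m:
            freqs.extend(float(x) for x in m.group(1).split())
            continue
        m = _INTEN_RE.search(line)
        if m:
            intens.extend(float(x) for x in m.group(1).split())
            continue
        m = _GIBBS_RE.search(line)
        if m:
            if not freqs:
                raise ValueError(
                    "thermochemistry without a preceding frequency block"
                )
            if len(freqs) != len(intens):
                raise ValueError(
                    f"parsed {len(freqs)} frequencies but {len(intens)} intensities"
                )
            g = float(m.group(1)) * HARTREE_TO_KJ_MOL
            rec = ConformerRecord(
                id=f"{id_prefix}{len(records)}",
                gibbs_free_energy=g,
                frequencies=np.abs(freqs),
                intensities=np.array(intens),
            )
            if any(f <= 0 for f in freqs):
                rec.valid = False
            records.append(rec)
            freqs, intens = [], []
    if not records:
        raise ValueError("no complete frequency block with thermochemistry found")
    return records
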