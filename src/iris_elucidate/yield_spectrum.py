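"""IR ion spectra from wavelength-stepped ion-trap fragmentation scans.

At each laser wavelength step the trapped precursor ion is irradiated and a
fragmentation mass spectrum recorded. On resonance, precursor intensity
(I_P) converts into fragment intensity (sum I_F), and the dissociation yield

    Y = sum(I_F) / (I_P + sum(I_F))

is proportional to the dissociation rate, so plotting Y against wavenumber
gives the vibrational spectrum of the ion. Replicate mass spectra at a step
are intensity-averaged before the yield is computed, and the yield is
corrected linearly for the wavelength-dependent laser pulse energy
(division by the mean pulse energy across replicates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectrum import IRSpectrum

__all__ = [
    "ScanRecord",
    "ScanSeries",
    "compute_yield",
    "build_spectrum",
    "read_scan_series_csv",
    "write_scan_series_csv",
]

logger = logging.getLogger(__name__)

#: full scan range of the free-electron laser, cm^-1
SCAN_RANGE = (550.0, 3700.0)


@dataclass
class ScanRecord:
    """One replicate mass spectrum at one laser wavelength step."""

    wavenumber: float
    pulse_energy: float
    replicate_index: int
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.replicate_index < 0:
            raise ValueError("replicate index must be >= 0")
        for mz, inten in self.peaks:
            if inten < 0:
                raise ValueError(f"negative intensity at m/z {mz}")


@dataclass
class ScanSeries:
    """An ordered collection of scan records plus the windows that define
    precursor and fragment integration regions."""

    records: list[ScanRecord]
    precursor_mz: float
    fragment_windows: list[tuple[float, float]]
    grid_step: float | None = None
    precursor_halfwidth: float = 0.5

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("scan series is empty")
        if self.grid_step is None:
            self.grid_step = detect_grid_step([r.wavenumber for r in self.records])

    @property
    def precursor_window(self) -> tuple[float, float]:
        return (
            self.precursor_mz - self.precursor_halfwidth,
            self.precursor_mz + self.precursor_halfwidth,
        )

    @classmethod
    def from_fragment_mzs(
        cls,
        records: list[ScanRecord],
        precursor_mz: float,
        fragment_mzs: list[float],
        halfwidth: float = 0.5,
        **kw,
    ) -> "ScanSeries":
        windows = [(f - halfwidth, f + halfwidth) for f in fragment_mzs]
        return cls(records, precursor_mz, windows, precursor_halfwidth=halfwidth, **kw)


def detect_grid_step(wavenumbers: list[float]) -> float | None:
    """Most common positive difference between consecutive unique steps."""
    uniq = sorted(set(wavenumbers))
    if len(uniq) < 2:
        return None
    diffs = np.diff(uniq)
    vals, counts = np.unique(np.round(diffs, 6), return_counts=True)
    return float(vals[np.argmax(counts)])


def _window_sum(peaks: list[tuple[float, float]], window: tuple[float, float]) -> float:
    lo, hi = window
    return sum(inten for mz, inten in peaks if lo <= mz <= hi)


def _validate_windows(
    precursor_window: tuple[float, float], fragment_windows: list[tuple[float, float]]
) -> None:
    plo, phi = precursor_window
    for lo, hi in fragment_windows:
        if lo > hi:
            raise ValueError(f"fragment window ({lo}, {hi}) is inverted")
        if not (hi < plo or lo > phi):
            raise ValueError(
                f"fragment window ({lo}, {hi}) overlaps the precursor window "
                f"({plo}, {phi})"
            )


def compute_yield(
    record: ScanRecord,
    precursor_mz: float,
    fragment_windows: list[tuple[float, float]],
    mz_tol: float = 0.5,
) -> float | None:
    """Dissociation yield Y = sum(I_F) / (I_P + sum(I_F)) for one record.

    Returns ``None`` (a flagged missing point) when neither precursor nor
    fragment intensity is present. Overlapping windows are a validation
    error, not a silent double count.
    """
    pwin = (precursor_mz - mz_tol, precursor_mz + mz_tol)
    _validate_windows(pwin, fragment_windows)
    i_p = _window_sum(record.peaks, pwin)
    i_f = sum(_window_sum(record.peaks, w) for w in fragment_windows)
    total = i_p + i_f
    if total == 0:
        return None
    return i_f / total


def build_spectrum(
    series: ScanSeries, power_correction: bool = True, log_yield: bool = False
) -> IRSpectrum:
    """Assemble the IR ion spectrum from a scan series.

    Per wavelength step, replicate mass spectra are intensity-averaged
    before the yield is computed (for windowed sums this equals averaging
    the windowed intensities, both being linear), then the yield is divided
    by the mean pulse energy when ``power_correction`` is on. Steps with no
    usable signal are recorded as gaps, never interpolated.

    ``log_yield`` switches the corrected quantity from Y to -ln(1 - Y),
    the first-order-kinetics depletion form; both are proportional to the
    absorption cross-section in the one-photon limit. Complete depletion
    (Y = 1) is clamped just below 1 to keep the logarithm finite.
    """
    _validate_windows(series.precursor_window, series.fragment_windows)
    by_step: dict[float, list[ScanRecord]] = {}
    for rec in series.records:
        by_step.setdefault(rec.wavenumber, []).append(rec)

    grid, values, gaps = [], [], []
    for wn in sorted(by_step):
        reps = by_step[wn]
        if power_correction:
            for r in reps:
                if r.pulse_energy <= 0:
                    raise ValueError(
                        f"non-positive pulse energy at step {wn} cm^-1 "
                        f"(replicate {r.replicate_index})"
                    )
        # average of replicate spectra == mean of windowed intensities
        i_p = float(
            np.mean([_window_sum(r.peaks, series.precursor_window) for r in reps])
        )
        i_f = float(
            np.mean(
                [
                    sum(_window_sum(r.peaks, w) for w in series.fragment_windows)
                    for r in reps
                ]
            )
        )
        total = i_p + i_f
        if total == 0:
            logger.warning("no ion signal at %.1f cm^-1; point dropped", wn)
            gaps.append(wn)
            continue
        y = i_f / total
        if log_yield:
            y = -np.log(max(1.0 - y, 1e-12))
        if power_correction:
            y /= float(np.mean([r.pulse_energy for r in reps]))
        grid.append(wn)
        values.append(y)

    return IRSpectrum(np.array(grid), np.array(values), kind="experimental", gaps=gaps)


# ---------------------------------------------------------------------------
# long-format CSV I/O: wavenumber, pulse_energy, replicate, mz, intensity
# ---------------------------------------------------------------------------

def write_scan_series_csv(series: ScanSeries, path: str | Path) -> None:
    rows = []
    for rec in series.records:
        for mz, inten in rec.peaks:
            rows.append(
                {
                    "wavenumber": rec.wavenumber,
                    "pulse_energy": rec.pulse_energy,
                    "replicate": rec.replicate_index,
                    "mz": mz,
                    "intensity": inten,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scan_series_csv(
    path: str | Path,
    precursor_mz: float,
    fragment_mzs: list[float],
    halfwidth: float = 0.5,
) -> ScanSeries:
    df = pd.read_csv(path)
    records = []
    for (wn, energy, rep), grp in df.groupby(
        ["wavenumber", "pulse_energy", "replicate"], sort=True
    ):
        peaks = list(zip(grp["mz"].astype(float), grp["intensity"].astype(float)))
        records.append(ScanRecord(float(wn), float(energy), int(rep), peaks))
    return ScanSeries.from_fragment_mzs(records, precursor_mz, fragment_mzs, halfwidth)
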