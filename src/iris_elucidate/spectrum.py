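"""The IR spectrum container shared by the experimental and theoretical paths."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["IRSpectrum", "normalize"]


@dataclass
class IRSpectrum:
    """A wavenumber grid with non-negative intensities.

    ``kind`` distinguishes measured ion spectra from computed ones;
    ``normalized`` records whether the values have been max-normalized.
    The grid must be strictly ascending.
    """

    grid: np.ndarray
    values: np.ndarray
    kind: str = "experimental"  # or "theoretical"
    normalized: bool = False
    #: wavenumbers of steps that produced no usable data point
    gaps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")
        if self.kind not in ("experimental", "theoretical"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def copy(self) -> "IRSpectrum":
        return replace(self, grid=self.grid.copy(), values=self.values.copy(),
                       gaps=list(self.gaps))

    def normalize(self) -> "IRSpectrum":
        return normalize(self)

    # -- plain-text I/O (two columns: wavenumber, intensity) ---------------
    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        lines = [f"{w:.6g}{sep}{v:.8g}" for w, v in zip(self.grid, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path, kind: str = "experimental") -> "IRSpectrum":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            rows.append((float(parts[0]), float(parts[1])))
        rows.sort()
        grid = np.array([r[0] for r in rows])
        vals = np.array([r[1] for r in rows])
        return cls(grid, vals, kind=kind)


def normalize(spec: IRSpectrum) -> IRSpectrum:
    """Max-normalized copy; an all-zero spectrum is returned unchanged
    (but marked normalized). Idempotent."""
    out = spec.copy()
    peak = out.values.max(initial=0.0)
    if peak > 0:
        out.values = out.values / peak
    out.normalized = True
    return out
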