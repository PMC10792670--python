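"""Experimental-vs-theoretical spectral matching and candidate ranking.

The field's practice of matching measured ion spectra against computed
candidate spectra by eye is made quantitative here with a scale-invariant
similarity score (cosine on max-normalized, grid-matched spectra by
default; Pearson mapped to [0,1] as an alternative), optional weighting of
diagnostic wavenumber regions (for instance the C=O stretch region), and a
configurable exclusion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import IRSpectrum, normalize

__all__ = [
    "MatchResult",
    "RegionWeighting",
    "DIAGNOSTIC_REGIONS",
    "resample",
    "similarity",
    "rank_candidates",
]

#: diagnostic wavenumber intervals commonly used to discriminate isomers:
#: the carbonyl stretch and the alkene CH-bend regions
DIAGNOSTIC_REGIONS: dict[str, tuple[float, float]] = {
    "C=O stretch": (1700.0, 1800.0),
    "CH bend": (1050.0, 1125.0),
}


@dataclass(frozen=True)
class RegionWeighting:
    """Per-interval weights; grid points outside all intervals keep weight 1."""

    intervals: tuple[tuple[float, float, float], ...]  # (start, stop, weight)

    def __post_init__(self) -> None:
        for start, stop, w in self.intervals:
            if stop <= start:
                raise ValueError(f"interval ({start}, {stop}) is not ascending")
            if not np.isfinite(w) or w < 0:
                raise ValueError("weights must be finite and non-negative")

    def weights_on(self, grid: np.ndarray) -> np.ndarray:
        w = np.ones_like(grid, dtype=float)
        for start, stop, weight in self.intervals:
            w[(grid >= start) & (grid <= stop)] = weight
        return w


@dataclass(frozen=True)
class MatchResult:
    """Score, rank and exclusion flag for one candidate spectrum."""

    candidate_id: str
    score: float
    rank: int
    excluded: bool
    region_scores: dict[str, float] | None = None


def resample(spec: IRSpectrum, grid: np.ndarray) -> IRSpectrum:
    """Linear interpolation onto ``grid``; extrapolation is refused.

    Normalization state is preserved by re-normalizing when the source was
    normalized.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < spec.grid.min() - 1e-9 or grid.max() > spec.grid.max() + 1e-9:
        raise ValueError(
            f"target grid [{grid.min()}, {grid.max()}] exceeds source span "
            f"[{spec.grid.min()}, {spec.grid.max()}]"
        )
    vals = np.interp(grid, spec.grid, spec.values)
    out = IRSpectrum(grid, vals, kind=spec.kind)
    return normalize(out) if spec.normalized else out


def _common_grid(a: IRSpectrum, b: IRSpectrum) -> np.ndarray:
    lo = max(a.grid.min(), b.grid.min())
    hi = min(a.grid.max(), b.grid.max())
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavenumber range")
    # densest of the two grids over the overlap
    step = min(np.diff(a.grid).min(), np.diff(b.grid).min())
    return np.arange(lo, hi + step / 2, step)


def similarity(
    a: IRSpectrum,
    b: IRSpectrum,
    method: str = "cosine",
    weighting: RegionWeighting | None = None,
) -> float:
    """Similarity in [0, 1] between two spectra on their joint grid.

    ``cosine``: weighted inner product of max-normalized spectra (invariant
    under uniform intensity rescaling of either input). ``pearson``:
    correlation mapped through (r+1)/2. Zero spectra have no defined score.
    """
    if a.values.max(initial=0.0) == 0 or b.values.max(initial=0.0) == 0:
        raise ValueError("similarity is undefined for an all-zero spectrum")
    grid = _common_grid(a, b)
    x = resample(normalize(a), grid).values
    y = resample(normalize(b), grid).values
    w = weighting.weights_on(grid) if weighting is not None else np.ones_like(grid)
    if method == "cosine":
        num = float(np.sum(w * x * y))
        den = float(np.sqrt(np.sum(w * x * x) * np.sum(w * y * y)))
        if den == 0:
            raise ValueError("similarity is undefined: zero overlap energy")
        return float(np.clip(num / den, 0.0, 1.0))
    if method == "pearson":
        sw = w.sum()
        mx, my = np.sum(w * x) / sw, np.sum(w * y) / sw
        cov = np.sum(w * (x - mx) * (y - my))
        den = np.sqrt(np.sum(w * (x - mx) ** 2) * np.sum(w * (y - my) ** 2))
        if den == 0:
            raise ValueError("pearson similarity undefined for constant spectra")
        r = cov / den
        return float(np.clip((r + 1.0) / 2.0, 0.0, 1.0))
    raise ValueError(f"unknown similarity method {method!r}")


def rank_candidates(
    experimental: IRSpectrum,
    theoretical: dict[str, IRSpectrum],
    threshold: float = 0.8,
    weighting: RegionWeighting | None = None,
    method: str = "cosine",
    region_report: dict[str, tuple[float, float]] | None = None,
) -> list[MatchResult]:
    """Score and sort candidates by descending similarity.

    Ties break lexicographically on candidate id, so the ranking is a
    deterministic permutation of the inputs regardless of dict order.
    Candidates scoring below ``threshold`` are flagged excluded.
    ``region_report`` adds per-region scores (similarity restricted to each
    named interval) to every result.
    """
    if not theoretical:
        raise ValueError("need at least one candidate spectrum")
    scored: list[tuple[float, str]] = []
    regions: dict[str, dict[str, float]] = {}
    for cid, spec in theoretical.items():
        scored.append((similarity(experimental, spec, method, weighting), cid))
        if region_report:
            regions[cid] = {
                name: _region_similarity(experimental, spec, span, method)
                for name, span in region_report.items()
            }
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        MatchResult(
            candidate_id=cid,
            score=score,
            rank=i + 1,
            excluded=score < threshold,
            region_scores=regions.get(cid),
        )
        for i, (score, cid) in enumerate(scored)
    ]


def _region_similarity(
    a: IRSpectrum, b: IRSpectrum, region: tuple[float, float], method: str
) -> float:
    """Similarity computed on the sub-grid inside ``region`` only."""
    start, stop = region
    grid = _common_grid(a, b)
    sub = grid[(grid >= start) & (grid <= stop)]
    if sub.size < 2:
        raise ValueError(f"region ({start}, {stop}) contains no grid points")
    x = resample(normalize(a), sub).values
    y = resample(normalize(b), sub).values
    num = float(np.sum(x * y))
    den = float(np.sqrt(np.sum(x * x) * np.sum(y * y)))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))
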