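"""Chemical formulas, ion m/z arithmetic, and mass-shift / MS-MS annotation.

The conventions follow high-resolution accurate-mass (HRAM) practice for
electrospray adducts of small molecules:

* masses are monoisotopic sums over a bundled isotope table;
* ion m/z values are electron-corrected by default (the electron mass is
  subtracted for cations and added for anions), which is what reproduces
  printed FTICR accurate masses at the sixth decimal;
* nominal m/z is the monoisotopic m/z rounded half away from zero, matching
  the unit-resolution fragment labels customary in ion-trap MS/MS work.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

from .constants import ELECTRON_MASS, ISOTOPE_MASSES

__all__ = [
    "ChemicalFormula",
    "FormulaError",
    "IonSpecies",
    "MassShift",
    "MassShiftLibrary",
    "FragmentAnnotation",
    "ION_TYPES",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "nominal_mz",
    "ppm_error",
    "annotate_mass_shift",
    "annotate_msms",
    "default_mass_shift_library",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: supported ion types -> (adduct formula delta, charge)
ION_TYPES: dict[str, tuple[dict[str, int], int]] = {
    "[M+H]+": ({"H": 1}, +1),
    "[M-H]-": ({"H": -1}, -1),
    "[M+Na]+": ({"Na": 1}, +1),
}


class FormulaError(ValueError):
    """Raised for unparsable formulas or elements missing from the table."""


@dataclass(frozen=True)
class ChemicalFormula:
    """An element -> count map with monoisotopic-mass semantics.

    Counts may be negative only in *delta* formulas (mass-shift entries);
    plain molecular formulas must be non-negative, which :meth:`validate`
    enforces.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # drop zero counts so equality/hash behave set-like
        object.__setattr__(
            self, "counts", {el: n for el, n in self.counts.items() if n != 0}
        )

    def validate(self) -> "ChemicalFormula":
        bad = [el for el, n in self.counts.items() if n < 0]
        if bad:
            raise FormulaError(f"negative element counts for {bad}")
        return self

    def mass(self, isotope_table: dict[str, float] | None = None) -> float:
        return monoisotopic_mass(self, isotope_table)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ChemicalFormula(merged)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
        return ChemicalFormula(merged)

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        items = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if el in rest:
                items.append((el, rest.pop(el)))
        items.extend(sorted(rest.items()))
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in items)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-style formula string such as ``"C35H48O9"``.

    An empty string parses to the empty formula (mass 0). Unknown element
    symbols raise :class:`FormulaError` naming the symbol.
    """
    if text is None:
        raise FormulaError("formula text is None")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ISOTOPE_MASSES:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ChemicalFormula(counts).validate()


def monoisotopic_mass(
    formula: ChemicalFormula | dict[str, int] | str,
    isotope_table: dict[str, float] | None = None,
) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    table = ISOTOPE_MASSES if isotope_table is None else isotope_table
    if isinstance(formula, str):
        formula = parse_formula(formula)
    counts = formula.counts if isinstance(formula, ChemicalFormula) else formula
    total = 0.0
    for el, n in counts.items():
        if el not in table:
            raise FormulaError(f"element {el!r} missing from isotope table")
        total += n * table[el]
    return total


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ion of a neutral formula.

    ``ion_type`` is one of ``[M+H]+``, ``[M-H]-``, ``[M+Na]+``; the charge
    is implied by the ion type and checked for consistency. The m/z is always
    computed on demand, never stored.
    """

    formula: ChemicalFormula
    ion_type: str
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.ion_type not in ION_TYPES:
            raise ValueError(
                f"unsupported ion type {self.ion_type!r}; "
                f"supported: {sorted(ION_TYPES)}"
            )
        implied = ION_TYPES[self.ion_type][1]
        if self.charge is None:
            object.__setattr__(self, "charge", implied)
        elif self.charge != implied:
            raise ValueError(
                f"charge {self.charge} inconsistent with ion type {self.ion_type}"
            )

    @property
    def mz(self) -> float:
        return ion_mz(self.formula, self.ion_type)


def ion_mz(
    formula: ChemicalFormula | str,
    ion_type: str,
    electron_correction: bool = True,
    isotope_table: dict[str, float] | None = None,
) -> float:
    """m/z of a singly charged adduct/deprotonated ion of ``formula``.

    The adduct mass is added to the neutral monoisotopic mass and the
    electron mass subtracted for cations (added for anions) unless
    ``electron_correction`` is disabled.
    """
    if ion_type not in ION_TYPES:
        raise ValueError(
            f"unsupported ion type {ion_type!r}; supported: {sorted(ION_TYPES)}"
        )
    delta, charge = ION_TYPES[ion_type]
    m = monoisotopic_mass(formula, isotope_table) + monoisotopic_mass(
        delta, isotope_table
    )
    if electron_correction:
        m -= charge * ELECTRON_MASS
    return m / abs(charge)


def nominal_mz(mz: float) -> int:
    """Unit-resolution m/z: round half away from zero."""
    return int(math.floor(abs(mz) + 0.5)) * (1 if mz >= 0 else -1)


def ppm_error(observed: float, calculated: float) -> float:
    """Relative mass error in parts per million."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return 1e6 * (observed - calculated) / calculated


@dataclass(frozen=True)
class MassShift:
    """One named biotransformation / neutral-loss mass delta."""

    label: str
    delta_formula: ChemicalFormula
    delta_mass: float

    def check(self, tol: float = 1e-6) -> None:
        expected = monoisotopic_mass(self.delta_formula)
        if abs(expected - self.delta_mass) > tol:
            raise ValueError(
                f"mass shift {self.label!r}: stated delta {self.delta_mass} "
                f"differs from formula mass {expected}"
            )


def _delta(counts: dict[str, int]) -> ChemicalFormula:
    return ChemicalFormula(counts)


@dataclass
class MassShiftLibrary:
    """Collection of mass shifts used for shift and neutral-loss annotation."""

    entries: list[MassShift]

    def __post_init__(self) -> None:
        for e in self.entries:
            e.check()

    def __iter__(self):
        return iter(self.entries)


def default_mass_shift_library(
    ester_cleavage_loss: dict[str, int] | None = None,
) -> MassShiftLibrary:
    """The shifts relevant to phase I/II metabolism of geranyl ester parents.

    ``ester_cleavage_loss`` configures the composition lost on ester
    cleavage (default: a geranyl-tail loss, -C10H16).
    """
    shifts = [
        MassShift("hydroxylation (+O)", _delta({"O": 1}), monoisotopic_mass({"O": 1})),
        MassShift(
            "sulfonation (+SO3)",
            _delta({"S": 1, "O": 3}),
            monoisotopic_mass({"S": 1, "O": 3}),
        ),
        MassShift(
            "glucuronidation (+C6H8O6)",
            _delta({"C": 6, "H": 8, "O": 6}),
            monoisotopic_mass({"C": 6, "H": 8, "O": 6}),
        ),
        MassShift(
            "water loss (-H2O)",
            _delta({"H": -2, "O": -1}),
            -monoisotopic_mass({"H": 2, "O": 1}),
        ),
        MassShift(
            "SO3 loss (-SO3)",
            _delta({"S": -1, "O": -3}),
            -monoisotopic_mass({"S": 1, "O": 3}),
        ),
        MassShift(
            "glucuronide loss (-C6H8O6)",
            _delta({"C": -6, "H": -8, "O": -6}),
            -monoisotopic_mass({"C": 6, "H": 8, "O": 6}),
        ),
        MassShift(
            "geranyl loss (-C10H16)",
            _delta({"C": -10, "H": -16}),
            -monoisotopic_mass({"C": 10, "H": 16}),
        ),
    ]
    loss = ester_cleavage_loss if ester_cleavage_loss is not None else {"C": 10, "H": 16}
    shifts.append(
        MassShift(
            "ester-cleavage loss",
            _delta({el: -n for el, n in loss.items()}),
            -monoisotopic_mass(loss),
        )
    )
    return MassShiftLibrary(shifts)


def annotate_mass_shift(
    mz_low: float, mz_high: float, lib: MassShiftLibrary, tol: float = 0.01
) -> list[str]:
    """Labels of library entries whose delta matches ``mz_high - mz_low``.

    Matches within ``tol`` Da, sorted by absolute residual. An exact-zero
    difference returns no annotation (identity is not a shift).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    observed = mz_high - mz_low
    hits = [
        (abs(e.delta_mass - observed), e.label)
        for e in lib
        if abs(e.delta_mass - observed) <= tol
    ]
    hits.sort()
    return [label for _, label in hits]


@dataclass(frozen=True)
class FragmentAnnotation:
    """Annotation of one MS/MS fragment against a precursor ion."""

    fragment_mz: float
    losses: tuple[str, ...]  # empty when unannotated
    expected_mz: float | None
    residual_ppm: float | None

    @property
    def annotated(self) -> bool:
        return bool(self.losses)


def annotate_msms(
    precursor: IonSpecies,
    fragments: list[float],
    lib: MassShiftLibrary,
    tol: float = 0.5,
    max_combined: int = 2,
) -> list[FragmentAnnotation]:
    """Annotate fragment m/z values with neutral losses from the library.

    Each fragment is matched against the best single loss or combination of
    at most ``max_combined`` losses (sums of negative-delta entries); the
    combination cap avoids combinatorial false positives. Fragments with no
    match within ``tol`` Da are returned flagged (empty loss tuple).
    """
    pmz = precursor.mz
    losses = [e for e in lib if e.delta_mass < 0]
    combos: list[tuple[tuple[str, ...], float]] = []
    for k in range(1, max_combined + 1):
        for combo in itertools.combinations_with_replacement(losses, k):
            combos.append(
                (tuple(e.label for e in combo), sum(e.delta_mass for e in combo))
            )

    out = []
    for fmz in fragments:
        best: tuple[float, tuple[str, ...], float] | None = None
        for labels, dm in combos:
            expected = pmz + dm
            resid = abs(fmz - expected)
            if resid <= tol and (best is None or resid < best[0]):
                best = (resid, labels, expected)
        if best is None:
            out.append(FragmentAnnotation(fmz, (), None, None))
        else:
            _, labels, expected = best
            out.append(
                FragmentAnnotation(fmz, labels, expected, ppm_error(fmz, expected))
            )
    return out
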