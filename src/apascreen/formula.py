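"""Molecular formulas and monoisotopic ion masses.

The mass convention used throughout the package is the one under which
the reference 3-APA m/z values are self-consistent: the m/z of an ion is
the plain formula mass of the charged species (added protons counted as
H atoms) divided by the charge, with *no* electron-mass correction.
Under this convention the tetrahydropyridine diagnostic fragment
C6H12N+ sits at m/z 98.0970; an electron-corrected value would be
98.0964.

Monoisotopic atomic masses are shipped as a versioned JSON data file
(``data/atomic_masses.json``); only C, H, N and O are needed for the
alkaloid classes modeled here, but the table is keyed by symbol and
extendable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "IonSpecies",
    "ATOMIC_MASSES",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "add_protons",
    "mz_round",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid element symbols."""


def _load_masses() -> dict[str, float]:
    with resources.files("apascreen.data").joinpath("atomic_masses.json").open() as fh:
        return dict(json.load(fh)["masses"])


#: Monoisotopic mass of each supported element, Da.
ATOMIC_MASSES: dict[str, float] = _load_masses()

# Hill order: carbon, hydrogen, then remaining elements alphabetically.
_HILL_HEAD = ("C", "H")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map; the atom-level currency of all mass math.

    Instances are immutable and hashable.  Counts must be non-negative,
    at least one count must be positive, and every element must have a
    defined monoisotopic mass.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n!r}")
            if n > 0:
                cleaned[el] = n
        if not cleaned:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", cleaned)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def serialize(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts = []
        rest = sorted(el for el in self.counts if el not in _HILL_HEAD)
        for el in (*_HILL_HEAD, *rest):
            n = self.counts.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular formula string such as ``"C30H48N2"``.

    Underscores and whitespace (as they appear in subscripted table
    notation, e.g. ``C_30_H_48_N_2``) are stripped before parsing.
    """
    cleaned = text.replace("_", "").replace(" ", "")
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.groups()
        if el not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass."""
    return sum(n * ATOMIC_MASSES[el] for el, n in f)


def add_protons(f: ElementalFormula, k: int) -> ElementalFormula:
    """Return the formula with ``k`` protons added, counted as H atoms."""
    if k < 0:
        raise ValueError(f"proton count must be >= 0, got {k}")
    if k == 0:
        return f
    return f + ElementalFormula({"H": k})


def ion_mz(ion_formula: ElementalFormula, charge: int) -> float:
    """m/z of a charged species: formula mass divided by charge.

    The caller is responsible for adding protons to the formula first
    (``add_protons``) when the species is a protonated molecule; natively
    charged polycations are passed as-is.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return monoisotopic_mass(ion_formula) / charge


def mz_round(mz: float, ndigits: int = 4) -> float:
    """Round-half-even to ``ndigits`` decimals, the reporting convention."""
    return round(mz, ndigits)


@dataclass(frozen=True)
class IonSpecies:
    """A charged species with its full formula (protons counted as H).

    ``label`` tags the ion type, e.g. ``"[M+2H]2+"`` for a protonated
    doubly charged molecular ion or ``"[M]2+"`` for a native dication.
    """

    ion_formula: ElementalFormula
    charge: int
    label: str
    mz: float = field(init=False)

    def __post_init__(self) -> None:
        if self.charge not in (1, 2, 3):
            raise ValueError(f"charge must be 1, 2 or 3, got {self.charge}")
        object.__setattr__(self, "mz", ion_mz(self.ion_formula, self.charge))
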