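"""Elemental-formula parsing and exact-mass arithmetic.

This module provides the small amount of chemistry needed by a targeted
high-resolution MS assay: parsing Hill-style molecular formulas, computing
monoisotopic masses from a curated table of monoisotopic atomic masses,
deriving adduct m/z values (the protonated molecular ion in positive ESI
being the default), and signed ppm mass-error arithmetic.

The atomic-mass table is deliberately small and explicit rather than pulled
from a periodic-table package: the assay only monitors CHNOS-type small
molecules, and a frozen table makes reported masses reproducible to the
4-decimal print precision used in residue-analysis reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Tuple

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "AtomicMassTable",
    "DEFAULT_MASS_TABLE",
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
]

#: Monoisotopic atomic masses (Da) of the elements supported by the assay.
#: Carbon is exactly 12 by definition of the unified atomic mass unit.
MONOISOTOPIC_MASSES: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
    "P": 30.97376200,
    "F": 18.99840316,
    "Cl": 34.96885268,
    "Br": 78.91833760,
    "I": 126.90447190,
    "Na": 22.98976928,
    "K": 38.96370649,
}

#: Mass of the proton (Da).  Used for [M+H]+ / [M-H]- adducts; note this is
#: the mass of a charged hydrogen (H minus one electron), which is the
#: physically correct increment for a protonated ion.
PROTON_MASS = 1.00727646

#: Electron mass (Da), needed for cationization adducts such as [M+Na]+.
ELECTRON_MASS = 0.00054858


class FormulaError(ValueError):
    """Raised for malformed formulas or unknown/missing elements."""


@dataclass(frozen=True)
class AtomicMassTable:
    """A monoisotopic atomic-mass table plus the proton mass.

    Parameters
    ----------
    masses:
        Mapping element symbol -> monoisotopic mass in Da.  Must contain at
        least C, H, N, O and S, with C exactly 12.
    proton_mass:
        Mass increment used for (de)protonation adducts.  The default is the
        physical proton mass; instruments/software that reference the neutral
        hydrogen atom instead can pass ``proton_mass=1.00782503``.
    """

    masses: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_MASSES)
    )
    proton_mass: float = PROTON_MASS

    def __post_init__(self) -> None:
        required = {"C", "H", "N", "O", "S"}
        missing = required - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing required elements: {sorted(missing)}")
        if self.masses["C"] != 12.0:
            raise ValueError("monoisotopic mass of C must be exactly 12")
        for sym, m in self.masses.items():
            if not m > 0:
                raise ValueError(f"non-positive mass for element {sym!r}")
        if not self.proton_mass > 0:
            raise ValueError("proton mass must be positive")


DEFAULT_MASS_TABLE = AtomicMassTable()


@dataclass(frozen=True)
class ElementalFormula:
    """An element-multiset, e.g. ``{"C": 14, "H": 18, "N": 4, "O": 3}``.

    The empty formula (mass zero) is permitted; present elements must have
    count >= 1.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for element {sym!r} must be a positive integer, got {n!r}")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str, table: AtomicMassTable = DEFAULT_MASS_TABLE) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C14H18N4O3"``.

    An element symbol with no trailing digits has implicit count 1.  Repeated
    symbols accumulate.  Raises :class:`FormulaError` naming the offending
    position for unknown elements and malformed tokens (leading digits,
    orphan lowercase letters, ...).
    """
    if text is None or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    counts: Dict[str, int] = {}
    i = 0
    while i < len(s):
        m = _TOKEN.match(s, i)
        if m is None or m.end() == i:
            raise FormulaError(f"malformed token at position {i} in formula {s!r}: {s[i:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in table.masses:
            raise FormulaError(f"unknown element {sym!r} at position {i} in formula {s!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero count for element {sym!r} at position {i} in formula {s!r}")
        counts[sym] = counts.get(sym, 0) + n
        i = m.end()
    return ElementalFormula(counts)


def format_formula(formula: ElementalFormula) -> str:
    """Render a formula in Hill order (C, H, then other elements A-Z)."""
    counts = dict(formula.counts)
    parts = []
    order = [s for s in ("C", "H") if s in counts] + sorted(
        s for s in counts if s not in ("C", "H")
    )
    for sym in order:
        n = counts[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(
    formula: ElementalFormula, table: AtomicMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Sum of count-weighted monoisotopic atomic masses, in Da."""
    total = 0.0
    for sym, n in formula.counts.items():
        try:
            total += n * table.masses[sym]
        except KeyError:
            raise FormulaError(f"element {sym!r} missing from atomic-mass table") from None
    return total


# Adduct rules: name -> (mass delta as a function of the table, charge).
_ADDUCT_RULES: Dict[str, Tuple[Callable[[AtomicMassTable], float], int]] = {
    "[M+H]+": (lambda t: t.proton_mass, 1),
    "[M-H]-": (lambda t: -t.proton_mass, 1),
    "[M+Na]+": (lambda t: t.masses["Na"] - ELECTRON_MASS, 1),
}


def adduct_mz(
    formula: ElementalFormula,
    adduct: str = "[M+H]+",
    table: AtomicMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Theoretical m/z of an adduct ion of the given neutral formula.

    Only singly-charged adducts are supported; the table of rules is module
    level and pluggable.  Raises ``ValueError`` for unsupported adduct names.
    """
    try:
        delta, charge = _ADDUCT_RULES[adduct]
    except KeyError:
        known = ", ".join(sorted(_ADDUCT_RULES))
        raise ValueError(f"unsupported adduct {adduct!r}; supported: {known}") from None
    return (monoisotopic_mass(formula, table) + delta(table)) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, 1e6 * (observed - theoretical) / theoretical."""
    if not theoretical > 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical!r}")
    return 1e6 * (observed - theoretical) / theoretical
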