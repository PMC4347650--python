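"""Molecular-formula parsing and monoisotopic/charged mass arithmetic.

This is the numeric core of the package. A molecular formula is a flat
element-count string ("C6H8O7"); its neutral monoisotopic mass is the sum of
the most-abundant-isotope masses of its atoms. Electrospray ionization shifts
that neutral mass: an ion of charge z observed in positive (negative) mode has

    m/z = (M + s * z * m_H + sum(adducts) - sum(deducts)) / z      (z >= 1)

with s = +1 for positive mode, -1 for negative mode, and m_H the monoisotopic
mass of the hydrogen *atom*. Using the atom mass (rather than the bare proton,
i.e. neglecting the electron) is the convention adopted throughout: it
reproduces the customary QTof lock-mass value for leucine-enkephalin,
[M+H]+ = 556.2771, to four decimals. The error relative to the proton
convention is one electron mass per charge (~0.00055 Da), well inside typical
instrument calibration.

Charge 0 is a valid state meaning "the neutral mass as given"; no ionization
event exists at z = 0, so adducts and deducts are disallowed there.

Sodiated species such as [M+Na]+ are expressed under the single proton-charging
formula as adduct "Na" plus deduct "H" (a net Na-H exchange).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

from .errors import ElementError, FormulaParseError, HypothesisError

__all__ = [
    "ElementMassTable",
    "MolecularFormula",
    "DEFAULT_ELEMENT_TABLE",
    "HYDROGEN_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "formula_mass",
    "ion_mz",
    "neutral_mass_from_observed",
]

# Monoisotopic (most abundant isotope) masses in Da, NIST compilation.
# Bundled as a constant so results never depend on a runtime lookup.
_NIST_MONOISOTOPIC: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "P": 30.97376163,
    "S": 31.972071,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Si": 27.9769265325,
    "B": 11.0093054,
    "Se": 79.9165213,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Mn": 54.9380451,
    "Cu": 62.9295975,
    "Co": 58.933195,
    "Ni": 57.9353429,
    "Mo": 97.9054082,
    "W": 183.9509312,
    "As": 74.9215965,
    "Li": 7.01600455,
    "Al": 26.98153863,
}


@dataclass(frozen=True)
class ElementMassTable:
    """Element symbol -> monoisotopic mass (Da), with a provenance tag."""

    entries: Mapping[str, float]
    version_tag: str = "custom"

    def __post_init__(self) -> None:
        for sym, m in self.entries.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for element {sym!r}: {m}")

    def mass(self, symbol: str) -> float:
        try:
            return self.entries[symbol]
        except KeyError:
            raise ElementError(
                f"element {symbol!r} is not in mass table {self.version_tag!r}"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries


DEFAULT_ELEMENT_TABLE = ElementMassTable(
    entries=_NIST_MONOISOTOPIC, version_tag="nist-monoisotopic-2011"
)

#: Monoisotopic mass of the hydrogen atom — the per-charge shift applied in
#: positive/negative ESI mode (electron mass neglected, see module docstring).
HYDROGEN_MASS: float = _NIST_MONOISOTOPIC["H"]


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element -> count map. The empty map is the null formula."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if n < 1:
                raise FormulaParseError(f"count for {sym!r} must be >= 1, got {n}")

    def __or__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical — a stable display convention.
        syms = sorted(
            self.counts, key=lambda s: (s != "C", s != "H", s)
        )
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in syms
        )


# One element token: capital letter, optional lowercase letter, optional count.
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(
    text: str, table: ElementMassTable = DEFAULT_ELEMENT_TABLE
) -> MolecularFormula:
    """Parse a flat element-count string into a :class:`MolecularFormula`.

    The grammar is a sequence of (element symbol, optional count >= 1) tokens;
    no parentheses, hydrates, charges or isotope labels — the flat strings
    found in pathway-database compound exports. Repeated element tokens sum
    ("CHHO" -> C1 H2 O1).

    Raises
    ------
    FormulaParseError
        Empty input, a leading digit, a zero count, or trailing garbage.
    ElementError
        A syntactically valid symbol absent from ``table``.
    """
    stripped = text.strip()
    if not stripped:
        raise FormulaParseError("empty formula string")

    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        m = _TOKEN_RE.match(stripped, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaParseError(
                f"malformed formula {text!r}: unexpected character "
                f"{stripped[pos]!r} at position {pos}"
            )
        sym, digits = m.group(1), m.group(2)
        if sym not in table:
            # A two-letter guess may hide a valid one-letter symbol followed
            # by garbage ("Xq3"): report the token the user wrote.
            raise ElementError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaParseError(f"zero count for {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(
    formula: MolecularFormula, table: ElementMassTable = DEFAULT_ELEMENT_TABLE
) -> float:
    """Neutral monoisotopic mass in Da: sum of count(e) * mass(e)."""
    return sum(n * table.mass(sym) for sym, n in formula.counts.items())


def formula_mass(
    text: str, table: ElementMassTable = DEFAULT_ELEMENT_TABLE
) -> float:
    """Convenience: parse a formula string and return its monoisotopic mass."""
    return monoisotopic_mass(parse_formula(text, table), table)


def _check_hypothesis_args(
    charge: int,
    mode: str,
    adduct_masses: Sequence[float],
    deduct_masses: Sequence[float],
) -> int:
    if charge < 0:
        raise HypothesisError(f"charge must be >= 0, got {charge}")
    if mode not in ("positive", "negative"):
        raise ValueError(f"mode must be 'positive' or 'negative', got {mode!r}")
    if charge == 0 and (adduct_masses or deduct_masses):
        raise HypothesisError("adducts/deducts are not allowed at charge 0")
    return 1 if mode == "positive" else -1


def ion_mz(
    neutral_mass: float,
    charge: int,
    mode: str = "positive",
    adduct_masses: Iterable[float] = (),
    deduct_masses: Iterable[float] = (),
) -> float:
    """m/z of the ion formed from a neutral molecule under one ion hypothesis.

    ``charge == 0`` returns the neutral mass unchanged (the identity case used
    when querying theoretical neutral masses directly).
    """
    adducts = list(adduct_masses)
    deducts = list(deduct_masses)
    s = _check_hypothesis_args(charge, mode, adducts, deducts)
    if charge == 0:
        return neutral_mass
    total = neutral_mass + s * charge * HYDROGEN_MASS + sum(adducts) - sum(deducts)
    if total <= 0:
        raise HypothesisError(
            f"ion mass {total:.4f} Da is non-positive for neutral mass "
            f"{neutral_mass:.4f} under the given adduct/deduct set"
        )
    return total / charge


def neutral_mass_from_observed(
    observed_mz: float,
    charge: int,
    mode: str = "positive",
    adduct_masses: Iterable[float] = (),
    deduct_masses: Iterable[float] = (),
) -> float:
    """Exact algebraic inverse of :func:`ion_mz`.

    Returns the candidate neutral mass M such that ``ion_mz(M, ...)`` equals
    ``observed_mz``; composing the two is the identity to <= 1e-9 Da.

    Raises :class:`HypothesisError` if the candidate mass is non-positive
    (the hypothesis cannot explain the observation).
    """
    adducts = list(adduct_masses)
    deducts = list(deduct_masses)
    s = _check_hypothesis_args(charge, mode, adducts, deducts)
    if charge == 0:
        candidate = observed_mz
    else:
        candidate = (
            observed_mz * charge
            - s * charge * HYDROGEN_MASS
            - sum(adducts)
            + sum(deducts)
        )
    if candidate <= 0:
        raise HypothesisError(
            f"hypothesis implies non-positive neutral mass "
            f"{candidate:.4f} Da for observed m/z {observed_mz:.4f}"
        )
    return candidate
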