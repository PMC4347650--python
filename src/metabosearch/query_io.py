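"""Query input channels and query-type classification.

Three ways queries arrive:

* a single typed value (a mass, a compound name, a formula, or a SMILES
  string);
* a generic tab-delimited text file with the query in column 1 and any extra
  columns (intensities, statistics) carried through untouched;
* a MarkerLynx-style peak-table export whose first column labels each marker
  as ``RT_mz`` (retention time and m/z joined by an underscore) or as a bare
  mass.

Each query string is classified into exactly one of four types with a fixed
priority — mass, formula, SMILES, name — so behaviour is deterministic on
ambiguous strings ("CO" is read as the formula). The classification can be
overridden per run with ``force_type``.

Headers, blank lines and unusable first fields are tolerated: they are
recorded in the batch's ``skipped`` list with a reason rather than aborting
the run (``strict=True`` restores hard failure).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

from .errors import EmptyInputError, MetaboSearchError
from .formula_mass import DEFAULT_ELEMENT_TABLE, ElementMassTable, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "Query",
    "QueryBatch",
    "classify_query",
    "parse_single_query",
    "parse_query_text_file",
    "parse_markerlynx_file",
    "QUERY_TYPES",
]

QUERY_TYPES = ("name", "formula", "smiles", "mass")

# Unsigned decimal with "." separator; no exponents, no leading "."/"+"/"-".
_DECIMAL_RE = re.compile(r"^\d+(\.\d+)?$")
# Same but with a comma separator — rejected explicitly to avoid locale traps.
_COMMA_DECIMAL_RE = re.compile(r"^\d+,\d+$")
# Characters admissible in a SMILES string (organic subset + ring/bond/charge
# punctuation; 'l'/'r' only ever occur inside Cl/Br).
_SMILES_ALPHABET = set("BCNOPSFIHbcnopslr0123456789=#()[]@+-/\\.%*")
_SMILES_TRIGGERS = set("=#()[]@")
_AROMATIC_ATOMS = set("bcnops")

_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _is_positive_decimal(text: str) -> bool:
    return bool(_DECIMAL_RE.match(text)) and float(text) > 0


def _matches_formula_grammar(
    text: str, table: ElementMassTable
) -> Optional[int]:
    """Return the token count if *text* is a known-element formula, else None."""
    pos = 0
    tokens = 0
    while pos < len(text):
        m = _FORMULA_TOKEN_RE.match(text, pos)
        if not m or not m.group(1) or m.group(1) not in table:
            return None
        if m.group(2) == "0":
            return None
        tokens += 1
        pos = m.end()
    return tokens


def _smiles_heuristic(text: str) -> bool:
    if not set(text) <= _SMILES_ALPHABET:
        return False
    return bool(set(text) & _SMILES_TRIGGERS or set(text) & _AROMATIC_ATOMS)


def classify_query(
    text: str, table: ElementMassTable = DEFAULT_ELEMENT_TABLE
) -> str:
    """Classify a query string as 'mass', 'formula', 'smiles' or 'name'.

    Priority order (first match wins):

    1. parses as an unsigned positive decimal -> ``mass``;
    2. matches the element-count grammar with all symbols known, and either
       contains a digit or spans more than one element token -> ``formula``;
    3. consists solely of SMILES-alphabet characters and contains structural
       punctuation (``= # ( ) [ ] @``) or a lowercase aromatic atom ->
       ``smiles``;
    4. anything else -> ``name``.

    Total on non-empty strings; raises :class:`EmptyInputError` otherwise.
    """
    stripped = text.strip()
    if not stripped:
        raise EmptyInputError("empty query string")
    if _is_positive_decimal(stripped):
        return "mass"
    tokens = _matches_formula_grammar(stripped, table)
    if tokens is not None and (any(ch.isdigit() for ch in stripped) or tokens > 1):
        return "formula"
    if _smiles_heuristic(stripped):
        return "smiles"
    return "name"


@dataclass(frozen=True)
class Query:
    """One classified query plus the pass-through payload columns."""

    raw: str
    qtype: str
    mass_value: Optional[float] = None
    payload: Tuple[str, ...] = ()
    source_line: int = 0

    def __post_init__(self) -> None:
        if self.qtype not in QUERY_TYPES:
            raise ValueError(f"unknown query type {self.qtype!r}")
        if (self.qtype == "mass") != (self.mass_value is not None):
            raise ValueError("mass_value must be present iff qtype == 'mass'")


@dataclass
class QueryBatch:
    queries: List[Query] = field(default_factory=list)
    origin: str = "single"
    skipped: List[Tuple[int, str]] = field(default_factory=list)


def _make_query(
    raw: str,
    payload: Tuple[str, ...],
    source_line: int,
    table: ElementMassTable,
    force_type: Optional[str],
    mass_override: Optional[float] = None,
) -> Query:
    qtype = force_type if force_type and force_type != "auto" else classify_query(raw, table)
    mass = None
    if qtype == "mass":
        mass = mass_override if mass_override is not None else float(raw)
    return Query(raw=raw, qtype=qtype, mass_value=mass, payload=payload,
                 source_line=source_line)


def parse_single_query(
    text: str,
    table: ElementMassTable = DEFAULT_ELEMENT_TABLE,
    force_type: Optional[str] = None,
) -> QueryBatch:
    """Wrap one typed query value in a batch."""
    q = _make_query(text.strip(), (), 1, table, force_type)
    return QueryBatch(queries=[q], origin="single")


def _finish_batch(batch: QueryBatch, source: str, strict: bool) -> QueryBatch:
    for lineno, reason in batch.skipped:
        logger.warning("%s line %d skipped: %s", source, lineno, reason)
    if strict and batch.skipped:
        first = batch.skipped[0]
        raise MetaboSearchError(
            f"{source}: {len(batch.skipped)} unusable line(s) in strict mode "
            f"(first: line {first[0]}, {first[1]})"
        )
    if not batch.queries:
        raise EmptyInputError(f"{source}: no usable queries found")
    return batch


def parse_query_text_file(
    path: Union[str, Path],
    table: ElementMassTable = DEFAULT_ELEMENT_TABLE,
    force_type: Optional[str] = None,
    strict: bool = False,
) -> QueryBatch:
    """Parse a generic tab-delimited query list (queries in column 1).

    Every usable line yields one classified :class:`Query`; extra columns are
    preserved verbatim in ``payload``. Blank lines, empty first fields and
    comma-decimal numbers are skipped with logged reasons.
    """
    path = Path(path)
    batch = QueryBatch(origin="text_file")
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            batch.skipped.append((lineno, "blank line"))
            continue
        fields = line.rstrip("\n").split("\t")
        first = fields[0].strip()
        if not first:
            batch.skipped.append((lineno, "empty first field"))
            continue
        if _COMMA_DECIMAL_RE.match(first):
            batch.skipped.append(
                (lineno, f"comma decimal separator in {first!r} (use '.')")
            )
            continue
        batch.queries.append(
            _make_query(first, tuple(fields[1:]), lineno, table, force_type)
        )
    return _finish_batch(batch, str(path), strict)


_MARKER_RE = re.compile(r"^(\d+(?:\.\d+)?)_(\d+(?:\.\d+)?)$")


def parse_markerlynx_file(
    path: Union[str, Path],
    table: ElementMassTable = DEFAULT_ELEMENT_TABLE,
    strict: bool = False,
) -> QueryBatch:
    """Parse a MarkerLynx-style peak table into mass queries.

    The first column is either a marker label ``RT_mz`` (two decimal tokens
    joined by an underscore — the m/z is the second token and the retention
    time is prepended to the payload) or a bare mass. A single header row is
    auto-detected when the first cell is non-numeric and underscore-free.
    Every resulting query has ``qtype == 'mass'``.
    """
    path = Path(path)
    batch = QueryBatch(origin="markerlynx")
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            batch.skipped.append((lineno, "blank line"))
            continue
        fields = line.rstrip("\n").split("\t")
        first = fields[0].strip()
        rest = tuple(fields[1:])
        if not first:
            batch.skipped.append((lineno, "empty first field"))
            continue
        m = _MARKER_RE.match(first)
        if m:
            rt, mz = m.group(1), m.group(2)
            batch.queries.append(
                Query(raw=first, qtype="mass", mass_value=float(mz),
                      payload=(rt,) + rest, source_line=lineno)
            )
        elif _is_positive_decimal(first):
            batch.queries.append(
                Query(raw=first, qtype="mass", mass_value=float(first),
                      payload=rest, source_line=lineno)
            )
        elif lineno == 1 and "_" not in first:
            batch.skipped.append((lineno, f"header row ({first!r})"))
        else:
            batch.skipped.append(
                (lineno, f"first field {first!r} is not an RT_mz label or mass")
            )
    return _finish_batch(batch, str(path), strict)
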