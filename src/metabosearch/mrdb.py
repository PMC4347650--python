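"""Metabolic Reference Databases (MRDBs).

An MRDB is a per-organism flat-file catalog of compounds — name, molecular
formula, average molecular weight, monoisotopic mass, SMILES string, CAS
registry number, and the metabolic pathways each compound participates in —
derived from a genome-scale metabolic reconstruction. Restricting a search to
an organism's MRDB implements *genome restriction*: candidate identifications
are limited to compounds that organism's genome-encoded metabolism can
produce, which shrinks hit lists dramatically relative to universal chemical
databases.

File dialect (normative for this package): UTF-8, tab-delimited, one header
line, columns::

    compound_id  name  formula  average_mw  monoisotopic_mass  smiles  cas_id  pathways

``pathways`` is a pipe-separated list of ``id:name`` pairs; a blank field
means "absent". Masses are written with six decimals. Only *neutral*
monoisotopic masses are stored; charged-state m/z values are computed on the
fly by the search engine, which is algebraically equivalent and keeps the
files small.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import (
    DialectError,
    ElementError,
    EmptyInputError,
    FormulaParseError,
    SchemaError,
)
from .formula_mass import (
    DEFAULT_ELEMENT_TABLE,
    ElementMassTable,
    MolecularFormula,
    monoisotopic_mass,
    parse_formula,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "MRDB",
    "build_mrdb",
    "read_mrdb",
    "write_mrdb",
    "mass_distribution",
    "subset_mrdb",
    "DEFAULT_MASS_BINS",
]

COLUMNS = (
    "compound_id",
    "name",
    "formula",
    "average_mw",
    "monoisotopic_mass",
    "smiles",
    "cas_id",
    "pathways",
)

BUILD_COLUMNS = ("name", "formula", "average_mw", "smiles", "pathways")

#: Bin edges for the molecular-weight distribution summary: 50-99, 100-199,
#: ..., 900-999, >1000. Left-closed, right-open on integer edges.
DEFAULT_MASS_BINS: Tuple[float, ...] = (50.0, 100.0) + tuple(
    float(x) for x in range(200, 1001, 100)
)


@dataclass(frozen=True)
class CompoundRecord:
    """One metabolite in an MRDB."""

    compound_id: str
    name: str
    formula: Optional[MolecularFormula] = None
    average_mw: Optional[float] = None
    monoisotopic_mass: Optional[float] = None
    smiles: Optional[str] = None
    cas_id: Optional[str] = None
    pathways: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        if self.formula is not None and self.monoisotopic_mass is None:
            raise ValueError(
                f"{self.name}: formula present but monoisotopic mass absent"
            )

    def mass_of_kind(self, kind: str) -> Optional[float]:
        if kind == "monoisotopic":
            return self.monoisotopic_mass
        if kind == "average":
            return self.average_mw
        raise ValueError(f"unknown mass kind {kind!r}")


@dataclass
class MRDB:
    """A named collection of compound records for one organism/encyclopedia."""

    db_name: str
    records: List[CompoundRecord] = field(default_factory=list)
    link_template: str = ""
    created: str = ""
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.db_name:
            raise ValueError("db_name must be non-empty")
        seen = set()
        for rec in self.records:
            if rec.compound_id in seen:
                raise ValueError(f"duplicate compound_id {rec.compound_id!r}")
            seen.add(rec.compound_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _serialize_pathways(pathways: Sequence[Tuple[str, str]]) -> str:
    return "|".join(f"{pid}:{pname}" for pid, pname in pathways)


def _parse_pathways(text: str) -> Tuple[Tuple[str, str], ...]:
    if not text:
        return ()
    out = []
    for chunk in text.split("|"):
        pid, _, pname = chunk.partition(":")
        out.append((pid.strip(), pname.strip()))
    return tuple(out)


def build_mrdb(
    compound_table: Union[str, Path],
    db_name: str,
    link_template: str = "",
    table: ElementMassTable = DEFAULT_ELEMENT_TABLE,
    validate_smiles: bool = False,
) -> MRDB:
    """Build an MRDB from a tab-delimited compound/pathway export.

    The export must carry columns ``name``, ``formula``, ``average_mw``,
    ``smiles``, ``pathways`` (pipe-delimited ``id:name`` pairs) and may carry
    ``cas_id`` and ``compound_id``; formula, SMILES and MW may be blank.
    Every row with a parseable formula gains a computed neutral monoisotopic
    mass; rows whose formula fails to parse are retained mass-less and a
    warning is logged, so the record count always equals the input row count.

    With ``validate_smiles=True``, SMILES strings are checked with RDKit when
    it is importable; invalid strings are kept but logged.
    """
    try:
        df = pd.read_csv(compound_table, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"compound table {compound_table} is empty") from None
    missing = [c for c in BUILD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"compound table {compound_table} is missing mandatory "
            f"column(s): {', '.join(missing)}"
        )
    if df.empty:
        raise EmptyInputError(f"compound table {compound_table} has no data rows")

    smiles_checker = _smiles_validator() if validate_smiles else None

    records: List[CompoundRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        name = getattr(row, "name").strip()
        raw_formula = getattr(row, "formula").strip()
        formula = None
        mono = None
        if raw_formula:
            try:
                formula = parse_formula(raw_formula, table)
                mono = monoisotopic_mass(formula, table)
            except (FormulaParseError, ElementError) as exc:
                logger.warning(
                    "%s line %d (%s): unparseable formula %r kept mass-less (%s)",
                    compound_table, i, name, raw_formula, exc,
                )
        raw_mw = getattr(row, "average_mw").strip()
        smiles = getattr(row, "smiles").strip() or None
        if smiles and smiles_checker and not smiles_checker(smiles):
            logger.warning(
                "%s line %d (%s): SMILES %r failed RDKit validation",
                compound_table, i, name, smiles,
            )
        cas = getattr(row, "cas_id", "").strip() or None
        cid = getattr(row, "compound_id", "").strip() or f"CPD-{i - 1:04d}"
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=name,
                formula=formula,
                average_mw=float(raw_mw) if raw_mw else None,
                monoisotopic_mass=mono,
                smiles=smiles,
                cas_id=cas,
                pathways=_parse_pathways(getattr(row, "pathways").strip()),
            )
        )
    return MRDB(
        db_name=db_name,
        records=records,
        link_template=link_template,
        created=datetime.date.today().isoformat(),
        source_tag=str(compound_table),
    )


def _smiles_validator() -> Optional[Callable[[str], bool]]:
    try:
        from rdkit import Chem, RDLogger  # type: ignore

        RDLogger.DisableLog("rdApp.*")
        return lambda s: Chem.MolFromSmiles(s) is not None
    except ImportError:
        logger.warning("RDKit not importable; skipping SMILES validation")
        return None


def write_mrdb(mrdb: MRDB, path: Union[str, Path]) -> None:
    """Write an MRDB in the flat-file dialect (masses at six decimals)."""
    path = Path(path)
    lines = ["\t".join(COLUMNS)]
    lines += [f"# db_name: {mrdb.db_name}"]
    if mrdb.link_template:
        lines += [f"# link_template: {mrdb.link_template}"]
    if mrdb.created:
        lines += [f"# created: {mrdb.created}"]
    if mrdb.source_tag:
        lines += [f"# source_tag: {mrdb.source_tag}"]
    for rec in mrdb.records:
        lines.append(
            "\t".join(
                (
                    rec.compound_id,
                    rec.name,
                    str(rec.formula) if rec.formula is not None else "",
                    f"{rec.average_mw:.6f}" if rec.average_mw is not None else "",
                    f"{rec.monoisotopic_mass:.6f}"
                    if rec.monoisotopic_mass is not None
                    else "",
                    rec.smiles or "",
                    rec.cas_id or "",
                    _serialize_pathways(rec.pathways),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_mrdb(
    path: Union[str, Path], table: ElementMassTable = DEFAULT_ELEMENT_TABLE
) -> MRDB:
    """Read a flat-file MRDB; ``read(write(m))`` reproduces ``m`` field for
    field (masses to the six printed decimals).

    Raises :class:`DialectError` with the offending line number if a data
    line has the wrong column count.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise DialectError(f"{path}: empty file (missing header)")
    header = lines[0].split("\t")
    if tuple(header) != COLUMNS:
        raise DialectError(
            f"{path} line 1: header {header} does not match the MRDB dialect"
        )
    meta = {"db_name": path.stem, "link_template": "", "created": "", "source_tag": ""}
    records: List[CompoundRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() in meta:
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if len(fields) != len(COLUMNS):
            raise DialectError(
                f"{path} line {lineno}: expected {len(COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        cid, name, raw_formula, raw_mw, raw_mono, smiles, cas, raw_pw = fields
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=name,
                formula=parse_formula(raw_formula, table) if raw_formula else None,
                average_mw=float(raw_mw) if raw_mw else None,
                monoisotopic_mass=float(raw_mono) if raw_mono else None,
                smiles=smiles or None,
                cas_id=cas or None,
                pathways=_parse_pathways(raw_pw),
            )
        )
    return MRDB(records=records, **meta)


def mass_distribution(
    mrdb: MRDB,
    bin_edges: Sequence[float] = DEFAULT_MASS_BINS,
    mass_kind: str = "monoisotopic",
) -> "pd.Series":
    """Count compounds per molecular-weight bin (the encyclopedia summary).

    Bins are left-closed right-open on integer edges, labelled "50-99",
    "100-199", ..., with a final open ">=<last edge>" bin. Records below the
    first edge or without a usable mass are excluded and their counts logged;
    the returned counts sum to the number of records with a usable mass at or
    above the first edge.
    """
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = [
        f"{int(lo)}-{int(hi) - 1}" for lo, hi in zip(edges, edges[1:])
    ] + [f">={int(edges[-1])}"]
    counts = dict.fromkeys(labels, 0)
    below = 0
    massless = 0
    for rec in mrdb:
        m = rec.mass_of_kind(mass_kind)
        if m is None:
            massless += 1
            continue
        if m < edges[0]:
            below += 1
            continue
        for lo, hi, label in zip(edges, edges[1:], labels):
            if lo <= m < hi:
                counts[label] += 1
                break
        else:
            counts[labels[-1]] += 1
    if below or massless:
        logger.info(
            "%s: %d record(s) below %.0f Da and %d without a %s mass excluded",
            mrdb.db_name, below, edges[0], massless, mass_kind,
        )
    return pd.Series(counts, name=mrdb.db_name)


def subset_mrdb(
    mrdb: MRDB,
    keep: Union[Iterable[str], Callable[[CompoundRecord], bool]],
    db_name: Optional[str] = None,
) -> MRDB:
    """Genome-restrict an MRDB: keep records by name/compound_id or predicate.

    The result's records are a sub-list of the input's, so any query's hits
    against the subset are a subset of its hits against the original.
    """
    if callable(keep):
        records = [r for r in mrdb.records if keep(r)]
    else:
        wanted = {k.lower() for k in keep}
        records = [
            r
            for r in mrdb.records
            if r.name.lower() in wanted or r.compound_id.lower() in wanted
        ]
    return replace(
        mrdb,
        db_name=db_name or f"{mrdb.db_name} (subset)",
        records=records,
    )
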