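"""The search engine.

For mass queries the engine enumerates *ion hypotheses* — combinations of
proton charge state (0 to ``max_charge``), electrospray mode sign, and
adduct/deduct multisets up to ``max_adduct_count`` species — and for each
hypothesis algebraically neutralizes the observed m/z back to a candidate
neutral mass, which is compared against the database's stored neutral masses
within the user's tolerance (ppm or Da). Working in neutral-mass space rather
than ionizing every database record is equivalent (the two transforms are
exact inverses) and lets a sorted-mass binary search replace a full scan.

The ppm tolerance is referenced to the database compound's *theoretical*
mass, so whether a candidate passes depends only on the record being tested,
not on which hypothesis produced the candidate; at usual tolerances
(<= 100 ppm) the difference from referencing the observed mass is
second-order.

Name queries use case-insensitive substring matching (a query of "glucose"
also returns NDP-Glucoses, alpha-methyl-glucose, ...), formula queries use
element-count equality regardless of token order, and SMILES queries use
exact string matching after whitespace strip — no chemical canonicalization,
so two different well-formed spellings of the same molecule do not match.

The charge-state grid includes z = 0 (querying a theoretical neutral mass
directly) and, when adducts are declared, mixed hypotheses such as
[M+H+Na]2+; both are deliberate and can be suppressed/bounded via
``include_neutral`` and ``max_adduct_count``.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .errors import CapabilityError, EmptyInputError, HypothesisError
from .formula_mass import (
    DEFAULT_ELEMENT_TABLE,
    ElementMassTable,
    formula_mass,
    neutral_mass_from_observed,
    parse_formula,
)
from .mrdb import MRDB, CompoundRecord
from .query_io import Query, QueryBatch

__all__ = [
    "AdductSpec",
    "SearchParams",
    "IonHypothesis",
    "MatchResult",
    "enumerate_hypotheses",
    "within_tolerance",
    "match_mass_query",
    "match_name_query",
    "match_formula_query",
    "match_smiles_query",
    "search",
]


@dataclass(frozen=True)
class AdductSpec:
    """One adduct/deduct species: a label plus its mass shift in Da."""

    label: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"adduct/deduct {self.label!r} mass must be > 0")

    @classmethod
    def parse(
        cls, spec: str, table: ElementMassTable = DEFAULT_ELEMENT_TABLE
    ) -> "AdductSpec":
        """Parse a CLI-style spec: either a formula ("Na", "HCOOH") or a
        numeric mass in Da ("21.9819"), optionally "label=value"."""
        spec = spec.strip()
        label, eq, value = spec.partition("=")
        if not eq:
            label, value = spec, spec
        try:
            return cls(label=label.strip(), mass=float(value))
        except ValueError:
            return cls(label=label.strip(), mass=formula_mass(value.strip(), table))


@dataclass(frozen=True)
class SearchParams:
    """Everything the user specifies about one search run."""

    tolerance_value: float = 5.0
    tolerance_unit: str = "ppm"          # 'ppm' | 'Da'
    mode: str = "positive"               # 'positive' | 'negative'
    max_charge: int = 1                  # 0..5
    adducts: Tuple[AdductSpec, ...] = ()
    deducts: Tuple[AdductSpec, ...] = ()
    max_adduct_count: int = 0
    mass_kind: str = "monoisotopic"      # 'monoisotopic' | 'average'
    include_neutral: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_value <= 0:
            raise ValueError("tolerance_value must be > 0")
        if self.tolerance_unit not in ("ppm", "Da"):
            raise ValueError(f"tolerance_unit must be ppm or Da, got {self.tolerance_unit!r}")
        if not 0 <= self.max_charge <= 5:
            raise ValueError(f"max_charge must be in 0..5, got {self.max_charge}")
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"mode must be positive or negative, got {self.mode!r}")
        if self.mass_kind not in ("monoisotopic", "average"):
            raise ValueError(f"mass_kind must be monoisotopic or average")
        if self.max_adduct_count < 0:
            raise ValueError("max_adduct_count must be >= 0")
        if self.mass_kind == "average" and self.tolerance_unit == "ppm":
            raise ValueError(
                "ppm tolerance with average masses is ill-defined; use Da"
            )

    def tolerance_da(self, theoretical: float) -> float:
        if self.tolerance_unit == "Da":
            return self.tolerance_value
        return self.tolerance_value * theoretical / 1e6


@dataclass(frozen=True)
class IonHypothesis:
    """A charge state plus adduct/deduct multisets (sorted label tuples)."""

    charge: int
    mode: str
    adducts: Tuple[AdductSpec, ...] = ()
    deducts: Tuple[AdductSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.charge == 0 and (self.adducts or self.deducts):
            raise HypothesisError("z=0 hypotheses cannot carry adducts/deducts")

    @property
    def label(self) -> str:
        """Conventional ion notation, e.g. '[M+H]+', '[M+Na-H]+', '[M]'."""
        if self.charge == 0:
            return "[M]"
        sign = "+" if self.mode == "positive" else "-"
        nh = f"{self.charge}H" if self.charge > 1 else "H"
        parts = [f"{sign}{nh}"]
        parts += [f"+{a.label}" for a in self.adducts]
        parts += [f"-{d.label}" for d in self.deducts]
        zlabel = sign if self.charge == 1 else f"{self.charge}{sign}"
        return f"[M{''.join(parts)}]{zlabel}"

    def neutralize(self, observed_mz: float) -> float:
        return neutral_mass_from_observed(
            observed_mz,
            self.charge,
            self.mode,
            [a.mass for a in self.adducts],
            [d.mass for d in self.deducts],
        )


@dataclass(frozen=True)
class MatchResult:
    query: Query
    db_name: str
    compound: CompoundRecord
    hypothesis: Optional[IonHypothesis] = None
    candidate_neutral_mass: Optional[float] = None
    deviation_da: Optional[float] = None
    deviation_ppm: Optional[float] = None

    @property
    def pathways(self) -> Tuple[Tuple[str, str], ...]:
        return self.compound.pathways


def enumerate_hypotheses(params: SearchParams) -> List[IonHypothesis]:
    """The full hypothesis grid for one search.

    z = 0 (if ``include_neutral``) plus, for each z in 1..max_charge, every
    multiset over the declared adduct and deduct species with total count
    <= ``max_adduct_count``. Order is deterministic: z ascending, then by
    total species count, then lexicographically by labels.
    """
    species = [("adduct", a) for a in params.adducts] + [
        ("deduct", d) for d in params.deducts
    ]
    multisets: List[Tuple[Tuple[AdductSpec, ...], Tuple[AdductSpec, ...]]] = []
    seen = set()
    for count in range(params.max_adduct_count + 1):
        for combo in itertools.combinations_with_replacement(species, count):
            adducts = tuple(sorted((s for kind, s in combo if kind == "adduct"),
                                   key=lambda s: s.label))
            deducts = tuple(sorted((s for kind, s in combo if kind == "deduct"),
                                   key=lambda s: s.label))
            key = (adducts, deducts)
            if key not in seen:
                seen.add(key)
                multisets.append(key)

    hypotheses: List[IonHypothesis] = []
    if params.include_neutral:
        hypotheses.append(IonHypothesis(charge=0, mode=params.mode))
    for z in range(1, params.max_charge + 1):
        for adducts, deducts in multisets:
            hypotheses.append(
                IonHypothesis(charge=z, mode=params.mode,
                              adducts=adducts, deducts=deducts)
            )
    return hypotheses


def within_tolerance(
    theoretical: float, candidate: float, params: SearchParams
) -> Tuple[bool, float, float]:
    """Decide a match and return (ok, deviation_da, deviation_ppm).

    The deviation is candidate - theoretical; the ppm deviation is referenced
    to the theoretical (database) mass.
    """
    dev_da = candidate - theoretical
    dev_ppm = 1e6 * dev_da / theoretical
    return abs(dev_da) <= params.tolerance_da(theoretical), dev_da, dev_ppm


def _sort_mass_results(results: List[MatchResult]) -> List[MatchResult]:
    return sorted(
        results,
        key=lambda r: (abs(r.deviation_ppm), r.compound.name, r.db_name),
    )


def match_mass_query(
    query: Query, mrdb: MRDB, params: SearchParams
) -> List[MatchResult]:
    """All (compound, hypothesis) pairs explaining an observed mass.

    For every hypothesis the observed m/z is neutralized and every stored
    mass of the requested kind within tolerance yields one
    :class:`MatchResult`. Results are sorted by absolute ppm deviation, then
    compound name.
    """
    if query.qtype != "mass":
        raise ValueError(f"expected a mass query, got {query.qtype!r}")
    usable = [
        (rec.mass_of_kind(params.mass_kind), rec)
        for rec in mrdb
        if rec.mass_of_kind(params.mass_kind) is not None
    ]
    if not usable:
        raise CapabilityError(
            f"{mrdb.db_name}: no {params.mass_kind} masses available"
        )
    usable.sort(key=lambda pair: pair[0])
    masses = [m for m, _ in usable]

    results: List[MatchResult] = []
    for hyp in enumerate_hypotheses(params):
        try:
            candidate = hyp.neutralize(query.mass_value)
        except HypothesisError:
            continue
        # Over-wide bisect window (exact per-record recheck follows): the ppm
        # band is referenced to the theoretical mass, which is within ~tol of
        # the candidate, so 10% inflation more than covers the difference.
        half = (
            params.tolerance_value
            if params.tolerance_unit == "Da"
            else params.tolerance_value * candidate * 1.1 / 1e6
        )
        lo = bisect_left(masses, candidate - half)
        hi = bisect_right(masses, candidate + half)
        for theoretical, rec in usable[lo:hi]:
            ok, dev_da, dev_ppm = within_tolerance(theoretical, candidate, params)
            if ok:
                results.append(
                    MatchResult(
                        query=query,
                        db_name=mrdb.db_name,
                        compound=rec,
                        hypothesis=hyp,
                        candidate_neutral_mass=candidate,
                        deviation_da=dev_da,
                        deviation_ppm=dev_ppm,
                    )
                )
    return _sort_mass_results(results)


def match_name_query(query: Query, mrdb: MRDB) -> List[MatchResult]:
    """Case-insensitive substring match against compound names."""
    needle = query.raw.strip().lower()
    hits = [rec for rec in mrdb if needle in rec.name.lower()]
    return [
        MatchResult(query=query, db_name=mrdb.db_name, compound=rec)
        for rec in sorted(hits, key=lambda r: r.name)
    ]


def match_formula_query(
    query: Query,
    mrdb: MRDB,
    table: ElementMassTable = DEFAULT_ELEMENT_TABLE,
) -> List[MatchResult]:
    """Element-count equality (token order ignored)."""
    wanted = dict(parse_formula(query.raw.strip(), table).counts)
    hits = [
        rec
        for rec in mrdb
        if rec.formula is not None and dict(rec.formula.counts) == wanted
    ]
    return [
        MatchResult(query=query, db_name=mrdb.db_name, compound=rec)
        for rec in sorted(hits, key=lambda r: r.name)
    ]


def match_smiles_query(
    query: Query, mrdb: MRDB, substring: bool = False
) -> List[MatchResult]:
    """Exact SMILES string match after whitespace strip (no chemical
    canonicalization); optional substring mode mirrors name semantics."""
    needle = query.raw.strip()
    if substring:
        hits = [rec for rec in mrdb if rec.smiles and needle in rec.smiles]
    else:
        hits = [rec for rec in mrdb if rec.smiles and rec.smiles.strip() == needle]
    return [
        MatchResult(query=query, db_name=mrdb.db_name, compound=rec)
        for rec in sorted(hits, key=lambda r: r.name)
    ]


def search(
    batch: QueryBatch,
    mrdbs: Sequence[MRDB],
    params: SearchParams,
    table: ElementMassTable = DEFAULT_ELEMENT_TABLE,
) -> List[MatchResult]:
    """Run every query in the batch against every selected MRDB.

    Queries are dispatched by type; results are concatenated in query order,
    then database order, de-duplicated per query and database by
    (compound_id, hypothesis). Matcher errors propagate annotated with the
    database name.
    """
    if not batch.queries:
        raise EmptyInputError("query batch is empty")
    if not mrdbs:
        raise ValueError("at least one MRDB is required")

    out: List[MatchResult] = []
    for query in batch.queries:
        for mrdb in mrdbs:
            try:
                if query.qtype == "mass":
                    results = match_mass_query(query, mrdb, params)
                elif query.qtype == "name":
                    results = match_name_query(query, mrdb)
                elif query.qtype == "formula":
                    results = match_formula_query(query, mrdb, table)
                else:
                    results = match_smiles_query(query, mrdb)
            except (CapabilityError, HypothesisError) as exc:
                raise type(exc)(f"[{mrdb.db_name}] {exc}") from exc
            seen = set()
            for r in results:
                key = (r.compound.compound_id, r.hypothesis)
                if key not in seen:
                    seen.add(key)
                    out.append(r)
    return out
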