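"""Synthetic fixture MRDBs.

Real reference databases are extracted from Pathway/Genome Databases and run
to thousands of compounds; for testing and demonstration this module builds a
small, fully deterministic catalog that reproduces the *structure* of such a
database: the 20 proteinogenic amino acids, the defined-growth-medium
compounds (pyridoxal, pyridoxamine, thymidine, dihydrouracil, guanosine),
glucose and relatives, the TCA-cycle acids, the leucine-enkephalin lock-mass
peptide, and deliberate isobar pairs (citrate/isocitrate, leucine/isoleucine,
glucose/fructose) that exercise the engine's handling of compounds sharing a
formula and hence a monoisotopic mass.

All formulae are the true molecular formulae, so every monoisotopic mass in
the fixture is chemically correct; average molecular weights are computed
from standard atomic weights, standing in for the values a curated compound
export would carry.
"""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Sequence, Tuple

from .formula_mass import (
    DEFAULT_ELEMENT_TABLE,
    monoisotopic_mass,
    parse_formula,
)
from .mrdb import MRDB, CompoundRecord

__all__ = ["generate_fixture_mrdb", "CORE_CATALOG", "DEFINED_MEDIUM_COMPOUNDS"]

# Standard atomic weights (fixture-only, for the average-MW column).
_ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "Na": 22.990, "K": 39.098, "Cl": 35.45,
}

_PW = {
    "gly": ("GLYCOLYSIS", "glycolysis I"),
    "tca": ("TCA", "TCA cycle I (prokaryotic)"),
    "aa": ("AA-SYN", "amino acid biosynthesis superpathway"),
    "asp": ("ASPARAGINE-BIOSYNTHESIS", "asparagine biosynthesis I"),
    "trp": ("TRPSYN-PWY", "tryptophan biosynthesis"),
    "arg": ("ARGSYN-PWY", "arginine biosynthesis I"),
    "his": ("HISTSYN-PWY", "histidine biosynthesis"),
    "pyr": ("PYRIDOXSYN-PWY", "pyridoxal 5'-phosphate biosynthesis"),
    "nuc": ("PWY-7184", "pyrimidine nucleobase salvage"),
    "pur": ("PWY-6125", "purine nucleotide salvage"),
    "sug": ("SUGAR-DEG", "sugar degradation"),
    "glu": ("GLUTSYN-PWY", "glutamate biosynthesis"),
}

# (name, formula, smiles, cas_id, pathway keys). Formulae are the true
# molecular formulae of the neutral species.
CORE_CATALOG: Tuple[Tuple[str, str, Optional[str], Optional[str], Tuple[str, ...]], ...] = (
    ("Glycine", "C2H5NO2", "NCC(=O)O", "56-40-6", ("aa",)),
    ("L-Alanine", "C3H7NO2", "C[C@@H](N)C(=O)O", "56-41-7", ("aa",)),
    ("L-Serine", "C3H7NO3", "OC[C@@H](N)C(=O)O", "56-45-1", ("aa",)),
    ("L-Proline", "C5H9NO2", "OC(=O)[C@@H]1CCCN1", "147-85-3", ("aa", "glu")),
    ("L-Valine", "C5H11NO2", "CC(C)[C@@H](N)C(=O)O", "72-18-4", ("aa",)),
    ("L-Threonine", "C4H9NO3", "C[C@H](O)[C@@H](N)C(=O)O", "72-19-5", ("aa", "asp")),
    ("L-Cysteine", "C3H7NO2S", "NC(CS)C(=O)O", "52-90-4", ("aa",)),
    ("L-Leucine", "C6H13NO2", "CC(C)C[C@@H](N)C(=O)O", "61-90-5", ("aa",)),
    ("L-Isoleucine", "C6H13NO2", "CC[C@H](C)[C@@H](N)C(=O)O", "73-32-5", ("aa",)),
    ("L-Asparagine", "C4H8N2O3", "NC(=O)C[C@@H](N)C(=O)O", "70-47-3", ("aa", "asp")),
    ("L-Aspartate", "C4H7NO4", "OC(=O)C[C@@H](N)C(=O)O", "56-84-8", ("aa", "asp", "tca")),
    ("L-Glutamine", "C5H10N2O3", "NC(=O)CC[C@@H](N)C(=O)O", "56-85-9", ("aa", "glu")),
    ("L-Lysine", "C6H14N2O2", "NCCCC[C@@H](N)C(=O)O", "56-87-1", ("aa", "asp")),
    ("L-Glutamate", "C5H9NO4", "OC(=O)CC[C@@H](N)C(=O)O", "56-86-0", ("aa", "glu", "tca")),
    ("L-Methionine", "C5H11NO2S", "CSCC[C@@H](N)C(=O)O", "63-68-3", ("aa", "asp")),
    ("L-Histidine", "C6H9N3O2", "N[C@@H](Cc1cnc[nH]1)C(=O)O", "71-00-1", ("aa", "his")),
    ("L-Phenylalanine", "C9H11NO2", "N[C@@H](Cc1ccccc1)C(=O)O", "63-91-2", ("aa",)),
    ("L-Arginine", "C6H14N4O2", "NC(=N)NCCC[C@@H](N)C(=O)O", "74-79-3", ("aa", "arg", "glu")),
    ("L-Tyrosine", "C9H11NO3", "N[C@@H](Cc1ccc(O)cc1)C(=O)O", "60-18-4", ("aa",)),
    ("L-Tryptophan", "C11H12N2O2", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O", "73-22-3", ("aa", "trp")),
    ("D-glucose", "C6H12O6", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O", "50-99-7", ("gly", "sug")),
    ("citrate", "C6H8O7", "OC(=O)CC(O)(CC(=O)O)C(=O)O", "77-92-9", ("tca",)),
    ("isocitrate", "C6H8O7", "OC([C@@H](CC(=O)O)C(=O)O)C(=O)O", "320-77-4", ("tca",)),
    ("Pyridoxamine", "C8H12N2O2", "Cc1ncc(CO)c(CN)c1O", "85-87-0", ("pyr",)),
    ("Pyridoxal", "C8H9NO3", "Cc1ncc(CO)c(C=O)c1O", "66-72-8", ("pyr",)),
    ("Thymidine", "C10H14N2O5", "Cc1cn([C@H]2C[C@H](O)[C@@H](CO)O2)c(=O)[nH]c1=O", "50-89-5", ("nuc",)),
    ("Dihydrouracil", "C4H6N2O2", "O=C1CCNC(=O)N1", "504-07-4", ("nuc",)),
    ("Guanosine", "C10H13N5O5", "Nc1nc2n(cnc2c(=O)[nH]1)[C@@H]1O[C@H](CO)[C@@H](O)[C@H]1O", "118-00-3", ("pur",)),
    ("D-fructose", "C6H12O6", "OCC1(O)OC[C@@H](O)[C@@H](O)[C@@H]1O", "57-48-7", ("gly", "sug")),
    ("alpha-methyl-glucose", "C7H14O6", "CO[C@H]1O[C@H](CO)[C@@H](O)[C@H](O)[C@H]1O", "97-30-3", ("sug",)),
    ("NDP-Glucoses", "", None, None, ()),
    ("sucrose", "C12H22O11", None, "57-50-1", ("sug",)),
    ("D-ribose", "C5H10O5", None, "50-69-1", ("sug",)),
    ("pyruvate", "C3H4O3", "CC(=O)C(=O)O", "127-17-3", ("gly", "tca")),
    ("succinate", "C4H6O4", "OC(=O)CCC(=O)O", "110-15-6", ("tca",)),
    ("fumarate", "C4H4O4", "OC(=O)/C=C/C(=O)O", "110-17-8", ("tca",)),
    ("(S)-malate", "C4H6O5", "O[C@@H](CC(=O)O)C(=O)O", "97-67-6", ("tca",)),
    ("oxaloacetate", "C4H4O5", "OC(=O)CC(=O)C(=O)O", "328-42-7", ("tca",)),
    ("2-oxoglutarate", "C5H6O5", "OC(=O)CCC(=O)C(=O)O", "328-50-7", ("tca", "glu")),
    ("cis-aconitate", "C6H6O6", "OC(=O)C=C(CC(=O)O)C(=O)O", "585-84-2", ("tca",)),
    ("leucine-enkephalin", "C28H37N5O7", None, "58822-25-6", ()),
)

#: The defined-growth-medium compounds asserted detectable by mass search.
DEFINED_MEDIUM_COMPOUNDS: Tuple[str, ...] = (
    "Tyrosine", "Pyridoxamine", "Lysine", "Thymidine", "Pyridoxal",
    "Glycine", "Dihydrouracil", "Arginine", "Threonine", "Alanine",
    "Serine", "Asparagine", "Histidine", "Tryptophan", "Aspartate",
    "Glutamate", "Guanosine",
)

_PATHWAY_POOL = tuple(_PW.values())


def _average_mw(formula_text: str) -> float:
    f = parse_formula(formula_text)
    return sum(n * _ATOMIC_WEIGHTS[sym] for sym, n in f.counts.items())


def generate_fixture_mrdb(
    seed: int = 0,
    n_compounds: Optional[int] = None,
    isobar_groups: Optional[Sequence[Tuple[Sequence[str], str]]] = None,
    db_name: str = "fixture-organism",
) -> MRDB:
    """Build a deterministic fixture MRDB.

    Parameters
    ----------
    seed:
        Seeds the pseudo-random extras; identical seeds give byte-identical
        databases when written out.
    n_compounds:
        Total record count. Defaults to the full core catalog
        (:data:`CORE_CATALOG`); larger values append synthetic metabolites
        with random C/H/N/O formulae, smaller values truncate the catalog
        (the amino acids and medium compounds come first and survive).
    isobar_groups:
        Extra ``(names, formula)`` groups: every named compound is given the
        shared formula (appended if not already in the catalog), guaranteeing
        equal monoisotopic masses within each group.
    """
    rng = random.Random(seed)
    catalog: List[Tuple[str, str, Optional[str], Optional[str], Tuple[str, ...]]]
    catalog = list(CORE_CATALOG)

    if isobar_groups:
        by_name = {entry[0]: i for i, entry in enumerate(catalog)}
        for names, formula in isobar_groups:
            for name in names:
                if name in by_name:
                    i = by_name[name]
                    old = catalog[i]
                    catalog[i] = (old[0], formula, old[2], old[3], old[4])
                else:
                    catalog.append((name, formula, None, None, ()))
                    by_name[name] = len(catalog) - 1

    total = len(catalog) if n_compounds is None else n_compounds
    if total < 1:
        raise ValueError("n_compounds must be >= 1")
    catalog = catalog[:total]
    for i in range(len(catalog), total):
        formula = _random_formula(rng)
        pw_keys = tuple(rng.sample(sorted(_PW), rng.randint(0, 2)))
        catalog.append((f"synthetic metabolite {i + 1:03d}", formula, None, None, pw_keys))

    records: List[CompoundRecord] = []
    for i, (name, formula_text, smiles, cas, pw_keys) in enumerate(catalog, start=1):
        if formula_text:
            formula = parse_formula(formula_text)
            mono = monoisotopic_mass(formula, DEFAULT_ELEMENT_TABLE)
            avg = _average_mw(formula_text)
        else:
            formula, mono, avg = None, None, None
        records.append(
            CompoundRecord(
                compound_id=f"CPD-{i:04d}",
                name=name,
                formula=formula,
                average_mw=avg,
                monoisotopic_mass=mono,
                smiles=smiles,
                cas_id=cas,
                pathways=tuple(_PW[k] for k in pw_keys),
            )
        )
    return MRDB(
        db_name=db_name,
        records=records,
        link_template="https://biocyc.example.org/compound?orgid=FIX&id={id}",
        created="",
        source_tag=f"fixture(seed={seed})",
    )


def _random_formula(rng: random.Random) -> str:
    """A plausible small-molecule C/H/N/O formula."""
    c = rng.randint(5, 30)
    h = rng.randint(c, 2 * c + 2)
    n = rng.randint(0, 5)
    o = rng.randint(1, 10)
    parts = [f"C{c}", f"H{h}"]
    if n:
        parts.append(f"N{n}")
    parts.append(f"O{o}")
    return "".join(parts)
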