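# Methods

## Mass model

Neutral monoisotopic masses are computed by summing per-element monoisotopic
masses over a parsed molecular formula. The element table is a constant
bundled in the source (`formula_mass._NIST_MONOISOTOPIC`, tag
`nist-monoisotopic-2011`) rather than a runtime lookup, so results are
reproducible independent of installed library versions; the test suite
cross-checks every entry against pyteomics' NIST compilation to 1e-6 Da.

The formula grammar is a flat sequence of (element symbol, optional count
≥ 1) tokens. Parentheses, hydrates ("·H2O"), isotope labels and charges are
rejected: the formulae this package consumes come from pathway-database
compound exports, which use flat element-count strings. Repeated tokens sum,
so token order never matters.

Ionization follows

    m/z = (M + s·z·m_H + Σ adducts − Σ deducts) / z,   z ≥ 1

with s = ±1 by electrospray mode and m_H the **hydrogen-atom** mass
(1.0078250 Da). Neglecting the electron is a deliberate convention: it
reproduces the customary leucine-enkephalin lock-mass value 556.2771 exactly,
whereas the bare-proton convention gives 556.2766. The corresponding
negative-mode [M−H]⁻ value computes to 554.2615; the commonly quoted
two-decimal figure 554.25 is not consistent with either electron convention
and is treated as a rounding approximation, not a reference. Charge 0 is a
valid state meaning "match the neutral mass as given"; adducts and deducts
are disallowed there because no ionization event exists to attach them to.
Cationization such as [M+Na]⁺ is expressed as adduct Na plus deduct H under
the single proton-charging formula; the hypothesis grid therefore also
contains mixed species such as [M+H+Na]²⁺, which some instruments produce
and which can be pruned simply by lowering `max_adduct_count`.

## Search engine

For each mass query the engine enumerates the hypothesis grid (z ascending,
then adduct/deduct multisets in deterministic order), algebraically
neutralizes the observed m/z per hypothesis, and compares the candidate
neutral mass against the database's stored neutral masses. This direction —
neutralize once per hypothesis, then binary-search a sorted mass array —
is algebraically identical to ionizing every database record (the two
transforms are exact inverses, verified to 1e-9 Da over the full grid) but
costs O(hypotheses · log records) instead of O(hypotheses · records). The
bisect window is deliberately inflated 10% beyond the ppm band and every
candidate passes an exact per-record tolerance recheck, so the speedup can
never change the result; a brute-force triple-loop oracle confirms exact
hit-set equality over 1,000 randomized parameterizations.

ppm tolerances are referenced to the **theoretical** (database) mass, not
the observed one. This makes acceptance depend only on the record under
test, keeping matching symmetric across hypotheses; the difference from an
observed-mass reference is second-order (≤ tol²·M/10¹²) and irrelevant at
practical tolerances ≤ 100 ppm. Searching with average molecular weights
(`mass_kind="average"`) compares against the stored average-MW column and
accepts Da tolerances only — ppm relative to an isotope-abundance-weighted
average is ill-defined and is rejected at parameter construction.

Matching results are ordered by |ppm deviation|, then compound name, then
database name — a deterministic order chosen for diffable outputs. Per
query and database, (compound, hypothesis) duplicates are removed.

Name matching is case-insensitive substring containment (so "glucose" also
returns NDP-Glucoses and alpha-methyl-glucose — partial matches are a
feature, giving control over query specificity). Formula matching is
element-multiset equality. SMILES matching is exact string equality after
whitespace strip, with an optional substring mode; there is **no** chemical
canonicalization, so two different valid spellings of the same molecule do
not match — a documented limitation, since the source databases store one
canonical string per compound.

## Query classification

Every query string is routed to exactly one type with a fixed priority:
unsigned positive decimal → mass; element-count grammar over known elements
(with a digit, or more than one element token) → formula; SMILES-alphabet
characters with structural punctuation or an aromatic lowercase atom →
SMILES; otherwise name. Ambiguity ("CO" is both carbon monoxide's formula
and a letter pair) resolves to the earlier class; `force_type` overrides
classification per run. Headers, blank lines, empty first fields and
comma-decimal numbers are skipped with logged reasons instead of aborting
(strict mode restores hard failure); decimal masses must use "." to avoid
locale ambiguity. The MarkerLynx dialect accepted here is an
underscore-joined "RT_mz" label (mass = second token, retention time
prepended to the payload) or a bare mass column, with a single header row
auto-detected when the first cell is non-numeric and underscore-free.

## MRDB files

UTF-8, tab-delimited, one header line, columns `compound_id, name, formula,
average_mw, monoisotopic_mass, smiles, cas_id, pathways`; pathways are
pipe-separated `id:name` pairs; blank means absent; masses print at six
decimals, which bounds round-trip error at 5e-7 Da. Only neutral
monoisotopic masses are stored; charged-state masses are derived on demand,
which is equivalent by the round-trip identity and keeps files small.
Average MW is carried verbatim from the source export, never recomputed.
Build inputs with unparseable formulae are **kept** (mass-less, logged) so
row accounting is preserved; such records still match name/formula/SMILES
queries where applicable. The molecular-weight summary uses left-closed
right-open bins on integer edges (50–99, 100–199, …, ≥1000), the layout
conventional for encyclopedia size comparisons.

## Synthetic fixture

`generate_fixture_mrdb` emulates a small organism database with chemically
true content: the 20 proteinogenic amino acids, the defined-growth-medium
compounds (pyridoxal, pyridoxamine, thymidine, dihydrouracil, guanosine),
glucose and relatives, TCA-cycle acids, the leucine-enkephalin lock-mass
peptide, and built-in isobar pairs (citrate/isocitrate, leucine/isoleucine,
glucose/fructose) — 41 records, all formulae and hence all monoisotopic
masses exact. Pathway assignments (1–3 per core compound) are fixed and
plausible but not curated biology. Extra records beyond the core are random
C/H/N/O formulae from a seeded generator; identical seeds give byte-identical
files. What the fixture does **not** emulate: real database scale (thousands
of compounds, so real hit lists are longer), noisy or centroiding-biased
masses, missing/dirty pathway annotations, and retention-time structure.
Passing tests therefore demonstrate correctness of the search semantics, not
expected hit counts on production databases, which shift with every database
release.

## Numerical and design choices

* Tolerances: round-trip identities asserted to 1e-9 Da; stored-mass
  consistency to 1e-4 Da (six-decimal file precision with margin);
  reference-value checks at ±0.001 Da, the precision those values are
  conventionally quoted at.
* TSV numeric formatting defaults to 4 dp (masses, Da deviations) and 2 dp
  (ppm); configurable via `Precision` / `--precision`.
* Zero-hit queries appear as explicit "no match" rows so input and output
  row counts always reconcile.
* Hyperlinks in the HTML report are template-driven per database
  (`link_template` with an `{id}` placeholder) rather than hard-coded URLs;
  with no template, names render as plain text with a logged warning.
* The CLI accepts a YAML config mirroring every search flag; explicit flags
  win. Exit codes: 0 success, 1 usage error, 2 data error.
* Test problem sizes: the oracle-equivalence check runs 1,000 randomized
  parameter draws against the 41-compound fixture, and property tests use
  100–500 derandomized examples — sizes chosen so the whole suite exercises
  every code path while completing in seconds.

## Known limitations

No isotope-envelope or MS/MS fragment scoring, no retention-time matching,
no intensity statistics (peak lists' extra columns are echoed, never
analyzed), no average-mass recomputation from formulae, no live
pathway-database connection (MRDBs are built from tab-delimited exports),
and no chemical equivalence for SMILES queries.
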