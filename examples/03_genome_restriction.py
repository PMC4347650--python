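"""Genome restriction: nested organism databases narrow the hit list.

Queries one mass with a deliberately wide tolerance against the full
encyclopedia-style fixture and two nested organism subsets; the hit count
shrinks as the search space is restricted to what each genome can produce.
"""

from metabosearch import (
    Query,
    QueryBatch,
    SearchParams,
    generate_fixture_mrdb,
    search,
    subset_mrdb,
)

full = generate_fixture_mrdb(seed=1, n_compounds=80, db_name="encyclopedia")
names = [r.name for r in full]
organism = subset_mrdb(full, names[:28], db_name="organism")
mutant = subset_mrdb(full, names[:12], db_name="reduced-strain")

batch = QueryBatch(
    queries=[Query(raw="146.1", qtype="mass", mass_value=146.1)]
)
params = SearchParams(tolerance_value=0.15, tolerance_unit="Da", max_charge=1)

for db in (full, organism, mutant):
    hits = search(batch, [db], params)
    compounds = sorted({r.compound.name for r in hits})
    print(f"{db.db_name:<15} ({len(db):>2} compounds): "
          f"{len(compounds)} candidate(s): {', '.join(compounds)}")
# Each restriction yields a subset of the wider database's candidates —
# the remaining identifications are the metabolically plausible ones.
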