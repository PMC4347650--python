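"""Mixed query types: names are substring-matched, formulae are canonical.

The classifier routes each query string by type; a name query for "glucose"
also returns every compound containing the substring, and a formula query
matches regardless of element-token order.
"""

from metabosearch import (
    SearchParams,
    classify_query,
    generate_fixture_mrdb,
    parse_single_query,
    search,
)

db = generate_fixture_mrdb(seed=1)

for text in ("glucose", "O7H8C6", "192.0270", "OC(=O)CC(O)(CC(=O)O)C(=O)O"):
    qtype = classify_query(text)
    batch = parse_single_query(text)
    results = search(batch, [db], SearchParams(
        tolerance_value=0.001, tolerance_unit="Da", max_charge=0))
    hits = ", ".join(r.compound.name for r in results) or "(none)"
    print(f"{text!r} classified as {qtype:>7}: {hits}")
# "glucose" pulls in partial name matches; "O7H8C6" equals C6H8O7 as an
# element multiset; the mass and SMILES queries hit the same isobar pair
# and the exact stored citrate structure respectively.
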