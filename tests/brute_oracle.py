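"""Independent brute-force matcher used as the oracle for the search engine.

Deliberately naive and self-contained: explicit triple loop over compounds x
charge states x adduct/deduct multisets, with the neutralization algebra and
the tolerance check written out inline (no imports from the engine's code
paths beyond the data containers). Returns hits as hashable keys so the
engine's result set can be compared for exact equality.
"""

import itertools

HYDROGEN = 1.00782503207


def brute_force_mass_hits(observed_mz, mrdb, params):
    """Set of (compound_id, z, adduct labels, deduct labels) explaining the
    observed m/z within tolerance."""
    sign = 1 if params.mode == "positive" else -1
    species = [("a", a.label, a.mass) for a in params.adducts] + [
        ("d", d.label, d.mass) for d in params.deducts
    ]

    hypotheses = []
    if params.include_neutral:
        hypotheses.append((0, (), ()))
    for z in range(1, params.max_charge + 1):
        seen = set()
        for count in range(params.max_adduct_count + 1):
            for combo in itertools.combinations_with_replacement(species, count):
                add = tuple(sorted(s[1] for s in combo if s[0] == "a"))
                ded = tuple(sorted(s[1] for s in combo if s[0] == "d"))
                if (add, ded) in seen:
                    continue
                seen.add((add, ded))
                hypotheses.append((z, add, ded))

    mass_of = {s[1]: s[2] for s in species}
    hits = set()
    for z, add, ded in hypotheses:
        if z == 0:
            candidate = observed_mz
        else:
            candidate = (
                observed_mz * z
                - sign * z * HYDROGEN
                - sum(mass_of[a] for a in add)
                + sum(mass_of[d] for d in ded)
            )
        if candidate <= 0:
            continue
        for rec in mrdb:
            theoretical = (
                rec.monoisotopic_mass
                if params.mass_kind == "monoisotopic"
                else rec.average_mw
            )
            if theoretical is None:
                continue
            limit = (
                params.tolerance_value
                if params.tolerance_unit == "Da"
                else params.tolerance_value * theoretical / 1e6
            )
            if abs(candidate - theoretical) <= limit:
                hits.add((rec.compound_id, z, add, ded))
    return hits


def engine_hit_keys(results):
    """Project engine MatchResults onto the oracle's key space."""
    keys = set()
    for r in results:
        h = r.hypothesis
        keys.add(
            (
                r.compound.compound_id,
                h.charge,
                tuple(sorted(a.label for a in h.adducts)),
                tuple(sorted(d.label for d in h.deducts)),
            )
        )
    return keys
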