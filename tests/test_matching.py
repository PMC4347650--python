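"""The search engine: hypothesis enumeration, tolerance logic, matchers."""

import random

import pytest

from metabosearch import (
    AdductSpec,
    CapabilityError,
    EmptyInputError,
    IonHypothesis,
    MRDB,
    Query,
    QueryBatch,
    SearchParams,
    enumerate_hypotheses,
    formula_mass,
    generate_fixture_mrdb,
    match_formula_query,
    match_mass_query,
    match_name_query,
    match_smiles_query,
    search,
    subset_mrdb,
    within_tolerance,
)
from brute_oracle import brute_force_mass_hits, engine_hit_keys

NA = AdductSpec.parse("Na")
K = AdductSpec.parse("K")
H = AdductSpec.parse("H")


def mass_query(value, payload=()):
    return Query(raw=f"{value}", qtype="mass", mass_value=value, payload=tuple(payload))


def mass_batch(values):
    return QueryBatch(queries=[mass_query(v) for v in values], origin="text_file")


class TestEnumerateHypotheses:
    def test_charge_only_grid(self):
        hyps = enumerate_hypotheses(SearchParams(max_charge=1))
        assert [h.charge for h in hyps] == [0, 1]

    def test_adduct_multisets(self):
        params = SearchParams(max_charge=1, adducts=(NA,), max_adduct_count=2)
        hyps = enumerate_hypotheses(params)
        # z=0 plus z=1 with {}, {Na}, {Na,Na}
        assert len(hyps) == 4
        z1 = [tuple(a.label for a in h.adducts) for h in hyps if h.charge == 1]
        assert z1 == [(), ("Na",), ("Na", "Na")]

    def test_zero_max_adducts_degenerates(self):
        with_specs = enumerate_hypotheses(
            SearchParams(max_charge=2, adducts=(NA, K), max_adduct_count=0)
        )
        without = enumerate_hypotheses(SearchParams(max_charge=2))
        assert [h.label for h in with_specs] == [h.label for h in without]

    def test_no_duplicates_and_deterministic(self):
        params = SearchParams(max_charge=3, adducts=(NA, K), deducts=(H,),
                              max_adduct_count=2)
        hyps = enumerate_hypotheses(params)
        keys = [(h.charge, h.adducts, h.deducts) for h in hyps]
        assert len(keys) == len(set(keys))
        assert keys == [
            (h.charge, h.adducts, h.deducts) for h in enumerate_hypotheses(params)
        ]

    def test_neutral_suppressible(self):
        hyps = enumerate_hypotheses(SearchParams(max_charge=2, include_neutral=False))
        assert [h.charge for h in hyps] == [1, 2]

    def test_ion_labels(self):
        params = SearchParams(max_charge=2, adducts=(NA,), deducts=(H,),
                              max_adduct_count=2)
        labels = {h.label for h in enumerate_hypotheses(params)}
        assert "[M]" in labels
        assert "[M+H]+" in labels
        assert "[M+2H]2+" in labels
        assert "[M+H+Na-H]+" in labels  # net sodiation, [M+Na]+


class TestWithinTolerance:
    def test_da_window(self):
        ok, dev_da, _ = within_tolerance(
            192.0270, 192.0275, SearchParams(tolerance_value=0.001, tolerance_unit="Da")
        )
        assert ok and dev_da == pytest.approx(0.0005)

    def test_ppm_window_uses_theoretical_reference(self):
        params = SearchParams(tolerance_value=5, tolerance_unit="ppm")
        ok, _, _ = within_tolerance(192.0270, 192.0290, params)
        assert not ok  # limit is 5e-6 * 192.027 = 0.00096 Da
        ok, _, _ = within_tolerance(192.0270, 192.0279, params)
        assert ok

    def test_identity_match(self):
        ok, dev_da, dev_ppm = within_tolerance(100.0, 100.0, SearchParams())
        assert ok and dev_da == 0 and dev_ppm == 0


class TestMatchMassQuery:
    def test_isobaric_pair_found_by_neutral_mass(self, fixture_db):
        params = SearchParams(tolerance_value=0.001, tolerance_unit="Da",
                              max_charge=0)
        hits = match_mass_query(mass_query(192.027), fixture_db, params)
        assert sorted(r.compound.name for r in hits) == ["citrate", "isocitrate"]
        assert all(r.hypothesis.charge == 0 for r in hits)

    def test_lock_mass_found_via_protonated_hypothesis(self, fixture_db):
        params = SearchParams(tolerance_value=5, tolerance_unit="ppm",
                              mode="positive", max_charge=1)
        hits = match_mass_query(mass_query(556.2771), fixture_db, params)
        assert [r.compound.name for r in hits] == ["leucine-enkephalin"]
        assert hits[0].hypothesis.label == "[M+H]+"
        assert abs(hits[0].deviation_ppm) < 1

    def test_far_query_is_empty(self, fixture_db):
        params = SearchParams(tolerance_value=0.001, tolerance_unit="Da")
        assert match_mass_query(mass_query(999.9), fixture_db, params) == []

    def test_results_sorted_by_ppm_deviation(self, fixture_db):
        params = SearchParams(tolerance_value=0.05, tolerance_unit="Da",
                              max_charge=1)
        hits = match_mass_query(mass_query(148.06), fixture_db, params)
        devs = [abs(r.deviation_ppm) for r in hits]
        assert devs == sorted(devs)
        for r in hits:  # every emitted hit passes its own recheck
            ok, _, _ = within_tolerance(
                r.compound.monoisotopic_mass, r.candidate_neutral_mass, params
            )
            assert ok

    def test_average_mass_search_uses_average_column(self, fixture_db):
        avg = next(r.average_mw for r in fixture_db if r.name == "D-glucose")
        params = SearchParams(tolerance_value=0.01, tolerance_unit="Da",
                              max_charge=0, mass_kind="average")
        hits = match_mass_query(mass_query(avg), fixture_db, params)
        assert "D-glucose" in {r.compound.name for r in hits}

    def test_ppm_with_average_mass_rejected(self):
        with pytest.raises(ValueError, match="ill-defined"):
            SearchParams(tolerance_unit="ppm", mass_kind="average")

    def test_db_without_masses_is_capability_error(self):
        from metabosearch import CompoundRecord

        db = MRDB(db_name="nameless",
                  records=[CompoundRecord(compound_id="X", name="n")])
        with pytest.raises(CapabilityError):
            match_mass_query(mass_query(100.0), db, SearchParams())


class TestStringMatchers:
    def test_glucose_substring_semantics(self, fixture_db):
        q = Query(raw="glucose", qtype="name")
        hits = match_name_query(q, fixture_db)
        assert [r.compound.name for r in hits] == [
            "D-glucose", "NDP-Glucoses", "alpha-methyl-glucose",
        ]

    def test_name_match_is_case_insensitive(self, fixture_db):
        upper = match_name_query(Query(raw="GLUCOSE", qtype="name"), fixture_db)
        lower = match_name_query(Query(raw="glucose", qtype="name"), fixture_db)
        assert [r.compound.name for r in upper] == [r.compound.name for r in lower]

    def test_unknown_name_empty(self, fixture_db):
        assert match_name_query(Query(raw="zzz-not-a-compound", qtype="name"),
                                fixture_db) == []

    @pytest.mark.parametrize("text", ["C6H8O7", "O7H8C6", "H8C6O7"])
    def test_formula_match_ignores_token_order(self, fixture_db, text):
        hits = match_formula_query(Query(raw=text, qtype="formula"), fixture_db)
        assert sorted(r.compound.name for r in hits) == ["citrate", "isocitrate"]

    def test_formula_no_match(self, fixture_db):
        assert match_formula_query(Query(raw="C999", qtype="formula"),
                                   fixture_db) == []

    def test_smiles_exact_string_match(self, fixture_db, records_by_name):
        smiles = records_by_name["citrate"].smiles
        hits = match_smiles_query(Query(raw=smiles, qtype="smiles"), fixture_db)
        assert [r.compound.name for r in hits] == ["citrate"]
        hits = match_smiles_query(Query(raw=smiles + "  ", qtype="smiles"),
                                  fixture_db)
        assert [r.compound.name for r in hits] == ["citrate"]

    def test_equivalent_spelling_does_not_match(self, fixture_db):
        # chemically citrate, but written differently: string match misses it
        q = Query(raw="C(C(=O)O)C(CC(=O)O)(C(=O)O)O", qtype="smiles")
        assert match_smiles_query(q, fixture_db) == []


class TestSearch:
    def test_genome_restriction_nests_hits(self, fixture_db):
        sub = subset_mrdb(fixture_db, [r.name for r in fixture_db][:10], db_name="sub")
        params = SearchParams(tolerance_value=0.005, tolerance_unit="Da",
                              max_charge=2)
        batch = mass_batch([r.monoisotopic_mass for r in fixture_db
                            if r.monoisotopic_mass][:12])
        full_hits = {
            (r.query.raw, r.compound.compound_id)
            for r in search(batch, [fixture_db], params)
        }
        sub_hits = {
            (r.query.raw, r.compound.compound_id)
            for r in search(batch, [sub], params)
        }
        assert sub_hits <= full_hits

    def test_empty_batch_rejected(self, fixture_db):
        with pytest.raises(EmptyInputError):
            search(QueryBatch(queries=[]), [fixture_db], SearchParams())

    def test_results_labelled_per_database(self, fixture_db):
        sub = subset_mrdb(fixture_db, ["citrate"], db_name="tiny")
        batch = mass_batch([192.027])
        params = SearchParams(tolerance_value=0.001, tolerance_unit="Da",
                              max_charge=0)
        results = search(batch, [fixture_db, sub], params)
        assert {r.db_name for r in results} == {fixture_db.db_name, "tiny"}

    def test_tolerance_monotonicity(self, fixture_db):
        batch = mass_batch([192.028, 147.05, 556.28])
        keys = []
        for tol in (0.0005, 0.005, 0.05):
            params = SearchParams(tolerance_value=tol, tolerance_unit="Da",
                                  max_charge=1)
            keys.append(engine_hit_keys(
                r for r in search(batch, [fixture_db], params)
                if r.hypothesis is not None
            ))
        assert keys[0] <= keys[1] <= keys[2]

    def test_hypothesis_space_monotonicity(self, fixture_db):
        batch = mass_batch([215.02, 230.0])
        base = dict(tolerance_value=0.01, tolerance_unit="Da",
                    adducts=(NA,), deducts=(H,))
        small = SearchParams(max_charge=1, max_adduct_count=1, **base)
        large = SearchParams(max_charge=3, max_adduct_count=2, **base)
        hits_small = engine_hit_keys(search(batch, [fixture_db], small))
        hits_large = engine_hit_keys(search(batch, [fixture_db], large))
        assert hits_small <= hits_large


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_random_draws(self, fixture_db):
        """Exhaustive loop over compounds x charges x adduct multisets with a
        direct tolerance check returns exactly the engine's hit set."""
        rng = random.Random(20240915)
        species = [NA, K, AdductSpec.parse("HCOOH"), H]
        masses = [r.monoisotopic_mass for r in fixture_db if r.monoisotopic_mass]
        for _ in range(200):
            unit = rng.choice(["Da", "Da", "ppm"])
            params = SearchParams(
                tolerance_value=rng.choice([0.0005, 0.002, 0.01])
                if unit == "Da" else rng.choice([5, 20, 100]),
                tolerance_unit=unit,
                mode=rng.choice(["positive", "negative"]),
                max_charge=rng.randint(0, 5),
                adducts=tuple(rng.sample(species[:3], rng.randint(0, 2))),
                deducts=(H,) if rng.random() < 0.5 else (),
                max_adduct_count=rng.randint(0, 2),
                include_neutral=rng.random() < 0.8,
            )
            base = rng.choice(masses)
            observed = base + rng.uniform(-0.01, 0.01) if rng.random() < 0.7 \
                else rng.uniform(50, 1100)
            expected = brute_force_mass_hits(observed, fixture_db, params)
            got = engine_hit_keys(
                match_mass_query(mass_query(observed), fixture_db, params)
            )
            assert got == expected, (observed, params)


def test_adduct_spec_parsing():
    assert NA.mass == pytest.approx(22.98977, abs=1e-5)
    assert AdductSpec.parse("21.9819").mass == pytest.approx(21.9819)
    labelled = AdductSpec.parse("formate=HCOOH")
    assert labelled.label == "formate"
    assert labelled.mass == pytest.approx(formula_mass("HCOOH"), abs=1e-9)
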