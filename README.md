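# metabosearch

Genome-restricted metabolite identification from mass-spectrometry peak
lists, with metabolic pathway mapping.

High-resolution LC-MS yields hundreds of accurate masses per sample, and most
of them go unidentified because universal chemical databases return long
lists of candidates with no biological plausibility filter. `metabosearch`
takes the opposite approach: it searches **Metabolic Reference Databases
(MRDBs)** — flat-file compound catalogs derived from genome-scale metabolic
reconstructions — so candidate identifications are restricted to compounds
the organism under study can actually produce, and every hit comes annotated
with the metabolic pathways it participates in. It is written for microbial
metabolomics practitioners who have a peak list (or names, formulae, SMILES
strings) and an organism, and want a short, pathway-mapped candidate list.

## The model

A molecular formula is a flat element-count string; its neutral monoisotopic
mass is

&nbsp;&nbsp;&nbsp;&nbsp; M = Σₑ nₑ · mₑ

with mₑ the NIST monoisotopic mass of element *e* (bundled as a versioned
constant). Electrospray ionization observes, for charge z ≥ 1 in positive
(s = +1) or negative (s = −1) mode with adduct/deduct species:

&nbsp;&nbsp;&nbsp;&nbsp; m/z = ( M + s·z·m_H + Σ adducts − Σ deducts ) / z

where m_H is the **hydrogen-atom** monoisotopic mass (1.0078250 Da; the
electron is neglected — this convention reproduces the leucine-enkephalin
lock mass [M+H]⁺ = 556.2771 to four decimals). For each mass query the
engine enumerates the full hypothesis grid — z ∈ {0, …, max_charge} crossed
with every adduct/deduct multiset up to a size cap — inverts the equation to
a candidate neutral mass, and accepts database compounds whose stored mass
lies within the tolerance (Da, or ppm referenced to the database compound's
theoretical mass). z = 0 means "match the neutral mass as given". Name
queries are case-insensitive substring matches, formula queries compare
element-count multisets, SMILES queries are exact string matches.

## Worked example

```
$ metabosearch fixture --seed 1 --out fix.tsv
wrote 41 compounds to fix.tsv
$ printf '5.32_192.0270\t1032.7\n4.10_147.0532\t88.1\n' > markers.txt
$ metabosearch search --db fix.tsv --input markers.txt --input-format markerlynx \
    --tolerance 0.001 --unit Da --max-charge 0 --out-dir out
3 match(es) for 2 query(ies); wrote out/compounds.tsv, out/pathways.tsv, out/report.html
```

The compounds file (parameter echo elided):

```
query          query_type  db_name           compound_id  compound_name  formula  theoretical_mass  ion  deviation_da  deviation_ppm  cas_id
5.32_192.0270  mass        fixture-organism  CPD-0022     citrate        C6H8O7   192.0270          [M]  -0.0000       -0.02          77-92-9   5.32  1032.7
5.32_192.0270  mass        fixture-organism  CPD-0023     isocitrate     C6H8O7   192.0270          [M]  -0.0000       -0.02          320-77-4  5.32  1032.7
4.10_147.0532  mass        fixture-organism  CPD-0014     L-Glutamate    C5H9NO4  147.0532          [M]  0.0000        0.29           56-86-0   4.10  88.1
```

The first marker (retention time 5.32 min, m/z 192.0270) hits *two*
compounds: citrate and isocitrate share the formula C₆H₈O₇ and are therefore
isobaric — exactly the ambiguity a mass-only search cannot resolve and a
retention-time standard must. The second marker identifies glutamate with a
+0.29 ppm deviation. The trailing columns are the retention time and
intensity carried through from the input untouched. `pathways.tsv` repeats
each row once per pathway (glutamate appears three times), and `report.html`
adds hyperlinks into the source pathway database.

The same is available from Python — see `examples/` for four short
scripts (mass/ion arithmetic, peak-list search, genome restriction,
mixed query types).

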