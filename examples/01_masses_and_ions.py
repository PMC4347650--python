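"""From a molecular formula to the m/z values an ESI instrument observes.

Parses citric-acid's formula, computes its neutral monoisotopic mass, and
enumerates the m/z of the common positive-mode ion species.
"""

from metabosearch import formula_mass, ion_mz, neutral_mass_from_observed
from metabosearch.formula_mass import DEFAULT_ELEMENT_TABLE

M = formula_mass("C6H8O7")
na = DEFAULT_ELEMENT_TABLE.mass("Na")
h = DEFAULT_ELEMENT_TABLE.mass("H")

print(f"citrate / isocitrate (C6H8O7) neutral monoisotopic mass: {M:.4f} Da")
print(f"  [M+H]+   = {ion_mz(M, 1, 'positive'):.4f}")
print(f"  [M+2H]2+ = {ion_mz(M, 2, 'positive'):.4f}")
print(f"  [M+Na]+  = {ion_mz(M, 1, 'positive', [na], [h]):.4f}  (adduct Na, deduct H)")
print(f"  [M-H]-   = {ion_mz(M, 1, 'negative'):.4f}")

# and back: an observed peak neutralized under the [M+H]+ hypothesis
obs = ion_mz(M, 1, "positive")
print(f"neutralizing {obs:.4f} under [M+H]+ recovers {neutral_mass_from_observed(obs, 1, 'positive'):.4f} Da")
# The neutral mass is what the database stores, so any charged observation
# can be matched by inverting its ion hypothesis.
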