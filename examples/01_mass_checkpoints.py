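"""Label-aware mass arithmetic: the gamma-18O-glutamate checkpoints.

Builds the elemental compositions of 18O-labeled glutamate and its Boc
intermediate and prints the adduct m/z values used to verify the label
synthesis analytically.
"""

from polyglu import ElementalComposition, low_res_mz, mono_mass, mz

glu_o18 = ElementalComposition({"C": 5, "H": 9, "N": 1, "O": 3, "18O": 1})
boc_o18 = ElementalComposition({"C": 10, "H": 17, "N": 1, "O": 5, "18O": 1})

print(f"gamma-18O-Glu neutral monoisotopic mass : {mono_mass(glu_o18):.5f} Da")
print(f"[M-H]- high-resolution m/z              : {mz(mono_mass(glu_o18), 1, 'deprotonated'):.5f}")
print(f"[M-H]- unit-resolution ESI reading      : {low_res_mz(glu_o18, 1, 'deprotonated'):.1f}")
print(f"Boc-gamma-18O-Glu [M+Na]+ m/z           : {mz(mono_mass(boc_o18), 1, 'sodiated'):.1f}")
print()
print("The +2.00425 Da shift per 18O atom is what lets MS1 envelopes report")
print("whether a labeled glutamate's gamma-carboxyl survived bond formation.")
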