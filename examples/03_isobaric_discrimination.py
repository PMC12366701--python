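"""Why MS1 cannot tell extension from branching - and MS/MS can.

Compares a 2-Glu C-terminal extension with a 2-Glu lateral branch at E445 on
the same tryptic peptide: identical precursor mass, different fragment
ladders.
"""

from polyglu import (
    Peptidoform,
    composition,
    discriminating_ions,
    glu_chain,
    mono_mass,
    variant_cterm_peptidoform,
)

pep, start = variant_cterm_peptidoform("TUBA1B", "dTyr")
ext = Peptidoform(peptide=pep, start=start, extension=glu_chain(2, "D5"))
br = Peptidoform(peptide=pep, start=start, branches=((445, glu_chain(2, "D5")),))

m_ext, m_br = mono_mass(composition(ext)), mono_mass(composition(br))
print(f"extension form : {ext.canonical()}")
print(f"branch form    : {br.canonical()}")
print(f"precursor masses: {m_ext:.6f} vs {m_br:.6f} Da  (|diff| = {abs(m_ext - m_br):.2e} Da)")

pairs = discriminating_ions(ext, br, tol_ppm=20)
print(f"\ndiscriminating fragment ions: {len(pairs)}")
for a, b in pairs[:6]:
    ion = a or b
    mza = f"{a.mz:.4f}" if a else "absent"
    mzb = f"{b.mz:.4f}" if b else "absent"
    print(f"  {ion.series}{ion.index:<3} extension {mza:>10}   branch {mzb:>10}")
print("  ...")
print("\nEvery listed ion shifts (or exists) in only one topology, so a single")
print("MS/MS spectrum resolves the attachment site the precursor mass cannot.")
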