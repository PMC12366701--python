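"""From a tubulin tail to the candidate peptidoform space.

Loads the TUBA1B C-tail, derives the detyrosinated variant, digests it with
trypsin/LysC, and enumerates every way of distributing two added glutamates
between the C-terminal extension and the E445/E446/E447 branch sites.
"""

from polyglu import (
    DigestRule,
    cterm_peptide,
    digest,
    enumerate_peptidoforms,
    load_tails,
    make_variant,
)

tails = load_tails()
variant = make_variant(tails["TUBA1B"], "dTyr")
print(f"alpha-tail (dTyr): ...{variant.sequence[-12:]}  (ends at residue {variant.last_residue})")

peps = digest(variant.sequence, DigestRule(enzyme="trypsin_lysC"))
pep = cterm_peptide(peps)
start = variant.numbering_offset + pep.start + 1
print(f"tryptic C-terminal peptide: {pep.sequence} (residues {start}-{start + len(pep.sequence) - 1})")

forms = enumerate_peptidoforms(pep.sequence, start, 2, allowed_sites=(445, 446, 447), label="D5")
print(f"\ncandidate peptidoforms with <= 2 added D5-Glu: {len(forms)}")
for f in forms:
    print(" ", f.canonical())
print("\nForms with equal total Glu are isobaric at MS1; only their b/y ladders differ.")
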