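# polyglu

Inference of tubulin C-terminal tail **polyglutamylation** from LC-MS/MS
data: candidate peptidoform enumeration, stable-isotope-aware mass
arithmetic, branched b/y fragment ladders, attachment-site localization,
¹⁸O-based linkage-chemistry calling, and pool-normalized quantification of
glutamylation-state distributions.

## The problem

Tubulin C-terminal tails are decorated with polyglutamate chains added by
TTLL-family glutamylases. Two chemically distinct topologies produce the
same added mass:

* **lateral branching** — the first glutamate is attached through the
  γ-carboxyl of an internal Glu residue (an isopeptide bond), e.g. at
  E445/E446/E447 of α-tubulin;
* **primary-chain extension** — glutamates are appended to the α-carboxyl
  of the polypeptide C-terminus, directly elongating the main chain.

A peptide with *k* added glutamates has the same precursor mass whichever
topology carries them: branched and extended forms are **isobaric at MS1**
and can only be told apart on the fragmentation level. For a main chain of
*n* residues plus *k* appended units, the b/y ladder obeys

> b_i + y_{N−i} = M + 2·m_H⁺  for every cut i, N = n + k,

and a branch at residue *r* shifts every fragment containing *r* by the
full branch-chain mass. Ions that differ between candidate topologies
("discriminating ions") localize the attachment site; the score of a
candidate is Σ √(relative intensity) over its matched ions plus a bonus on
matched discriminating ions, and a site is called when the top candidate
leads by a margin (delta score).

Linkage chemistry is read from γ-¹⁸O-labeled glutamate: a label survives
amide-bond formation only if the bond is not formed through the labeled
carboxyl, so an α-linked (extended) chain of *k* labels retains all *k*
(+2.00425·k Da), while a γ-linked chain loses each within-chain label with
probability ½ — a binomial(k−1, ½) envelope signature.

Quantification uses the *pool rule*: per-state MS1 intensities from the
before- and after-reaction samples are normalized so the combined pool sums
to 1, and the conversion fraction is the after-pool mass at k ≥ 1.

A bundled synthetic-data generator (envelope peaks, fragment spectra with
coverage/jitter/decoy noise, ground-truth manifests) makes every stage
testable without instrument data.

## Worked example

```sh
python examples/03_isobaric_discrimination.py
```

```
extension form : DYEEVGVDSVEGEGEEEGEE/431+ext[E:D5,E:D5]
branch form    : DYEEVGVDSVEGEGEEEGEE/431+br@445[E:D5,E:D5]
precursor masses: 2452.982196 vs 2452.982196 Da  (|diff| = 0.00e+00 Da)

discriminating fragment ions: 26
  b15  extension  1594.6391   branch  1862.7871
  ...
```

The two forms of the tryptic α-tail peptide (residues 431–450, two added
D5-glutamates) are exactly isobaric, yet 26 fragment ions differ — b-ions
past residue 445 carry the branch mass only in the branched form, and the
y-series extends into the appended chain only in the extended form.

```sh
python examples/06_quantification.py
```

```
combined normalized pool sums to 1.000000000
recovered conversion fraction: 0.9018  (planted 0.9)
```

A simulated before/after experiment with 90 % planted conversion and a
geometric chain-length distribution over 0–11 added glutamates is recovered
to within 0.002. The other examples cover the label mass checkpoints
(`01`), digestion and candidate enumeration (`02`), site localization on
exemplar spectra (`04`), and ¹⁸O linkage calling (`05`).

The full pipeline is also exposed as a thin CLI:

```sh
polyglu run --out bundle --seed 1     # simulate → localize → quantify
polyglu digest DYEEVGVDSVEGEGEEEGEEY  # single stages
```

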