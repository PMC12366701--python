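# Methods

This note documents the models, defaults, and design choices behind
`polyglu`, and what the synthetic-data tests do and do not demonstrate
about real instrument data.

## Coordinates, tails, and peptidoforms

Residue positions are 1-based full-length mature-isoform numbers
throughout; peptide-local indices never appear in outputs. The bundled
C-tail fixtures (TUBA1A/TUBA1B, TUBB5/TUBB4B, TUBB2A/TUBB2B) come from
UniProt and are recorded with their accession and C-terminal residue number
in `data/tails_manifest.json`, so the α-tubulin branch hotspots E445–E447
are addressable directly. Truncation variants (αTyr/αΔTyr/αΔ2/αΔ3 and the
β analogues) are prefixes of the base tail.

A `Peptidoform` is a digested peptide plus a modification topology: an
ordered *extension* chain appended to the C-terminal α-carboxyl and/or
*branch* chains keyed by internal Glu positions. Each added unit carries a
label (`light`, `D5`, `O18`) and the linkage through which it binds the
*next* unit (`alpha`/`gamma`/`none`). Within-chain linkage defaults to
α — the elongation chemistry — and is configurable per unit. Candidate
enumeration distributes 0..k_max glutamates across the extension and the
allowed branch sites with one uniform label; label multisets are not
enumerated because a reaction uses a single glutamate species.

## Digestion

`trypsin_lysC` cleaves after K unconditionally (the LysC component ignores
the proline rule) and after R unless followed by P; `aspN` cleaves
N-terminal to D, with an optional E-inclusive mode since tubulin tails are
Glu-rich (off by default — the conservative specificity). Missed-cleavage
products are generated up to a limit. Added glutamate chains are never
cleavage substrates: digestion operates on the genetically encoded
sequence and chains are attached afterwards.

## Masses and envelopes

All isotope masses and abundances are pinned in `data/isotopes.json`
(CODATA/IUPAC values), making every printed mass bit-stable. Compositions
carry explicit heavy-isotope slots (`2H`, `13C`, `18O`): a heavy atom
contributes its exact mass and no isotopic spread, while C/H/N/O/S are
convolved from their natural distributions. Envelopes are aggregated on
the nominal-mass grid (fine structure is out of scope) with
abundance-weighted bin masses, pruned below 1e-6 relative abundance
(default) and renormalized. Adducts: protonated, deprotonated, sodiated,
with electron mass accounted. `low_res_mz` additionally reports the
unit-resolution ESI reading (nominal m/z at one decimal), the convention
for low-resolution instrument printouts.

## ¹⁸O retention model

The γ-¹⁸O label sits on the γ-carboxyl. When a chain bond forms *through*
a labeled γ-carboxyl, the two carboxylate oxygens are chemically
equivalent, so the label leaves with the expelled water with probability
½; bonds through α-carboxyls never touch it. The branch-initiation bond
consumes the *substrate* residue's γ-carboxyl, so incoming labels are
never lost at initiation — only within-chain γ bonds can lose them.
Losses are independent across bonds, giving retained = m − Binomial(g, ½)
for m labels and g labeled γ bonds. Linkage calling compares an observed
MS1 envelope against the full-retention (α) and binomial-loss (γ) mixture
envelopes by L1 distance with a decision margin (default 0.1, peak pairing
within 0.02 Da); chains with fewer than two labeled units are declared
ambiguous because the two models coincide. Isotopic label purity is a
simulator parameter (default 1.0) that thins the label count binomially.

## Fragment ladders and localization

b/y ions are generated for the main chain only; branch chains ride along
intact (a flag enables exploratory b-ions into the extension). Extension
units index as continuation of the genetic sequence, so y1 of an extended
form is the last added glutamate. b1 ions are emitted but flagged
low-confidence. +1/+2 ¹³C satellite masses are available for long Glu-rich
fragments whose monoisotopic peak is weak. Neutral losses and a/c/x/z
series are out of scope.

Peak matching is greedy nearest-within-tolerance (default 20 ppm MS/MS,
10 ppm MS1), each observed peak used once, ties broken by smaller ppm
error then ladder order. The localization score is Σ √(relative
intensity) over matched ions — the square root tempers dominant peaks and
makes the score invariant to global intensity scaling — plus a bonus
(weight 1.0) on matched ions that discriminate the candidate from the
other isobaric candidates. A site call requires delta score ≥ 1.0
(default); otherwise the result is ambiguous. These thresholds codify
what is in practice a manual b/y-series reading, and are configurable.

## Quantification

Input is an integrated MS1 peak/XIC table (m/z, intensity); chromatographic
peak integration is upstream of this package. For each glutamylation state
the top-3 isotopologues are looked up at charges 2 and 3; each observed row
is apportioned to the nearest theoretical target within tolerance, and the
matched intensity is divided, per charge state, by the theoretical
abundance fraction of the isotopologues actually matched. This corrects
both the envelope-width difference between short and long chains and the
occasional dropped peak, without assuming the charge-state split. Pool
normalization divides every intensity by the grand total of the combined
before+after tables, so the pool sums to exactly 1; the conversion
fraction is the after-pool share at k ≥ 1. Equal ionization efficiency
across states is assumed (the standard caveat, echoed in the JSON report).
Isobaric branched/extended forms are quantified jointly at MS1 and split
only when localization results are supplied.

## Synthetic data: what it emulates, and what it does not

The generator plants, per variant, a before pool (unmodified peptide) and
an after pool whose states follow P(0) = 1 − conversion and a truncated
geometric (p = 0.25) over k = 1..max_k — the monotone-decay shape of real
XIC state series. Defaults chosen once as the study conditions: conversion
0.9, max_k 11 for α-tails (27 supported for β), D5 label, m/z jitter 5 ppm
s.d., log-normal intensity noise σ = 0.1 (MS1) and 0.5 (fragments),
fragment coverage 0.9, 10 uniform decoy peaks per spectrum over the
250–2500 m/z acquisition window, charges 2–3 split 60/40. Random streams
are partitioned per spectrum, so enlarging a simulation never perturbs
earlier spectra, and a fixed seed reproduces output files byte for byte.

Not emulated: chromatographic peak shapes and co-elution, ion-mobility
separation, charge-state-dependent ionization efficiency, profile-mode
peak shapes, chimeric MS/MS, and real fragmentation propensities
(fragment presence is i.i.d. at the coverage probability). Passing
recovery tests therefore demonstrates the *inference* is correct under the
stated noise model, not that the noise model captures every failure mode
of instrument data.

## Numerical choices and problem sizes

Envelope convolution uses binary exponentiation per element with relative
pruning (1e-3 of the target prune) at intermediate steps; associativity
holds to <1e-6 Da / 1e-4 relative on all bins above 1e-6 abundance.
Envelopes are cached by composition during quantification. Degenerate
inputs fail loudly: empty digests, zero pool totals, branch sites that are
not Glu, non-isobaric inputs to the discriminating-ion analysis, linkage
calls without ¹⁸O units. Test and acceptance runs use the α-tail tryptic
peptide with up to 11 added glutamates, 20 replicates per planted
conversion and 1000 linkage trials — sizes chosen so the full suite
completes in well under a minute while keeping Monte-Carlo error an order
of magnitude below the asserted tolerances.

## Known limitations

β-tubulin branch positions are not modeled unless supplied by the user
(β forms default to extension-only candidates). The score has no
target–decoy FDR calibration — candidate spaces here are single-protein.
Branch-internal fragmentation is off by default. Average masses and
sulfur-PTM chemistry are out of scope.
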