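"""Pool-normalized quantification of glutamylation states.

Simulates a before/after enzyme-reaction experiment (planted conversion
0.9, geometric chain lengths up to 11 added Glu), extracts per-state MS1
intensities, applies the pool normalization (before + after sum to 1), and
reports the recovered conversion fraction.
"""

from polyglu import (
    Peptidoform,
    SimulationConfig,
    conversion_fraction,
    extract_state_intensities,
    glu_chain,
    normalize_pool,
    simulate_sample,
    variant_cterm_peptidoform,
)
from polyglu.quant import state_distribution

cfg = SimulationConfig(conversion=0.9, max_k=11, seed=1, n_ms2=0)
sample = simulate_sample(cfg)

pep, start = variant_cterm_peptidoform("TUBA1B", "dTyr")
series = [
    Peptidoform(peptide=pep, start=start, extension=glu_chain(k, "D5")) for k in range(12)
]
before = extract_state_intensities(
    sample.ms1[sample.ms1.condition == "before"], series, variant="aDTyr", condition="before"
)
after = extract_state_intensities(
    sample.ms1[sample.ms1.condition == "after"], series, variant="aDTyr", condition="after"
)
table = normalize_pool(before, after)

print(f"combined normalized pool sums to {table['normalized_intensity'].sum():.9f}")
print(f"recovered conversion fraction: {float(conversion_fraction(table)['aDTyr']):.4f}"
      f"  (planted {cfg.conversion})")
print("\nafter-pool glutamylation-state distribution (k = added Glu):")
for k, frac in state_distribution(table, "after").items():
    print(f"  k={k:<2} {frac:.4f} " + "#" * int(200 * frac))
print("\nThe decaying histogram mirrors the XIC state series of a heavily")
print("modified substrate; the conversion is the mass at k >= 1.")
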