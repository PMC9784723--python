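"""Simulate a genome with planted retroelements and inspect the truth.

The generator plants eight locus categories: autonomous LTR
retrotransposons (full-length and truncated), five non-autonomous TR
subtypes (two LTRs around a single ORF) and gene-like multi-exon loci,
three of which are GAG-host fusions emulating domesticated GAG genes.
"""

from collections import Counter

from retroscope import SimConfig, simulate_genome

config = SimConfig(seed=1, genome_length=300_000)
genome, truth = simulate_genome(config)

print(f"genome: {len(genome):,} bp, {len(truth)} planted elements")
print("census:", dict(Counter(t.category for t in truth)))

te = next(t for t in truth if t.category == "tr_gag")
print(f"\nexample TR element {te.element_id}:")
print(f"  span {te.span}, strand {te.strand}, TSD {te.tsd!r}")
print(f"  LTRs {te.ltr5_span} / {te.ltr3_span}, encodes {te.domain_layout}")
# A TR-GAG element: two long terminal repeats flanking one GAG-encoding ORF,
# the whole cassette bracketed by a short target-site duplication.
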